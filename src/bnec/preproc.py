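"""ROI extraction and time-series preprocessing.

Turns volumetric resting-state data (NIfTI) or raw ROI matrices into the
analysis-ready series the network stage consumes.  The chain mirrors
standard resting-state practice: linear detrending, frequency-domain
band-pass filtering (default 0.01–0.08 Hz), then least-squares regression
of nuisance signals (six head-motion profiles, global, white-matter and
CSF signals, provided as columns).

ROI spheres live in world (MNI) millimetre space: a voxel belongs to a
sphere when its center, mapped through the image affine, lies within the
radius (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.signal

from .exceptions import (
    ExtractionError,
    FormatError,
    ParameterError,
    RankDeficiencyError,
)


@dataclass(frozen=True)
class ROIDefinition:
    """A spherical region of interest in MNI millimetre coordinates."""

    name: str
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"ROI {self.name!r}: radius must be positive")
        if len(self.center) != 3:
            raise ParameterError(f"ROI {self.name!r}: center must be (x, y, z)")


def _check_unique(rois: Sequence[ROIDefinition]) -> None:
    names = [r.name for r in rois]
    if len(set(names)) != len(names):
        raise ParameterError("ROI names must be unique")


def _load_image(image: "nib.spatialimages.SpatialImage | str"):
    if isinstance(image, (str,)):
        try:
            image = nib.load(image)
        except Exception as err:  # nibabel raises several unrelated types
            raise FormatError(f"cannot read NIfTI image: {err}") from err
    if image.affine is None:
        raise FormatError("image carries no voxel-to-world affine")
    return image


def _sphere_mask(shape3d, affine: np.ndarray, roi: ROIDefinition) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(shape3d[0]), np.arange(shape3d[1]), np.arange(shape3d[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = nib.affines.apply_affine(affine, vox)
    d2 = np.sum((world - np.asarray(roi.center)) ** 2, axis=1)
    mask = (d2 <= roi.radius**2 + 1e-9).reshape(shape3d)
    if not mask.any():
        raise ExtractionError(
            f"ROI {roi.name!r} (center {roi.center}, radius {roi.radius} mm) "
            "contains no voxel centers"
        )
    return mask


def extract_roi_timeseries(
    image: "nib.spatialimages.SpatialImage | str",
    rois: Sequence[ROIDefinition],
) -> pd.DataFrame:
    """Mean time course over each ROI sphere of a 4-D image.

    Column ``r`` at time ``t`` is the mean of the voxels whose world-space
    centers lie within ``radius`` of the ROI center (Euclidean distance,
    boundary inclusive).
    """
    _check_unique(rois)
    img = _load_image(image)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D image, got {data.ndim}-D")
    cols = {}
    for roi in rois:
        mask = _sphere_mask(data.shape[:3], img.affine, roi)
        cols[roi.name] = data[mask].mean(axis=0)
    return pd.DataFrame(cols)


def roi_mean_z(
    zmap: "nib.spatialimages.SpatialImage | str", roi: ROIDefinition
) -> float:
    """Mean z-score over an ROI sphere of a 3-D statistical map."""
    img = _load_image(zmap)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D map, got {data.ndim}-D")
    mask = _sphere_mask(data.shape, img.affine, roi)
    return float(data[mask].mean())


# ---------------------------------------------------------------------------
# temporal filters
# ---------------------------------------------------------------------------


def _as_matrix(series) -> tuple[np.ndarray, "pd.DataFrame | None"]:
    if isinstance(series, pd.DataFrame):
        return series.to_numpy(dtype=float), series
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


def _like(result: np.ndarray, template: "pd.DataFrame | None"):
    if template is not None:
        return pd.DataFrame(result, index=template.index, columns=template.columns)
    return result


def detrend(series):
    """Remove each column's least-squares line (slope and intercept)."""
    x, template = _as_matrix(series)
    if x.shape[0] < 3:
        raise ParameterError("detrend needs at least 3 timepoints")
    out = scipy.signal.detrend(x, axis=0, type="linear")
    return _like(out, template)


def bandpass_filter(series, tr_seconds: float, low_hz: float, high_hz: float):
    """Zero DFT bins outside [low_hz, high_hz] (inclusive) per column.

    A discrete-Fourier mask rather than an IIR filter: exactly invertible
    on retained bins and exactly zero on rejected ones, which makes the
    operation directly testable against the transform itself.
    """
    if tr_seconds <= 0:
        raise ParameterError("tr_seconds must be positive")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 <= low_hz < high_hz <= nyquist + 1e-12):
        raise ParameterError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist:.4g}] "
            "or inverted"
        )
    x, template = _as_matrix(series)
    n = x.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=0)
    return _like(out, template)


def nuisance_regress(series, confounds):
    """Residualize each column on [intercept | confounds] by least squares.

    Residuals are orthogonal to every confound column.  A rank-deficient
    design (after adding the intercept) is rejected with the offending
    columns named.
    """
    y, template = _as_matrix(series)
    c, cframe = _as_matrix(confounds)
    if c.shape[0] != y.shape[0]:
        raise ParameterError(
            f"confounds have {c.shape[0]} rows but series has {y.shape[0]}"
        )
    design = np.column_stack([np.ones(y.shape[0]), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = (
            list(cframe.columns)
            if cframe is not None
            else [f"confound_{j}" for j in range(c.shape[1])]
        )
        # walk columns, flagging any that adds no rank
        offending = []
        running = design[:, :1]
        for j in range(c.shape[1]):
            cand = np.column_stack([running, c[:, j]])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(running):
                offending.append(names[j])
            else:
                running = cand
        raise RankDeficiencyError(
            f"confound design is rank deficient; offending columns: {offending}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    out = y - design @ beta
    return _like(out, template)


def preprocess_series(
    series,
    tr_seconds: float = 2.0,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    confounds=None,
    do_detrend: bool = True,
    do_bandpass: bool = True,
):
    """Full chain: detrend, band-pass and nuisance regression, jointly.

    The three steps are all linear projections; applying them one after the
    other is only approximately idempotent because the trend line is not
    spanned by Fourier modes and confounds are not band-limited.  The chain
    therefore removes the union of the nuisance subspaces in a single
    least-squares projection: the linear-trend basis, the DFT modes outside
    ``[low_hz, high_hz]``, and the confound columns.  Each step alone
    reduces to the corresponding single operation, and the composite is
    exactly idempotent.
    """
    x, template = _as_matrix(series)
    n = x.shape[0]
    if n < 3:
        raise ParameterError("preprocessing needs at least 3 timepoints")
    columns = []
    if do_detrend:
        t = np.arange(n, dtype=float)
        columns.append(np.ones(n))
        columns.append(t - t.mean())
    if do_bandpass:
        if tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 <= low_hz < high_hz <= nyquist + 1e-12):
            raise ParameterError(
                f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist:.4g}]"
            )
        freqs = np.fft.rfftfreq(n, d=tr_seconds)
        t = np.arange(n, dtype=float)
        for m, f in enumerate(freqs):
            if low_hz - 1e-12 <= f <= high_hz + 1e-12:
                continue  # retained bin
            columns.append(np.cos(2 * np.pi * m * t / n))
            if 0 < m < n / 2:
                columns.append(np.sin(2 * np.pi * m * t / n))
    if confounds is not None:
        c, _ = _as_matrix(confounds)
        if c.shape[0] != n:
            raise ParameterError(
                f"confounds have {c.shape[0]} rows but series has {n}"
            )
        columns.extend(c.T)
    if not columns:
        return _like(x.copy(), template)
    design = np.column_stack(columns)
    if design.shape[1] >= n:
        raise ParameterError(
            f"nuisance subspace ({design.shape[1]} columns) is not smaller "
            f"than the series length ({n})"
        )
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return _like(x - design @ beta, template)
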