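"""ROI sphere extraction and the detrend / band-pass / nuisance chain."""

import nibabel as nib
import numpy as np
import pytest

from bnec.exceptions import ExtractionError, ParameterError, RankDeficiencyError
from bnec.preproc import (
    ROIDefinition,
    bandpass_filter,
    detrend,
    extract_roi_timeseries,
    nuisance_regress,
    preprocess_series,
    roi_mean_z,
)


def _img4d(data, voxel_mm=3.0):
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)


def _brute_force_sphere(shape, voxel_mm, center, radius):
    hits = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                d = np.linalg.norm(voxel_mm * np.array([i, j, k]) - np.array(center))
                if d <= radius:
                    hits.append((i, j, k))
    return hits


class TestSphereExtraction:
    def test_constant_sphere_returns_constant(self):
        data = np.zeros((10, 10, 10, 5))
        roi = ROIDefinition("PCC", (15.0, 15.0, 15.0), 6.0)
        hits = _brute_force_sphere((10, 10, 10), 3.0, roi.center, roi.radius)
        for i, j, k in hits:
            data[i, j, k, :] = 4.5
        series = extract_roi_timeseries(_img4d(data), [roi])
        assert np.allclose(series["PCC"], 4.5)

    def test_voxel_count_at_radius_6_on_3mm_grid(self):
        # oracle: integer offsets with ||3*(i,j,k)|| <= 6, boundary inclusive
        data = np.zeros((11, 11, 11, 1))
        roi = ROIDefinition("R", (15.0, 15.0, 15.0), 6.0)
        hits = _brute_force_sphere((11, 11, 11), 3.0, roi.center, roi.radius)
        data[:, :, :, 0] = 1.0
        series = extract_roi_timeseries(_img4d(data), [roi])
        assert len(hits) == 33
        # verify the mean uses exactly those voxels: weight one voxel
        data2 = np.zeros((11, 11, 11, 1))
        for i, j, k in hits:
            data2[i, j, k, 0] = 2.0
        series2 = extract_roi_timeseries(_img4d(data2), [roi])
        assert series2["R"].iloc[0] == pytest.approx(2.0)

    def test_two_disjoint_rois_match_masked_mean_oracle(self, rng):
        data = rng.standard_normal((12, 12, 12, 7))
        rois = [
            ROIDefinition("L", (6.0, 6.0, 6.0), 4.0),
            ROIDefinition("R", (27.0, 27.0, 27.0), 4.0),
        ]
        series = extract_roi_timeseries(_img4d(data), rois)
        for roi in rois:
            hits = _brute_force_sphere((12, 12, 12), 3.0, roi.center, roi.radius)
            oracle = np.mean([data[i, j, k, :] for i, j, k in hits], axis=0)
            assert np.allclose(series[roi.name], oracle, atol=1e-10)

    def test_empty_sphere_raises_with_roi_name(self):
        data = np.zeros((5, 5, 5, 2))
        roi = ROIDefinition("tiny", (4.5, 4.5, 4.5), 0.5)
        with pytest.raises(ExtractionError, match="tiny"):
            extract_roi_timeseries(_img4d(data), [roi])

    def test_roi_mean_z(self, rng):
        data = rng.standard_normal((8, 8, 8))
        img = nib.Nifti1Image(data, np.diag([3.0, 3.0, 3.0, 1.0]))
        roi = ROIDefinition("R", (12.0, 12.0, 12.0), 5.0)
        hits = _brute_force_sphere((8, 8, 8), 3.0, roi.center, roi.radius)
        oracle = np.mean([data[i, j, k] for i, j, k in hits])
        assert roi_mean_z(img, roi) == pytest.approx(oracle, abs=1e-10)
        zero = nib.Nifti1Image(np.zeros((8, 8, 8)), np.diag([3.0, 3.0, 3.0, 1.0]))
        assert roi_mean_z(zero, roi) == 0.0

    def test_constant_z_value(self):
        data = np.full((8, 8, 8), 1.7)
        img = nib.Nifti1Image(data, np.diag([3.0, 3.0, 3.0, 1.0]))
        assert roi_mean_z(img, ROIDefinition("R", (12.0, 12.0, 12.0), 6.0)) == pytest.approx(1.7)


class TestDetrend:
    def test_exact_line_removed(self):
        t = np.arange(50.0)
        out = detrend((2.0 * t + 5.0)[:, None])
        assert np.max(np.abs(out)) < 1e-10

    def test_idempotent_on_detrended_input(self, rng):
        x = rng.standard_normal((100, 3))
        once = detrend(x)
        twice = detrend(once)
        assert np.allclose(once, twice, atol=1e-10)

    def test_residual_orthogonal_to_line_basis(self, rng):
        x = rng.standard_normal((80, 2))
        out = detrend(x)
        t = np.arange(80.0)
        assert abs(out.sum(axis=0)).max() < 1e-8
        assert abs(t @ out).max() < 1e-6

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            detrend(np.zeros((2, 1)))


class TestBandpass:
    def test_retained_bin_unchanged(self):
        n, tr = 190, 2.0
        freqs = np.fft.rfftfreq(n, tr)
        inside = freqs[(freqs >= 0.02) & (freqs <= 0.07)][0]
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * inside * t)[:, None]
        out = bandpass_filter(x, tr, 0.01, 0.08)
        assert np.allclose(out, x, atol=1e-8)

    def test_out_of_band_sinusoid_attenuated(self):
        n, tr = 190, 2.0
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.2 * t)[:, None]
        out = bandpass_filter(x, tr, 0.01, 0.08)
        rms_in = np.sqrt(np.mean(x**2))
        rms_out = np.sqrt(np.mean(out**2))
        assert rms_out < 0.05 * rms_in

    def test_constant_removed_when_low_positive(self):
        out = bandpass_filter(np.full((64, 2), 3.0), 2.0, 0.01, 0.08)
        assert np.max(np.abs(out)) < 1e-10

    def test_band_validation(self):
        x = np.zeros((64, 1))
        with pytest.raises(ParameterError):
            bandpass_filter(x, 2.0, 0.08, 0.01)
        with pytest.raises(ParameterError):
            bandpass_filter(x, 2.0, 0.01, 0.3)  # above Nyquist = 0.25


class TestNuisance:
    def test_confound_copy_of_column_zeroes_it(self, rng):
        y = rng.standard_normal((60, 3))
        confounds = np.column_stack([y[:, 1], rng.standard_normal(60)])
        out = nuisance_regress(y, confounds)
        assert np.max(np.abs(np.asarray(out)[:, 1])) < 1e-8

    def test_intercept_only_mean_centers(self, rng):
        y = rng.standard_normal((40, 2)) + 5.0
        out = nuisance_regress(y, np.zeros((40, 0)))
        assert np.allclose(out, y - y.mean(axis=0), atol=1e-10)

    def test_residuals_orthogonal_to_confounds(self, rng):
        y = rng.standard_normal((120, 4))
        c = rng.standard_normal((120, 8))
        out = nuisance_regress(y, c)
        assert np.max(np.abs(c.T @ np.asarray(out))) < 1e-8

    def test_rank_deficiency_names_columns(self, rng):
        import pandas as pd

        c = rng.standard_normal((50, 2))
        frame = pd.DataFrame(
            {"motion1": c[:, 0], "motion2": c[:, 1], "dup": c[:, 0]}
        )
        with pytest.raises(RankDeficiencyError, match="dup"):
            nuisance_regress(rng.standard_normal((50, 2)), frame)


class TestChain:
    def test_chain_is_nearly_idempotent(self, rng):
        x = rng.standard_normal((190, 9))
        c = rng.standard_normal((190, 8))
        once = preprocess_series(x, 2.0, 0.01, 0.08, confounds=c)
        twice = preprocess_series(once, 2.0, 0.01, 0.08, confounds=c)
        rel = np.linalg.norm(np.asarray(twice) - np.asarray(once)) / np.linalg.norm(
            np.asarray(once)
        )
        assert rel < 1e-6

    @pytest.mark.parametrize("step", ["detrend", "bandpass", "nuisance"])
    def test_variance_never_increases(self, rng, step):
        x = rng.standard_normal((150, 5)) + np.linspace(0, 3, 150)[:, None]
        if step == "detrend":
            out = detrend(x)
        elif step == "bandpass":
            out = bandpass_filter(x, 2.0, 0.01, 0.08)
        else:
            out = nuisance_regress(x, rng.standard_normal((150, 6)))
        assert np.all(np.var(np.asarray(out), axis=0) <= np.var(x, axis=0) + 1e-10)
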