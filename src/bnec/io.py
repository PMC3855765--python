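"""Plain-text serialization of every artifact the pipeline touches.

Dialects (all tab-separated with header rows):

* subject series — one file per subject, header = region names, one row
  per timepoint;
* subjects manifest — ``subject_id  group  path`` (path relative to the
  manifest's directory);
* covariates / FC tables — ``subject_id`` plus named columns;
* DAG + parameters — an edge list ``parent  child  weight`` and a node
  table ``node  mean  variance``;
* ROI table — ``name  x  y  z  radius_mm``;
* cohort config — a key=value file referencing the truth files above.

Readers validate column layouts and raise :class:`~bnec.exceptions.FormatError`
naming the offending file.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .exceptions import FormatError
from .gbn import DAGStructure, GBNParameters
from .metrics import ConvergenceIndexTable
from .preproc import ROIDefinition
from .synthetic import (
    CohortConfig,
    CohortTimeSeries,
    CovariateLink,
    SubjectSeries,
    SyntheticCohort,
)

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def write_matrix(path: "str | Path", data: pd.DataFrame) -> None:
    data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_matrix(path: "str | Path", expect_columns: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as err:
        raise FormatError(f"{path}: not a readable tab-separated table ({err})") from err
    if expect_columns is not None and list(df.columns) != list(expect_columns):
        raise FormatError(
            f"{path}: expected columns {list(expect_columns)}, found {list(df.columns)}"
        )
    return df


# ---------------------------------------------------------------------------
# DAG + parameters
# ---------------------------------------------------------------------------


def write_bn(
    directory: "str | Path", stem: str, dag: DAGStructure, params: GBNParameters | None
) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edges_path = directory / f"{stem}_edges.tsv"
    nodes_path = directory / f"{stem}_nodes.tsv"
    rows = []
    for p, c in dag.edges():
        w = params.weights.get(c, {}).get(p, math.nan) if params else math.nan
        rows.append({"parent": p, "child": c, "weight": w})
    # 17 significant digits: doubles round-trip exactly
    pd.DataFrame(rows, columns=["parent", "child", "weight"]).to_csv(
        edges_path, sep="\t", index=False, float_format="%.17g"
    )
    nrows = []
    for n in dag.nodes:
        nrows.append(
            {
                "node": n,
                "mean": params.mean[n] if params else math.nan,
                "variance": params.variance[n] if params else math.nan,
            }
        )
    pd.DataFrame(nrows, columns=["node", "mean", "variance"]).to_csv(
        nodes_path, sep="\t", index=False, float_format="%.17g"
    )
    return edges_path, nodes_path


def read_bn(directory: "str | Path", stem: str) -> tuple[DAGStructure, GBNParameters]:
    directory = Path(directory)
    edges = read_matrix(directory / f"{stem}_edges.tsv", ["parent", "child", "weight"])
    nodes = read_matrix(directory / f"{stem}_nodes.tsv", ["node", "mean", "variance"])
    node_names = tuple(nodes["node"].astype(str))
    dag = DAGStructure.from_edges(
        node_names, list(zip(edges["parent"].astype(str), edges["child"].astype(str)))
    )
    weights: dict[str, dict[str, float]] = {n: {} for n in node_names}
    for _, row in edges.iterrows():
        weights[str(row["child"])][str(row["parent"])] = float(row["weight"])
    params = GBNParameters(
        mean={str(r["node"]): float(r["mean"]) for _, r in nodes.iterrows()},
        variance={str(r["node"]): float(r["variance"]) for _, r in nodes.iterrows()},
        weights=weights,
    )
    return dag, params


def write_dot(path: "str | Path", dag: DAGStructure, params: GBNParameters | None = None) -> None:
    """DOT-format text export for visualization."""
    lines = ["digraph EC {"]
    for n in dag.nodes:
        lines.append(f'  "{n}";')
    for p, c in dag.edges():
        if params is not None:
            w = params.weights.get(c, {}).get(p, float("nan"))
            lines.append(f'  "{p}" -> "{c}" [label="{w:.3f}"];')
        else:
            lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ROI table and confounds
# ---------------------------------------------------------------------------


def read_roi_table(path: "str | Path") -> list[ROIDefinition]:
    df = read_matrix(path, ["name", "x", "y", "z", "radius_mm"])
    return [
        ROIDefinition(
            name=str(r["name"]),
            center=(float(r["x"]), float(r["y"]), float(r["z"])),
            radius=float(r["radius_mm"]),
        )
        for _, r in df.iterrows()
    ]


def write_roi_table(path: "str | Path", rois: Sequence[ROIDefinition]) -> None:
    pd.DataFrame(
        [
            {"name": r.name, "x": r.center[0], "y": r.center[1],
             "z": r.center[2], "radius_mm": r.radius}
            for r in rois
        ]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, directory: "str | Path") -> Path:
    """Write a cohort: subject files, manifest, covariates, FC, truth."""
    directory = Path(directory)
    (directory / "subjects").mkdir(parents=True, exist_ok=True)
    ts = cohort.timeseries
    manifest_rows = []
    for s in ts.subjects:
        rel = Path("subjects") / f"{s.subject_id}.tsv"
        write_matrix(
            directory / rel,
            pd.DataFrame(s.data, columns=list(ts.region_names)),
        )
        manifest_rows.append(
            {"subject_id": s.subject_id, "group": s.group, "path": rel.as_posix()}
        )
    pd.DataFrame(manifest_rows).to_csv(
        directory / "manifest.tsv", sep="\t", index=False
    )
    cohort.fc_z.reset_index().to_csv(
        directory / "fc_z.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    cohort.covariates.reset_index().to_csv(
        directory / "covariates.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    write_cohort_config(cohort.config, directory / "truth")
    return directory


def read_timeseries(directory: "str | Path") -> CohortTimeSeries:
    """Load subject matrices via the manifest."""
    directory = Path(directory)
    manifest = read_matrix(directory / "manifest.tsv", ["subject_id", "group", "path"])
    subjects = []
    region_names: tuple[str, ...] | None = None
    for _, row in manifest.iterrows():
        df = read_matrix(directory / str(row["path"]))
        cols = tuple(df.columns)
        if region_names is None:
            region_names = cols
        elif cols != region_names:
            raise FormatError(
                f"{row['path']}: region columns {cols} differ from {region_names}"
            )
        subjects.append(
            SubjectSeries(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                data=df.to_numpy(dtype=float),
            )
        )
    if region_names is None:
        raise FormatError(f"{directory}: manifest lists no subjects")
    return CohortTimeSeries(region_names=region_names, subjects=tuple(subjects))


def read_cohort(directory: "str | Path") -> SyntheticCohort:
    """Load a cohort written by :func:`write_cohort` (truth included)."""
    directory = Path(directory)
    ts = read_timeseries(directory)
    fc = read_matrix(directory / "fc_z.tsv").set_index("subject_id")
    cov = read_matrix(directory / "covariates.tsv").set_index("subject_id")
    config = read_cohort_config(directory / "truth")
    return SyntheticCohort(timeseries=ts, fc_z=fc, covariates=cov, config=config)


# ---------------------------------------------------------------------------
# cohort config (key=value + BN dialect files)
# ---------------------------------------------------------------------------

_SCALARS = {
    "n_group_a": int,
    "n_group_b": int,
    "n_timepoints": int,
    "ar1_coefficient": float,
    "seed": int,
    "group_a_label": str,
    "group_b_label": str,
    "fc_baseline": float,
    "fc_ci_scale": float,
    "fc_noise_sd": float,
}


def write_cohort_config(config: CohortConfig, directory: "str | Path") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for key in _SCALARS:
        val = getattr(config, key)
        if isinstance(val, float):
            lines.append(f"{key} = {val!r}")
        else:
            lines.append(f"{key} = {val}")
    for opt in ("seed_a", "seed_b"):
        val = getattr(config, opt)
        if val is not None:
            lines.append(f"{opt} = {val}")
    lines.append("region_names = " + ",".join(config.region_names))
    for name, link in sorted(config.covariate_spec.items()):
        lines.append(
            f"covariate:{name} = {link.metric},{link.strength!r},{link.noise_scale!r}"
        )
    (directory / "config.txt").write_text("\n".join(lines) + "\n")
    write_bn(directory, "dag_a", config.dag_a, config.params_a)
    write_bn(directory, "dag_b", config.dag_b, config.params_b)
    return directory


def read_cohort_config(directory: "str | Path") -> CohortConfig:
    directory = Path(directory)
    path = directory / "config.txt"
    if not path.exists():
        raise FormatError(f"{path}: missing cohort config")
    scalars: dict[str, object] = {}
    covariates: dict[str, CovariateLink] = {}
    region_names: tuple[str, ...] = ()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "region_names":
            region_names = tuple(v.strip() for v in value.split(","))
        elif key.startswith("covariate:"):
            name = key.split(":", 1)[1]
            metric, strength, noise = value.rsplit(",", 2)
            covariates[name] = CovariateLink(
                metric=metric.strip(), strength=float(strength), noise_scale=float(noise)
            )
        elif key in _SCALARS:
            scalars[key] = _SCALARS[key](value)
        elif key in ("seed_a", "seed_b"):
            scalars[key] = int(value)
        else:
            raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
    dag_a, params_a = read_bn(directory, "dag_a")
    dag_b, params_b = read_bn(directory, "dag_b")
    return CohortConfig(
        region_names=region_names,
        dag_a=dag_a,
        params_a=params_a,
        dag_b=dag_b,
        params_b=params_b,
        covariate_spec=covariates,
        **scalars,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_ci_tables(path: "str | Path", tables: Sequence[ConvergenceIndexTable]) -> None:
    frames = [t.to_frame() for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
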