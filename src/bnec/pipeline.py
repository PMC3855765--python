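"""Reproducible pipeline runs: simulate → preprocess → learn → compare → report.

Every stage reads and writes the tab-separated dialects defined in
:mod:`bnec.io`; a run log (JSON) records the seeds, the configuration hash
and the package version so a run is fully reconstructible from its
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigError, DataError
from .io import (
    read_timeseries,
    write_bn,
    write_cohort,
    write_matrix,
)
from .metrics import classify_regions, convergence_index
from .preproc import preprocess_series
from .stats import (
    compare_ci_between_groups,
    compare_fc_between_groups,
    fit_group_bn,
    fit_subject_bns,
    pearson_correlation,
    permutation_test_edges,
    spearman_correlation,
)
from .synthetic import CohortConfig, CohortTimeSeries, SubjectSeries, generate_cohort


@dataclass(frozen=True)
class RunConfig:
    """Analysis-stage knobs; paths are passed to the stage functions."""

    seed: int = 0
    n_permutations: int = 1000
    band: tuple[float, float] = (0.01, 0.08)
    tr_seconds: float = 2.0
    apply_detrend: bool = False
    apply_bandpass: bool = False
    restarts: int = 50
    permutation_restarts: int = 10
    subject_restarts: int = 10
    max_parents: int = 8
    alpha: float = 0.05
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        low, high = self.band
        if not 0 <= low < high:
            raise ConfigError("band must satisfy 0 <= low < high")


def _config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj):
        payload = repr(dataclasses.asdict(obj))
    else:
        payload = repr(obj)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_log(out_dir: Path, stage: str, **entries) -> None:
    log = {
        "stage": stage,
        "bnec_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **entries,
    }
    path = out_dir / "run_log.json"
    existing = []
    if path.exists():
        existing = json.loads(path.read_text())
    existing.append(log)
    path.write_text(json.dumps(existing, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_simulate(config: CohortConfig, out_dir: "str | Path") -> Path:
    """Generate a cohort and write it (subjects, manifest, covariates, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    write_cohort(cohort, out_dir)
    _write_log(
        out_dir, "simulate",
        seed=config.seed, config_hash=_config_hash(config),
        n_subjects=len(cohort.timeseries.subjects),
        n_timepoints=config.n_timepoints,
        regions=list(config.region_names),
    )
    return out_dir


def run_preprocess(
    cohort_dir: "str | Path", out_dir: "str | Path", run: RunConfig
) -> Path:
    """Detrend/band-pass every subject series and re-write the cohort."""
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    ts = read_timeseries(cohort_dir)
    processed = []
    for s in ts.subjects:
        df = pd.DataFrame(s.data, columns=list(ts.region_names))
        out = preprocess_series(
            df,
            tr_seconds=run.tr_seconds,
            low_hz=run.band[0],
            high_hz=run.band[1],
            do_detrend=run.apply_detrend,
            do_bandpass=run.apply_bandpass,
        )
        processed.append(
            SubjectSeries(subject_id=s.subject_id, group=s.group,
                          data=out.to_numpy(dtype=float))
        )
    out_ts = CohortTimeSeries(region_names=ts.region_names, subjects=tuple(processed))
    (out_dir / "subjects").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in out_ts.subjects:
        rel = Path("subjects") / f"{s.subject_id}.tsv"
        write_matrix(out_dir / rel, pd.DataFrame(s.data, columns=list(ts.region_names)))
        rows.append({"subject_id": s.subject_id, "group": s.group, "path": rel.as_posix()})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    for extra in ("fc_z.tsv", "covariates.tsv"):
        src = cohort_dir / extra
        if src.exists():
            (out_dir / extra).write_text(src.read_text())
    _write_log(out_dir, "preprocess", config_hash=_config_hash(run),
               band=list(run.band), tr_seconds=run.tr_seconds,
               detrend=run.apply_detrend, bandpass=run.apply_bandpass)
    return out_dir


def run_learn(cohort_dir: "str | Path", out_dir: "str | Path", run: RunConfig) -> dict:
    """Group and subject networks plus convergence-index tables."""
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts = read_timeseries(cohort_dir)
    groups = ts.groups()
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 groups, found {groups}")

    group_fits = {}
    ci_frames = []
    for g in groups:
        result, params = fit_group_bn(
            ts, g, seed=run.seed, restarts=run.restarts, max_parents=run.max_parents
        )
        write_bn(out_dir, f"group_{g}", result.dag, params)
        ci = classify_regions(convergence_index(result.dag, scope=g))
        ci_frames.append(ci.to_frame())
        group_fits[g] = (result, params)

    subject_fits = fit_subject_bns(
        ts, seed=run.seed, restarts=run.subject_restarts, max_parents=run.max_parents
    )
    for f in subject_fits:
        ci_frames.append(f.ci_table.to_frame())
    pd.concat(ci_frames, ignore_index=True).to_csv(
        out_dir / "convergence_index.tsv", sep="\t", index=False
    )
    subj_rows = [
        {"subject_id": f.subject_id, "group": f.group, "score": f.result.score,
         "n_edges": f.result.dag.n_edges}
        for f in subject_fits
    ]
    pd.DataFrame(subj_rows).to_csv(out_dir / "subject_fits.tsv", sep="\t", index=False)
    _write_log(out_dir, "learn", seed=run.seed, config_hash=_config_hash(run),
               groups=list(groups),
               group_scores={g: group_fits[g][0].score for g in groups})
    return {"groups": group_fits, "subjects": subject_fits, "timeseries": ts}


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def run_compare(
    cohort_dir: "str | Path",
    out_dir: "str | Path",
    run: RunConfig,
    learned: dict | None = None,
) -> dict:
    """Permutation test on edges, FC/CI t-tests and correlation layers."""
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts = learned["timeseries"] if learned else read_timeseries(cohort_dir)
    groups = ts.groups()
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 groups, found {groups}")
    ga, gb = groups

    perm = permutation_test_edges(
        ts, n_permutations=run.n_permutations, seed=run.seed,
        restarts=run.permutation_restarts, max_parents=run.max_parents,
        group_a=ga, group_b=gb,
    )
    edge_df = perm.to_frame()
    if run.bh_correct:
        edge_df["p_a_gt_b_bh"] = _bh_adjust(edge_df["p_a_gt_b"].to_numpy())
        edge_df["p_b_gt_a_bh"] = _bh_adjust(edge_df["p_b_gt_a"].to_numpy())
    edge_df.to_csv(out_dir / "edge_comparison.tsv", sep="\t", index=False,
                   float_format="%.6g")

    subject_fits = (
        learned["subjects"]
        if learned
        else fit_subject_bns(ts, seed=run.seed, restarts=run.subject_restarts,
                             max_parents=run.max_parents)
    )
    ci_tests = compare_ci_between_groups(subject_fits, ga, gb)
    ci_tests.to_csv(out_dir / "ci_ttests.tsv", sep="\t", index=False,
                    float_format="%.6g")

    assoc_rows = []
    fc_path = cohort_dir / "fc_z.tsv"
    cov_path = cohort_dir / "covariates.tsv"
    if fc_path.exists():
        fc = pd.read_csv(fc_path, sep="\t").set_index("subject_id")
        grp = pd.Series({s.subject_id: s.group for s in ts.subjects})
        fc = fc.loc[grp.index]
        compare_fc_between_groups(fc, grp, ga, gb).to_csv(
            out_dir / "fc_ttests.tsv", sep="\t", index=False, float_format="%.6g"
        )
        # CI–FC coupling within the patient group, subject-level CI
        ci_by_subject = {
            f.subject_id: dict(zip(f.ci_table.regions, f.ci_table.ci))
            for f in subject_fits
        }
        for region in ts.region_names:
            ids = [f.subject_id for f in subject_fits if f.group == gb]
            x = [ci_by_subject[i][region] for i in ids]
            y = [float(fc.loc[i, region]) for i in ids]
            if np.std(x) > 0 and np.std(y) > 0:
                r = pearson_correlation(x, y, f"ci:{region}", f"fc:{region}")
                assoc_rows.append(r)
        if cov_path.exists():
            cov = pd.read_csv(cov_path, sep="\t").set_index("subject_id")
            numeric = [c for c in cov.columns if c != "group"]
            ids = [f.subject_id for f in subject_fits if f.group == gb]
            for region in ts.region_names:
                x = [ci_by_subject[i][region] for i in ids]
                if np.std(x) == 0:
                    continue
                for name in numeric:
                    y = cov.loc[ids, name].to_numpy(dtype=float)
                    if np.std(y) == 0:
                        continue
                    assoc_rows.append(
                        spearman_correlation(x, y, f"ci:{region}", name)
                    )
    if assoc_rows:
        pd.DataFrame(
            [
                {"x": a.x_name, "y": a.y_name, "method": a.method,
                 "coefficient": a.coefficient, "p": a.p_value, "n": a.n}
                for a in assoc_rows
            ]
        ).to_csv(out_dir / "associations.tsv", sep="\t", index=False,
                 float_format="%.6g")

    _write_log(out_dir, "compare", seed=run.seed, config_hash=_config_hash(run),
               n_permutations=run.n_permutations,
               groups=[ga, gb])
    return {"permutation": perm, "ci_tests": ci_tests, "associations": assoc_rows}


def run_report(out_dir: "str | Path", run: RunConfig) -> Path:
    """Plain-text digest of the comparison tables in ``out_dir``."""
    out_dir = Path(out_dir)
    lines = [f"bnec {__version__} report", "=" * 30]
    edge_path = out_dir / "edge_comparison.tsv"
    if edge_path.exists():
        df = pd.read_csv(edge_path, sep="\t")
        sig = df[(df["p_a_gt_b"] < run.alpha) | (df["p_b_gt_a"] < run.alpha)]
        lines.append(
            f"directed connection differences at alpha={run.alpha} "
            f"({len(sig)} of {len(df)} ordered pairs):"
        )
        for _, r in sig.iterrows():
            direction = "A>B" if r["p_a_gt_b"] < run.alpha else "B>A"
            p = min(r["p_a_gt_b"], r["p_b_gt_a"])
            lines.append(
                f"  {r['parent']} -> {r['child']}: diff={r['diff']:+.3f} "
                f"({direction}, p={p:.4g})"
            )
        lines.append(
            "note: edge directionality from observational BIC search is "
            "resolved only up to Markov equivalence and should be "
            "interpreted cautiously"
        )
    ci_path = out_dir / "ci_ttests.tsv"
    if ci_path.exists():
        df = pd.read_csv(ci_path, sep="\t")
        sig = df[df["p"] < run.alpha]
        lines.append(f"regions with CI group differences (p<{run.alpha}):")
        for _, r in sig.iterrows():
            lines.append(
                f"  {r['region']}: {r['mean_a']:.2f}±{r['sd_a']:.2f} vs "
                f"{r['mean_b']:.2f}±{r['sd_b']:.2f} (p={r['p']:.4g})"
            )
    report = out_dir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    _write_log(out_dir, "report", config_hash=_config_hash(run))
    return report


def run_all(
    cohort_config: CohortConfig, out_dir: "str | Path", run: RunConfig
) -> dict:
    """simulate → (optional preprocess) → learn → compare → report."""
    out_dir = Path(out_dir)
    cohort_dir = out_dir / "cohort"
    run_simulate(cohort_config, cohort_dir)
    analysis_input = cohort_dir
    if run.apply_detrend or run.apply_bandpass:
        analysis_input = out_dir / "preprocessed"
        run_preprocess(cohort_dir, analysis_input, run)
    results_dir = out_dir / "results"
    learned = run_learn(analysis_input, results_dir, run)
    compared = run_compare(analysis_input, results_dir, run, learned=learned)
    run_report(results_dir, run)
    return {"learned": learned, "compared": compared, "results_dir": results_dir}
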