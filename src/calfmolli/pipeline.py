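"""End-to-end cohort analysis: fit -> compartment metrics -> ECV -> statistics.

The subject-level flow mirrors the clinical analysis: fit pre- and
post-contrast T1 maps over the labeled voxels, extract peak/mean/min T1 and
cross-sectional area per muscle compartment and the averaged peak blood-pool
T1 over the arteries, average the two sides when both are available, then
compute per-compartment ECV and run the group-comparison and univariate
regression layers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ecv import cohort_ecv
from .phantom import CohortConfig, SubjectBundle, generate_cohort
from .roi import (ARTERIES, MUSCLE_COMPARTMENTS, RegionSet, bilateral_average,
                  blood_pool_t1, compartment_metrics)
from .stats import compare_groups, icc_two_way_average, univariate_regression
from .t1fit import FitOptions, InversionSeries, T1Map, fit_map

logger = logging.getLogger(__name__)

__all__ = [
    "analyze_subject_legs", "analyze_cohort", "group_comparison_table",
    "regression_tables", "intra_observer_icc", "run_pipeline", "RunConfig",
]

COVARIATES = ["abi_rest", "delta_abi", "cot_s", "pwt_s", "bmi", "egfr"]


def _labelled_mask(regions: RegionSet) -> np.ndarray:
    mask = np.zeros(next(iter(regions.labels.values())).shape, dtype=bool)
    for name in list(MUSCLE_COMPARTMENTS) + list(ARTERIES):
        if name in regions.labels:
            mask |= regions.labels[name]
    return mask


def fit_leg(
    pre: InversionSeries, post: InversionSeries, regions: RegionSet,
    options: FitOptions | None = None, fit_scope: str = "labels",
) -> tuple[T1Map, T1Map]:
    """Fit the pre- and post-contrast maps of one leg.

    ``fit_scope`` restricts fitting to the labeled compartments+arteries
    (default) or the whole leg outline (``"leg"``).
    """
    if fit_scope == "leg" and "leg" in regions.labels:
        mask = regions.labels["leg"] | _labelled_mask(regions)
    else:
        mask = _labelled_mask(regions)
    return fit_map(pre, mask, options), fit_map(post, mask, options)


def analyze_subject_legs(
    legs: dict[str, tuple[InversionSeries, InversionSeries, RegionSet]],
    options: FitOptions | None = None,
) -> tuple[list[dict], dict]:
    """Per-compartment metrics and blood-pool T1 for one subject.

    Returns (metric rows, blood row); when both sides are present the
    subject-level values are the bilateral averages and per-side rows are
    kept alongside (side = left/right/bilateral).
    """
    per_side: dict[str, dict] = {}
    blood_sides: dict[str, tuple[float, float]] = {}
    for side, (pre, post, regions) in legs.items():
        mpre, mpost = fit_leg(pre, post, regions, options)
        mets = {}
        for comp in MUSCLE_COMPARTMENTS:
            mets[comp] = (
                compartment_metrics(mpre, regions[comp], regions.pixel_spacing_mm, comp, side),
                compartment_metrics(mpost, regions[comp], regions.pixel_spacing_mm, comp, side),
            )
        bp_pre, _ = blood_pool_t1(mpre, regions)
        bp_post, _ = blood_pool_t1(mpost, regions)
        per_side[side] = mets
        blood_sides[side] = (bp_pre, bp_post)

    sides = sorted(per_side)
    rows: list[dict] = []

    def metric_row(pre_m, post_m, side):
        return {
            "compartment": pre_m.compartment, "side": side,
            "peak_t1_pre_ms": pre_m.peak_t1_ms, "mean_t1_pre_ms": pre_m.mean_t1_ms,
            "min_t1_pre_ms": pre_m.min_t1_ms,
            "peak_t1_post_ms": post_m.peak_t1_ms, "mean_t1_post_ms": post_m.mean_t1_ms,
            "min_t1_post_ms": post_m.min_t1_ms,
            "csa_mm2": pre_m.csa_mm2, "n_voxels": pre_m.n_voxels,
        }

    for comp in MUSCLE_COMPARTMENTS:
        for side in sides:
            rows.append(metric_row(*per_side[side][comp], side))
        if len(sides) == 2:
            pre_b = bilateral_average(per_side[sides[0]][comp][0], per_side[sides[1]][comp][0])
            post_b = bilateral_average(per_side[sides[0]][comp][1], per_side[sides[1]][comp][1])
            rows.append(metric_row(pre_b, post_b, "bilateral"))

    bp = np.mean([blood_sides[s] for s in sides], axis=0)
    blood = {"blood_t1_pre_ms": float(bp[0]), "blood_t1_post_ms": float(bp[1])}
    return rows, blood


def analyze_cohort(
    bundles: list[SubjectBundle],
    options: FitOptions | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the subject-level analysis over a cohort.

    Returns ``metrics`` (subject-level rows, bilateral where available),
    ``metrics_by_side`` (all rows), ``blood`` and ``subjects`` tables.
    """
    all_rows, blood_rows, subj_rows = [], [], []
    t0 = time.perf_counter()
    for b in bundles:
        rows, blood = analyze_subject_legs(b.legs, options)
        for r in rows:
            r.update(subject=b.subject, group=b.group)
        all_rows.extend(rows)
        blood_rows.append({"subject": b.subject, "group": b.group, **blood})
        subj_rows.append({"subject": b.subject, "group": b.group, **b.covariates})
    logger.info("analyzed %d subjects in %.1f s", len(bundles), time.perf_counter() - t0)
    metrics_by_side = pd.DataFrame(all_rows)
    subject_level = "bilateral" if (metrics_by_side["side"] == "bilateral").any() else metrics_by_side["side"].iloc[0]
    metrics = metrics_by_side[metrics_by_side["side"] == subject_level].reset_index(drop=True)
    return {
        "metrics": metrics,
        "metrics_by_side": metrics_by_side,
        "blood": pd.DataFrame(blood_rows),
        "subjects": pd.DataFrame(subj_rows),
    }


def _composites(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-subject five-compartment averages (peak/mean T1 pre, CSA)."""
    g = metrics.groupby(["subject", "group"])
    out = g.agg(avg_peak_t1_pre_ms=("peak_t1_pre_ms", "mean"),
                avg_mean_t1_pre_ms=("mean_t1_pre_ms", "mean"),
                avg_csa_mm2=("csa_mm2", "mean")).reset_index()
    return out


def group_comparison_table(
    metrics: pd.DataFrame, blood: pd.DataFrame, ecv: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Claudicant-vs-control comparisons of every imaging variable.

    One row per variable with the branch taken (t vs Mann-Whitney), the
    per-branch summaries and the p-value — the analysis plan behind the
    study's group-difference table.
    """
    rows = []

    def add(name, df, col):
        a = df.loc[df["group"] == "pad", col].to_numpy(dtype=float)
        b = df.loc[df["group"] == "control", col].to_numpy(dtype=float)
        c = compare_groups(a, b, alpha=alpha, variable=name)
        rows.append({
            "variable": name, "test": c.test_used,
            "pad_summary": c.summary_a, "control_summary": c.summary_b,
            "n_pad": c.n[0], "n_control": c.n[1],
            "p_value": c.p_value,
            "shapiro_p_pad": c.normality_p[0], "shapiro_p_control": c.normality_p[1],
        })

    add("Native peak T1 of composite arteries (ms)", blood, "blood_t1_pre_ms")
    comp_names = {"AM": "anterior muscle group", "LM": "lateral muscle group",
                  "DM": "deep posterior muscle group", "SM": "soleus muscle",
                  "GM": "gastrocnemius muscle"}
    for comp in MUSCLE_COMPARTMENTS:
        sub = metrics[metrics["compartment"] == comp]
        add(f"Cross-sectional area, {comp_names[comp]} (mm2)", sub, "csa_mm2")
    comps = _composites(metrics)
    add("Average cross-sectional area (mm2)", comps, "avg_csa_mm2")
    for comp in MUSCLE_COMPARTMENTS:
        sub = metrics[metrics["compartment"] == comp]
        add(f"Native peak T1, {comp_names[comp]} (ms)", sub, "peak_t1_pre_ms")
    for comp in MUSCLE_COMPARTMENTS:
        sub = metrics[metrics["compartment"] == comp]
        add(f"Minimum T1, {comp_names[comp]} (ms)", sub, "min_t1_pre_ms")
    add("Average cross-sectional native peak T1 (ms)", comps, "avg_peak_t1_pre_ms")
    add("Average cross-sectional mean T1 (ms)", comps, "avg_mean_t1_pre_ms")
    for comp in MUSCLE_COMPARTMENTS:
        sub = ecv[ecv["compartment"] == comp]
        add(f"ECV, {comp_names[comp]} (%)", sub, "ecv_percent")
    avg_ecv = ecv.groupby(["subject", "group"])["ecv_percent"].mean().reset_index()
    add("ECV, averaged over 5 muscle compartments (%)", avg_ecv, "ecv_percent")
    return pd.DataFrame(rows)


def regression_tables(
    metrics: pd.DataFrame, ecv: pd.DataFrame, subjects: pd.DataFrame,
) -> pd.DataFrame:
    """Pooled univariate regressions of imaging outcomes on clinical markers.

    One row per outcome x covariate with n, standardized beta, raw slope
    and SE, R², adjusted r² and p — the layout of the study's regression
    tables.
    """
    rows = []

    def add(outcome_name, df, col):
        merged = df.merge(subjects, on=["subject", "group"])
        for cov in COVARIATES:
            y = merged[col].to_numpy(dtype=float)
            x = merged[cov].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 3 or np.ptp(x[keep]) == 0:
                continue
            r = univariate_regression(y[keep], x[keep])
            rows.append({"outcome": outcome_name, "covariate": cov, "n": r.n,
                         "beta_std": r.beta_std, "slope_raw": r.slope_raw,
                         "slope_se": r.slope_se, "r2": r.r2,
                         "adj_r2": r.adj_r2, "p_value": r.p_value})

    for comp in MUSCLE_COMPARTMENTS:
        add(f"ECV, {comp} (%)", ecv[ecv["compartment"] == comp], "ecv_percent")
    for comp in MUSCLE_COMPARTMENTS:
        add(f"Native peak T1 of {comp} (ms)",
            metrics[metrics["compartment"] == comp], "peak_t1_pre_ms")
    comps = _composites(metrics)
    add("Native peak T1 averaged over all calf muscle compartments (ms)",
        comps, "avg_peak_t1_pre_ms")
    avg_ecv = ecv.groupby(["subject", "group"])["ecv_percent"].mean().reset_index()
    add("Mean ECV (averaged over all calf muscle compartments) (%)",
        avg_ecv, "ecv_percent")
    return pd.DataFrame(rows)


def intra_observer_icc(
    bundles: list[SubjectBundle],
    options: FitOptions | None = None,
    seed: int = 0,
    side: str = "right",
) -> pd.DataFrame:
    """Emulated repeat-tracing reliability of the compartment peak T1 and area.

    A second "tracing" of every muscle mask is produced by shifting the
    mask one voxel in a random direction (a coarse stand-in for manual
    re-delineation), the metrics are recomputed on the same native map,
    and the two tracings enter a two-way random-effects average-measures
    ICC per compartment.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, list[list[float]]] = {c: [] for c in MUSCLE_COMPARTMENTS}
    areas: dict[str, list[list[float]]] = {c: [] for c in MUSCLE_COMPARTMENTS}
    for b in bundles:
        use_side = side if side in b.legs else next(iter(b.legs))
        pre, post, regions = b.legs[use_side]
        mpre, _ = fit_leg(pre, post, regions, options)
        for comp in MUSCLE_COMPARTMENTS:
            m1 = compartment_metrics(mpre, regions[comp], regions.pixel_spacing_mm, comp)
            dy, dx = rng.choice([-1, 0, 1], size=2)
            shifted = np.roll(regions[comp], (dy, dx), axis=(0, 1))
            shifted &= mpre.valid
            if not shifted.any():
                shifted = regions[comp]
            m2 = compartment_metrics(mpre, shifted, regions.pixel_spacing_mm, comp)
            values[comp].append([m1.peak_t1_ms, m2.peak_t1_ms])
            areas[comp].append([m1.csa_mm2, m2.csa_mm2])
    rows = []
    for comp in MUSCLE_COMPARTMENTS:
        for label, mat in (("peak_t1", values[comp]), ("csa", areas[comp])):
            r = icc_two_way_average(np.asarray(mat))
            rows.append({"variable": f"{comp}_{label}", "icc": r.icc,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "excellent": r.excellent})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the end-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (see YAML keys of the CLI)."""

    output_dir: str = "calfmolli_out"
    seed: int = 0
    n_pad: int = 18
    n_control: int = 19
    grid_size: int = 64
    pixel_spacing_mm: float = 3.0
    snr: float = 50.0
    bilateral: bool = True
    use_mean_ecv: bool = False
    ll_correction: bool = False
    save_maps: bool = False
    run_icc: bool = True
    log_level: str = "INFO"
    extra: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort, run every analysis stage and write all artifacts.

    Outputs (CSV/JSON/text under ``config.output_dir``) are deterministic
    byte-for-byte under a fixed config and seed.  Returns the in-memory
    tables.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()

    stage("simulate")
    ccfg = CohortConfig(
        n_pad=config.n_pad, n_control=config.n_control,
        grid_size=config.grid_size, pixel_spacing_mm=config.pixel_spacing_mm,
        snr=config.snr, bilateral=config.bilateral, seed=config.seed,
    )
    bundles, truth = generate_cohort(ccfg)

    stage("fit+metrics")
    opts = FitOptions(ll_correction=config.ll_correction)
    res = analyze_cohort(bundles, opts)

    stage("ecv")
    ecv_df, n_excluded = cohort_ecv(res["metrics"], res["blood"], res["subjects"],
                                    use_mean=config.use_mean_ecv)

    stage("stats")
    comparisons = group_comparison_table(res["metrics"], res["blood"], ecv_df)
    regressions = regression_tables(res["metrics"], ecv_df, res["subjects"])
    icc_df = (intra_observer_icc(bundles, opts, seed=config.seed)
              if config.run_icc else pd.DataFrame())

    stage("write")
    from .io import ECV_COLUMNS, METRICS_COLUMNS, write_series, write_t1_map, write_table

    met = res["metrics_by_side"]
    write_table(out / "metrics.csv", met, METRICS_COLUMNS)
    write_table(out / "blood.csv", res["blood"])
    write_table(out / "subjects.csv", res["subjects"])
    write_table(out / "ecv.csv", ecv_df, ECV_COLUMNS)
    write_table(out / "ground_truth.csv", truth)
    write_table(out / "comparisons.csv", comparisons)
    write_table(out / "regressions.csv", regressions)
    if config.run_icc:
        write_table(out / "icc.csv", icc_df)
    if config.save_maps and bundles:
        side = next(iter(bundles[0].legs))
        pre, post, regions = bundles[0].legs[side]
        write_series(out / "example_pre.nii", pre)
        mpre, mpost = fit_leg(pre, post, regions, opts)
        write_t1_map(out / "example_t1_pre.nii", mpre)
        write_t1_map(out / "example_t1_post.nii", mpost)

    report = _text_report(comparisons, regressions, icc_df, n_excluded)
    (out / "report.txt").write_text(report)
    provenance = {
        "package": "calfmolli", "version": __version__,
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items() if k != "extra"},
        "n_subjects": len(bundles),
        "ecv_excluded_subjects": n_excluded,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    logger.info("wrote outputs to %s", out)
    return {"metrics": res["metrics"], "blood": res["blood"],
            "subjects": res["subjects"], "ecv": ecv_df, "truth": truth,
            "comparisons": comparisons, "regressions": regressions, "icc": icc_df}


def _text_report(comparisons, regressions, icc_df, n_excluded) -> str:
    lines = ["calfmolli cohort report", "=" * 23, "",
             "Group comparisons (claudicants vs controls)", "-" * 43]
    for _, r in comparisons.iterrows():
        lines.append(f"{r['variable']}: {r['pad_summary']} vs {r['control_summary']} "
                     f"[{r['test']}] p={r['p_value']:.3g}")
    lines += ["", f"Subjects excluded from ECV for missing inputs: {n_excluded}", "",
              "Univariate regressions (pooled)", "-" * 31]
    for _, r in regressions.iterrows():
        lines.append(f"{r['outcome']} ~ {r['covariate']}: beta={r['beta_std']:.3f} "
                     f"slope={r['slope_raw']:.4g} (SE {r['slope_se']:.4g}) "
                     f"R2={r['r2']:.3f} adjR2={r['adj_r2']:.3f} p={r['p_value']:.3g}")
    if len(icc_df):
        lines += ["", "Intra-observer ICC (emulated re-tracing)", "-" * 40]
        for _, r in icc_df.iterrows():
            lines.append(f"{r['variable']}: ICC={r['icc']:.3f} "
                         f"(95% CI {r['ci_low']:.3f}-{r['ci_high']:.3f})"
                         f"{' excellent' if r['excellent'] else ''}")
    return "\n".join(lines) + "\n"
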