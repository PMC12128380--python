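"""End-to-end orchestration: simulate -> quantify -> diagnose -> associate -> report.

Each stage reads and writes delimited tables in a run directory, so a
run is inspectable and resumable stage by stage; ``run_pipeline``
executes all of them and emits a machine-readable summary plus a run
manifest (config snapshot, seed, package version, stage timings and
SHA-256 digests of every artifact).  Every number in the summary is
recomputed from the persisted per-sample tables, never carried over
from in-memory state, so the report is traceable to its files.
"""
from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import GeneratorConfig, load_config
from .diagnostics import (
    DEFAULT_CUTOFF,
    auc_confidence,
    classify,
    confusion_at,
    roc_curve,
    youden_j,
)
from .exceptions import ConfigError, SpdefmethError
from .io import (
    cohort_frame,
    gel_frame,
    gel_from_frame,
    qpcr_frame,
    qpcr_from_frame,
    read_table,
    standards_frame,
    standards_from_frame,
    validate_input,
    write_table,
)
from .quantify import call_from_gel, call_from_qpcr, dc_ratio, fit_standard_curve
from .simulate import (
    simulate_cohort,
    simulate_gel,
    simulate_qpcr,
    simulate_standards,
)
from .stats import (
    GroupedValues,
    concordance_r2,
    dunn_posthoc,
    kruskal_wallis,
    linear_fit,
    mann_whitney_u,
    spearman,
)

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_quantify",
    "stage_diagnose",
    "stage_associate",
    "stage_report",
    "validate_input",
]


def _ext(fmt: str) -> str:
    return "csv" if fmt == "csv" else "tsv"


def _table(outdir: Path, name: str, fmt: str) -> Path:
    return outdir / f"{name}.{_ext(fmt)}"


def stage_simulate(config: GeneratorConfig, outdir: Path, fmt: str = "csv") -> None:
    """Generate and persist cohort, qPCR, gel and standards tables."""
    subjects = simulate_cohort(config)
    write_table(cohort_frame(subjects), _table(outdir, "cohort", fmt), fmt)
    write_table(
        qpcr_frame(simulate_qpcr(subjects, config)), _table(outdir, "qpcr", fmt), fmt
    )
    write_table(
        gel_frame(simulate_gel(subjects, config)), _table(outdir, "gel", fmt), fmt
    )
    write_table(
        standards_frame(simulate_standards(config)),
        _table(outdir, "standards", fmt),
        fmt,
    )


def stage_quantify(config: GeneratorConfig, outdir: Path, fmt: str = "csv") -> None:
    """Turn raw measurements into per-sample methylation calls.

    The calls table carries both assays on a common percent scale:
    qPCR (delta-Ct formula) and gel densitometry (inverted affine
    response), plus the classification at no particular cutoff — the
    diagnose stage applies the cutoff.
    """
    cohort = read_table(_table(outdir, "cohort", fmt), fmt)
    qpcr = qpcr_from_frame(read_table(_table(outdir, "qpcr", fmt), fmt))
    gel = gel_from_frame(read_table(_table(outdir, "gel", fmt), fmt))
    groups = dict(zip(cohort["sample_id"], cohort["group"]))
    gel_by_id = {g.sample_id: g for g in gel}
    rows = []
    for m in qpcr:
        call = call_from_qpcr(m)
        g = gel_by_id.get(m.sample_id)
        ratio = dc_ratio(g) if g is not None else np.nan
        gel_call = (
            call_from_gel(g, config.gel_alpha, config.gel_beta) if g is not None else None
        )
        rows.append(
            {
                "sample_id": m.sample_id,
                "group": groups.get(m.sample_id, ""),
                "delta_ct": call.delta_ct,
                "methylation_pct": call.methylation_pct,
                "hypomethylation_pct": call.hypomethylation_pct,
                "below_detection": int(call.below_detection),
                "dc_ratio": ratio,
                "gel_methylation_pct": (
                    gel_call.methylation_pct if gel_call else np.nan
                ),
            }
        )
    write_table(pd.DataFrame(rows), _table(outdir, "calls", fmt), fmt)

    standards = standards_from_frame(read_table(_table(outdir, "standards", fmt), fmt))
    fit = fit_standard_curve(standards)
    curve = pd.DataFrame(
        [
            {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "zero_control_capped": (
                    "" if fit.zero_control_capped is None else int(fit.zero_control_capped)
                ),
            }
        ]
    )
    write_table(curve, _table(outdir, "standard_curve", fmt), fmt)


def stage_diagnose(
    outdir: Path, cutoff: float = DEFAULT_CUTOFF, fmt: str = "csv"
) -> None:
    """ROC threshold sweep and the fixed-cutoff operating point."""
    calls = read_table(_table(outdir, "calls", fmt), fmt)
    scores = calls["methylation_pct"].to_numpy()
    labels = ["positive" if g == "PCa" else "negative" for g in calls["group"]]
    roc = roc_curve(scores, labels)
    sweep = pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    )
    write_table(sweep, _table(outdir, "roc", fmt), fmt)
    se, lo, hi = auc_confidence(roc, method="hanley-mcneil")
    conf = confusion_at(scores, labels, cutoff)
    thr_j, j = youden_j(roc)
    summary = pd.DataFrame(
        [
            {
                "cutoff": cutoff,
                "auc": roc.auc,
                "auc_se": se,
                "auc_ci95_low": lo,
                "auc_ci95_high": hi,
                "tp": conf.tp,
                "fp": conf.fp,
                "tn": conf.tn,
                "fn": conf.fn,
                "sensitivity": conf.sensitivity,
                "specificity": conf.specificity,
                "ppv": conf.ppv,
                "npv": conf.npv,
                "accuracy": conf.accuracy,
                "youden_threshold": thr_j,
                "youden_j": j,
            }
        ]
    )
    write_table(summary, _table(outdir, "diagnostics_summary", fmt), fmt)


def _assoc_row(analysis, method, stat_name, stat, p, n):
    return {
        "analysis": analysis,
        "method": method,
        "statistic_name": stat_name,
        "statistic": stat,
        "p_value": p,
        "n": n,
    }


def stage_associate(outdir: Path, fmt: str = "csv") -> None:
    """Association statistics between methylation and clinical variables."""
    cohort = read_table(_table(outdir, "cohort", fmt), fmt)
    calls = read_table(_table(outdir, "calls", fmt), fmt)
    df = cohort.merge(calls, on=["sample_id", "group"])
    rows = []

    pca = df[df["group"] == "PCa"]
    bph = df[df["group"] == "BPH"]
    mwu = mann_whitney_u(
        pca["hypomethylation_pct"], bph["hypomethylation_pct"]
    )
    rows.append(_assoc_row("group_comparison", "qPCR", "U", mwu.statistic,
                           mwu.p_value, mwu.n))

    # pooled PSA vs methylation, both assays
    for method, col in (("qPCR", "methylation_pct"), ("MSRE-PCR", "gel_methylation_pct")):
        sp = spearman(df["tpsa"], df[col])
        rows.append(_assoc_row("psa_methylation", method, "spearman_rho",
                               sp.statistic, sp.p_value, sp.n))

    # age / prostate weight within the cancer group (no coupling expected)
    for var in ("age", "prostate_weight"):
        sp = spearman(pca[var], pca["hypomethylation_pct"])
        rows.append(_assoc_row(f"{var}_hypomethylation", "qPCR", "spearman_rho",
                               sp.statistic, sp.p_value, sp.n))

    # ordinal clinical strata (stratified-mode cohorts only)
    for var in ("stage", "grade"):
        sub = pca[pca[var].notna() & (pca[var].astype(str) != "")]
        if sub.empty:
            continue
        order = sorted(sub[var].astype(str).unique())
        grouped = GroupedValues(
            labels=order,
            values=[
                sub.loc[sub[var].astype(str) == lab, "hypomethylation_pct"].to_numpy()
                for lab in order
            ],
        )
        kw = kruskal_wallis(grouped)
        rows.append(_assoc_row(f"{var}_omnibus", "qPCR", "kruskal_wallis_H",
                               kw.statistic, kw.p_value, kw.n))
        dunn = dunn_posthoc(grouped)
        for comp in dunn.comparisons:
            rows.append(
                _assoc_row(
                    f"{var}_dunn_{comp.pair[0]}_vs_{comp.pair[1]}",
                    "qPCR", "z", comp.statistic, comp.p_adjusted, kw.n,
                )
            )
        ordinal = sub[var].astype(str).map({lab: i + 1 for i, lab in enumerate(order)})
        fit = linear_fit(ordinal, sub["hypomethylation_pct"])
        rows.append(_assoc_row(f"{var}_regression", "qPCR", "r", fit.r,
                               fit.p_value, fit.n))
        sp = spearman(ordinal, sub["hypomethylation_pct"])
        rows.append(_assoc_row(f"{var}_rank_correlation", "qPCR", "spearman_rho",
                               sp.statistic, sp.p_value, sp.n))

    # method concordance
    r2 = concordance_r2(df["methylation_pct"], df["gel_methylation_pct"])
    rows.append(_assoc_row("method_concordance", "qPCR~MSRE-PCR", "r_squared",
                           r2, np.nan, len(df)))
    write_table(pd.DataFrame(rows), _table(outdir, "associations", fmt), fmt)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_report(
    config: GeneratorConfig,
    outdir: Path,
    cutoff: float,
    fmt: str,
    timings: Optional[dict[str, float]] = None,
) -> tuple[dict, dict]:
    """Assemble summary.json and manifest.json from persisted tables."""
    calls = read_table(_table(outdir, "calls", fmt), fmt)
    diag = read_table(_table(outdir, "diagnostics_summary", fmt), fmt).iloc[0]
    curve = read_table(_table(outdir, "standard_curve", fmt), fmt).iloc[0]
    assoc = read_table(_table(outdir, "associations", fmt), fmt)

    groups = {}
    for g, sub in calls.groupby("group"):
        groups[g] = {
            "n": int(len(sub)),
            "methylation_mean": round(float(sub["methylation_pct"].mean()), 4),
            "methylation_sd": round(float(sub["methylation_pct"].std(ddof=1)), 4),
            "hypomethylation_mean": round(float(sub["hypomethylation_pct"].mean()), 4),
            "hypomethylation_sd": round(float(sub["hypomethylation_pct"].std(ddof=1)), 4),
            "dc_ratio_mean": round(float(sub["dc_ratio"].mean()), 4),
            "dc_ratio_sd": round(float(sub["dc_ratio"].std(ddof=1)), 4),
            "complete_hypomethylation_n": int((sub["below_detection"] == 1).sum()),
        }

    summary = {
        "groups": groups,
        "diagnostics": {
            "cutoff": float(diag["cutoff"]),
            "auc": float(diag["auc"]),
            "auc_se": float(diag["auc_se"]),
            "auc_ci95": [float(diag["auc_ci95_low"]), float(diag["auc_ci95_high"])],
            "sensitivity": float(diag["sensitivity"]),
            "specificity": float(diag["specificity"]),
            "confusion": {k: int(diag[k]) for k in ("tp", "fp", "tn", "fn")},
        },
        "standard_curve": {
            "slope": float(curve["slope"]),
            "intercept": float(curve["intercept"]),
            "r_squared": float(curve["r_squared"]),
            "n_points": int(curve["n_points"]),
        },
        "associations": assoc.to_dict(orient="records"),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )

    artifacts = sorted(
        p.name for p in outdir.iterdir() if p.suffix in (".csv", ".tsv", ".json")
        and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "cutoff": cutoff,
        "format": fmt,
        "config": config.model_dump(mode="json"),
        "digests": {name: _sha256(outdir / name) for name in artifacts},
        "timings_s": timings or {},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return summary, manifest


def run_pipeline(
    config: GeneratorConfig | str | Path,
    outdir: str | Path,
    cutoff: float = DEFAULT_CUTOFF,
    fmt: str = "csv",
) -> tuple[dict, dict]:
    """Execute all stages; on failure remove partial outputs and re-raise."""
    if not isinstance(config, GeneratorConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pre_existing = set(outdir.iterdir())
    timings: dict[str, float] = {}
    stages = [
        ("simulate", lambda: stage_simulate(config, outdir, fmt)),
        ("quantify", lambda: stage_quantify(config, outdir, fmt)),
        ("diagnose", lambda: stage_diagnose(outdir, cutoff, fmt)),
        ("associate", lambda: stage_associate(outdir, fmt)),
    ]
    try:
        for name, fn in stages:
            t0 = time.perf_counter()
            fn()
            timings[name] = round(time.perf_counter() - t0, 4)
        return stage_report(config, outdir, cutoff, fmt, timings)
    except Exception:
        for p in set(outdir.iterdir()) - pre_existing:
            if p.is_file():
                p.unlink()
        raise
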