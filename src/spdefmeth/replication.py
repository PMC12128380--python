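"""Multi-seed replication of the study's headline statistics.

Runs the full object-level pipeline (cohort -> measurements -> calls ->
diagnostics/associations) across many seeds and averages, which is how
the package's recovered statistics are compared with the reference
assay's printed values.  Used by the analysis drivers and the
acceptance script; kept in the library so the numbers are computed one
way only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GeneratorConfig, default_config
from .diagnostics import DEFAULT_CUTOFF, confusion_at, roc_curve
from .quantify import (
    call_from_gel,
    call_from_qpcr,
    dc_ratio,
    fit_standard_curve,
)
from .simulate import (
    simulate_cohort,
    simulate_gel,
    simulate_qpcr,
    simulate_standards,
)
from .stats import concordance_r2, linear_fit, spearman

__all__ = [
    "GroupModeReplication",
    "StratifiedReplication",
    "replicate_group_mode",
    "replicate_stratified",
    "replicate_standard_curve",
    "seeds_from",
]


def seeds_from(base_seed: int, n: int) -> list[int]:
    """n distinct stream seeds derived from one base seed (all < 2^31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class GroupModeReplication:
    pca_hypomethylation_mean: float
    bph_hypomethylation_mean: float
    sensitivity_pct: float
    specificity_pct: float
    auc: float
    dc_ratio_pca_mean: float
    dc_ratio_bph_mean: float
    concordance_r2: float
    psa_spearman_pooled: float
    n_seeds: int
    n_subjects: int


@dataclass
class StratifiedReplication:
    stage_regression_r: float
    grade_regression_r: float
    n_seeds: int
    n_subjects: int


def _one_group_mode(config: GeneratorConfig, cutoff: float) -> list[float]:
    subjects = simulate_cohort(config)
    calls = [call_from_qpcr(m) for m in simulate_qpcr(subjects, config)]
    gels = simulate_gel(subjects, config)
    meth = np.array([c.methylation_pct for c in calls])
    hypo = 100.0 - meth
    groups = np.array([s.group for s in subjects])
    labels = ["positive" if g == "PCa" else "negative" for g in groups]
    pca, bph = groups == "PCa", groups == "BPH"
    conf = confusion_at(meth, labels, cutoff)
    roc = roc_curve(meth, labels)
    ratios = np.array([dc_ratio(g) for g in gels])
    gel_meth = np.array(
        [
            call_from_gel(g, config.gel_alpha, config.gel_beta).methylation_pct
            for g in gels
        ]
    )
    psa = np.array([s.tpsa for s in subjects])
    return [
        float(hypo[pca].mean()),
        float(hypo[bph].mean()),
        100.0 * conf.sensitivity,
        100.0 * conf.specificity,
        roc.auc,
        float(ratios[pca].mean()),
        float(ratios[bph].mean()),
        concordance_r2(meth, gel_meth),
        spearman(psa, meth).statistic,
    ]


def replicate_group_mode(
    base_seed: int,
    n_seeds: int = 100,
    cutoff: float = DEFAULT_CUTOFF,
    config: GeneratorConfig | None = None,
) -> GroupModeReplication:
    """Average the group-mode diagnostic surface over ``n_seeds`` cohorts."""
    template = config if config is not None else default_config()
    rows = []
    for seed in seeds_from(base_seed, n_seeds):
        cfg = template.model_copy(update={"seed": seed, "mode": "group"})
        rows.append(_one_group_mode(cfg, cutoff))
    mean = np.mean(rows, axis=0)
    return GroupModeReplication(
        *[float(v) for v in mean],
        n_seeds=n_seeds,
        n_subjects=template.n_pca + template.n_bph,
    )


def replicate_stratified(
    base_seed: int,
    n_seeds: int = 100,
    config: GeneratorConfig | None = None,
) -> StratifiedReplication:
    """Stage/grade ordinal regression r over stratified-mode PCa cohorts."""
    template = config if config is not None else default_config()
    r_stage, r_grade = [], []
    for seed in seeds_from(base_seed, n_seeds):
        cfg = template.model_copy(update={"seed": seed, "mode": "stratified"})
        subjects = [s for s in simulate_cohort(cfg) if s.group == "PCa"]
        calls = [call_from_qpcr(m) for m in simulate_qpcr(subjects, cfg)]
        hypo = np.array([c.hypomethylation_pct for c in calls])
        stage_order = cfg.stage_labels()
        grade_order = cfg.grade_labels()
        stage = [stage_order.index(s.stage) + 1 for s in subjects]
        grade = [grade_order.index(s.grade) + 1 for s in subjects]
        r_stage.append(linear_fit(stage, hypo).r)
        r_grade.append(linear_fit(grade, hypo).r)
    return StratifiedReplication(
        stage_regression_r=float(np.mean(r_stage)),
        grade_regression_r=float(np.mean(r_grade)),
        n_seeds=n_seeds,
        n_subjects=template.n_pca,
    )


def replicate_standard_curve(
    base_seed: int,
    n_seeds: int = 1000,
    levels=(25.0, 50.0, 75.0, 100.0),
    config: GeneratorConfig | None = None,
) -> tuple[float, int]:
    """Median R² of the standard curve over ``n_seeds`` simulated runs."""
    template = config if config is not None else default_config()
    r2 = []
    for seed in seeds_from(base_seed, n_seeds):
        cfg = template.model_copy(update={"seed": seed})
        fit = fit_standard_curve(simulate_standards(cfg, levels=levels))
        r2.append(fit.r_squared)
    return float(np.median(r2)), n_seeds
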