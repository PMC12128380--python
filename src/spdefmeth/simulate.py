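"""Synthetic cohort, qPCR, gel and calibration-standard simulation.

The generator emulates a two-arm diagnostic study: prostate-cancer (PCa)
cases versus benign prostatic hyperplasia (BPH) controls, each subject
carrying a latent true methylated fraction ``m`` at one promoter CpG
site.  Measurements are then produced by explicit forward models:

* qPCR: undigested Ct ~ baseline + noise; digested Ct ~ baseline
  - ln(m)/0.7 + noise, capped at the detection limit (m = 0 never
  amplifies).  The expected delta-Ct is therefore -ln(m)/0.7, the exact
  inverse of the quantification formula, so the pipeline is consistent
  by construction and measurement error enters only through Ct noise.
* gel densitometry: expected D/C band-intensity ratio is affine in m,
  clipped to [0, 1.2], with its own noise.

Group mode draws ``m`` per group from a two-component mixture: a core
truncated normal on the correct side of the 55% diagnostic cutoff plus
a small contamination component just across it, which is what lets a
near-perfect AUC coexist with 177/180 sensitivity and specificity.
Stratified mode instead assigns PCa subjects to tumor-stage and ISUP
grade strata with fixed counts and draws hypomethylation around a
weighted blend of the two stratum means.

All randomness flows from ``config.seed`` through fixed per-stage
substreams, so adding a stage never perturbs earlier stages' draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps
from scipy.optimize import brentq

from .config import GeneratorConfig
from .exceptions import ConfigError
from .quantify import (
    DCT_COEFFICIENT,
    CalibrationStandard,
    GelMeasurement,
    QpcrMeasurement,
)

__all__ = [
    "Subject",
    "simulate_cohort",
    "simulate_qpcr",
    "simulate_gel",
    "simulate_standards",
]

# Fixed substream keys: appending new stages must never shift the draws
# of existing ones.
_STREAM_COHORT = 0
_STREAM_QPCR = 1
_STREAM_GEL = 2
_STREAM_STANDARDS = 3

# Support of the core methylation components (% scale): PCa strictly
# below the 55% cutoff with margin, BPH strictly above it.
_PCA_CORE_BOUNDS = (0.0, 50.0)
_BPH_CORE_BOUNDS = (60.0, 100.0)
_CUTOFF = 55.0

_AGE_BOUNDS = (40.0, 100.0)
_WEIGHT_BOUNDS = (1.0, 200.0)


@dataclass
class Subject:
    """One simulated participant."""

    id: str
    group: str  # "PCa" or "BPH"
    true_meth: float  # methylated fraction in [0, 1]
    tpsa: float  # ng/mL
    age: float  # years
    prostate_weight: float  # grams
    stage: Optional[str] = None
    grade: Optional[str] = None
    is_contaminant: bool = False


def _stage_rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


@lru_cache(maxsize=256)
def _solve_trunc_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of the underlying normal whose [lo, hi]-truncation has the
    requested mean.  The truncated mean is strictly increasing in the
    location, so a bracketed root always exists when the target is
    interior to (lo, hi)."""
    if sd == 0:
        return target_mean
    if not (lo < target_mean < hi):
        raise ConfigError(
            f"truncated-normal target mean {target_mean} outside support ({lo}, {hi})"
        )

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return _sps.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return brentq(gap, lo - 12 * sd, hi + 12 * sd, xtol=1e-10)


def _draw_trunc(
    n: int, loc: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, loc)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return _sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def _draw_group_meth(
    config: GeneratorConfig, group: str, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Group-mode methylation draw (% scale) with contamination flags.

    Exactly round(contamination_fraction * n) subjects are contaminants.
    """
    if group == "PCa":
        mean, sd = config.pca_meth
        lo, hi = _PCA_CORE_BOUNDS
        c_center = config.contamination_center[0]
        c_lo, c_hi = _CUTOFF, 100.0
    else:
        mean, sd = config.bph_meth
        lo, hi = _BPH_CORE_BOUNDS
        c_center = config.contamination_center[1]
        c_lo, c_hi = 0.0, _CUTOFF
    k = int(round(config.contamination_fraction * n))
    loc = _solve_trunc_loc(mean, sd, lo, hi)
    core = _draw_trunc(n - k, loc, sd, lo, hi, rng)
    contam = _draw_trunc(k, c_center, config.contamination_sd, c_lo, c_hi, rng)
    meth = np.concatenate([core, contam])
    flags = np.r_[np.zeros(n - k, dtype=bool), np.ones(k, dtype=bool)]
    return meth, flags


def _lognormal_params(median: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal from its median and standard deviation."""
    if median <= 0:
        raise ConfigError("lognormal median must be positive")
    mu = math.log(median)
    ratio = sd**2 / median**2
    u = (1.0 + math.sqrt(1.0 + 4.0 * ratio)) / 2.0  # u = exp(sigma^2)
    return mu, math.sqrt(math.log(u))


def _draw_psa(
    meth: np.ndarray,
    median: float,
    sd: float,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lognormal PSA coupled to the methylation *rank* via a Gaussian
    copula: the normal score of each subject's within-group methylation
    rank is mixed with fresh noise at correlation ``rho``, then pushed
    through the lognormal quantile function.  Marginals stay exact."""
    mu, sigma = _lognormal_params(median, sd)
    n = len(meth)
    scores = _sps.norm.ppf((_sps.rankdata(meth) - 0.5) / n)
    z = rho * scores + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    return np.exp(mu + sigma * z)


def _stratified_pca_meth(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stage/grade assignment and methylation for stratified-mode PCa.

    Stage and grade strata are filled comonotonically (subjects sorted
    by disease severity receive both labels in the same order), which is
    the maximal-agreement coupling consistent with both marginal count
    tables.  Expected hypomethylation blends the stage and grade stratum
    means; residual spread is ``within_stratum_sd``, clipped to [0, 100]
    so that the most advanced strata saturate at complete
    hypomethylation (methylated fraction 0).
    """
    stages = [s for s in config.stage_table for _ in range(s.count)]
    grades = [g for g in config.grade_table for _ in range(g.count)]
    h_stage = np.array([s.hypomethylation_mean for s in stages])
    h_grade = np.array([g.hypomethylation_mean for g in grades])
    w = config.stage_grade_weight
    hypo = w * h_stage + (1.0 - w) * h_grade
    hypo = hypo + rng.normal(0.0, config.within_stratum_sd, len(hypo))
    hypo = np.clip(hypo, 0.0, 100.0)
    meth = 100.0 - hypo
    return meth, [s.label for s in stages], [g.label for g in grades]


def simulate_cohort(config: GeneratorConfig) -> list[Subject]:
    """Draw the full two-group cohort of ``n_pca + n_bph`` subjects."""
    if config.n_pca <= 0 or config.n_bph <= 0:
        raise ConfigError("group sizes must be positive")
    rng = _stage_rng(config, _STREAM_COHORT)
    subjects: list[Subject] = []
    for group, n in (("PCa", config.n_pca), ("BPH", config.n_bph)):
        stages: list[Optional[str]] = [None] * n
        grades: list[Optional[str]] = [None] * n
        if group == "PCa" and config.mode == "stratified":
            meth, stages, grades = _stratified_pca_meth(config, rng)
            flags = np.zeros(n, dtype=bool)
        else:
            meth, flags = _draw_group_meth(config, group, n, rng)
        params = "pca" if group == "PCa" else "bph"
        psa = _draw_psa(
            meth,
            *getattr(config.psa_params, params),
            config.psa_copula_rho,
            rng,
        )
        age_m, age_sd = getattr(config.age_params, params)
        wt_m, wt_sd = getattr(config.weight_params, params)
        age = _draw_trunc(n, age_m, age_sd, *_AGE_BOUNDS, rng)
        weight = _draw_trunc(n, wt_m, wt_sd, *_WEIGHT_BOUNDS, rng)
        for i in range(n):
            subjects.append(
                Subject(
                    id=f"{group}-{i + 1:04d}",
                    group=group,
                    true_meth=float(meth[i]) / 100.0,
                    tpsa=float(psa[i]),
                    age=float(age[i]),
                    prostate_weight=float(weight[i]),
                    stage=stages[i],
                    grade=grades[i],
                    is_contaminant=bool(flags[i]),
                )
            )
    return subjects


def _forward_ct_pair(
    m: float,
    config: GeneratorConfig,
    replicates: int,
    rng: np.random.Generator,
) -> tuple[list[float], list[float], list[bool]]:
    """One sample's replicate Ct pairs under the forward model."""
    und = config.ct_baseline + rng.normal(0.0, config.ct_noise_sd, replicates)
    if m <= 0.0:
        dig = np.full(replicates, config.ct_cap)
        capped = [True] * replicates
    else:
        raw = (
            config.ct_baseline
            - math.log(m) / DCT_COEFFICIENT
            + rng.normal(0.0, config.ct_noise_sd, replicates)
        )
        capped = list(raw >= config.ct_cap)
        dig = np.minimum(raw, config.ct_cap)
    return list(dig), list(und), capped


def simulate_qpcr(
    subjects: Sequence[Subject],
    config: GeneratorConfig,
    replicates: int = 2,
) -> list[QpcrMeasurement]:
    """Duplicate (by default) digested/undigested Ct pairs per subject."""
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    rng = _stage_rng(config, _STREAM_QPCR)
    out = []
    for s in subjects:
        dig, und, capped = _forward_ct_pair(s.true_meth, config, replicates, rng)
        out.append(
            QpcrMeasurement(
                sample_id=s.id,
                ct_digested=dig,
                ct_undigested=und,
                capped_digested=capped,
            )
        )
    return out


def simulate_gel(
    subjects: Sequence[Subject], config: GeneratorConfig
) -> list[GelMeasurement]:
    """Band intensities with an affine-in-m expected D/C ratio.

    The undigested reference intensity is drawn from a positive
    lognormal (densitometry units are arbitrary; only the ratio
    carries signal), and the digested intensity is ratio x reference.
    """
    rng = _stage_rng(config, _STREAM_GEL)
    out = []
    for s in subjects:
        ratio = float(
            np.clip(
                config.gel_beta
                + config.gel_alpha * s.true_meth
                + rng.normal(0.0, config.gel_noise_sd),
                0.0,
                1.2,
            )
        )
        reference = float(np.exp(np.log(1000.0) + 0.1 * rng.standard_normal()))
        out.append(
            GelMeasurement(
                sample_id=s.id,
                intensity_digested=ratio * reference,
                intensity_undigested=reference,
            )
        )
    return out


def simulate_standards(
    config: GeneratorConfig,
    levels: Sequence[float] = (0.0, 25.0, 50.0, 75.0, 100.0),
    replicates: int = 2,
) -> list[CalibrationStandard]:
    """Calibration standards through the same forward model as samples."""
    if any(not (0.0 <= lv <= 100.0) for lv in levels):
        raise ConfigError("standard levels must lie in [0, 100] %")
    rng = _stage_rng(config, _STREAM_STANDARDS)
    out = []
    for lv in levels:
        dig, und, capped = _forward_ct_pair(lv / 100.0, config, replicates, rng)
        out.append(
            CalibrationStandard(
                nominal_meth=float(lv),
                ct_digested=dig,
                ct_undigested=und,
                capped_digested=capped,
            )
        )
    return out
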