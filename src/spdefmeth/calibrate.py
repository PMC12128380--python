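"""Moment-matching calibration of the synthetic-data generator.

``calibrate_generator`` adjusts one generator knob per named target so
that large-sample simulated *pipeline outputs* (not latent parameters)
hit requested values: measured group hypomethylation means, gel D/C
means, method-concordance R², the pooled PSA-methylation Spearman, and
the stratified-mode stage/grade regression coefficients.  Each target
is controlled by a single monotone knob, so bounded bisection on a
fixed-seed Monte-Carlo evaluation converges deterministically; an
unreachable target raises ``CalibrationError`` naming it rather than
looping forever.

The defaults shipped in ``GeneratorConfig`` are the output of this
routine run against the published group statistics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import stats as _sps

from .config import GeneratorConfig
from .exceptions import CalibrationError
from .quantify import DCT_COEFFICIENT
from .simulate import _draw_group_meth, _draw_psa, _stratified_pca_meth

__all__ = ["calibrate_generator", "CalibrationReport", "SUPPORTED_TARGETS"]

_EVAL_SEED_OFFSET = 424243  # fixed internal stream; keeps evaluation deterministic


@dataclass
class CalibrationReport:
    """Achieved value per target after calibration."""

    achieved: dict[str, float] = field(default_factory=dict)
    adjusted: dict[str, float] = field(default_factory=dict)  # knob -> new value


def _eval_rng(config: GeneratorConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(config.seed + _EVAL_SEED_OFFSET) % (2**31),
                               spawn_key=(salt,))
    )


def _measure_meth(m_frac: np.ndarray, config: GeneratorConfig,
                  rng: np.random.Generator, replicates: int = 2) -> np.ndarray:
    """Vectorized qPCR measurement of methylation % for an array of m."""
    n = len(m_frac)
    und = config.ct_baseline + rng.normal(0, config.ct_noise_sd, (n, replicates))
    with np.errstate(divide="ignore"):
        ideal = config.ct_baseline - np.log(m_frac)[:, None] / DCT_COEFFICIENT
    dig = np.minimum(ideal + rng.normal(0, config.ct_noise_sd, (n, replicates)),
                     config.ct_cap)
    dct = dig.mean(axis=1) - und.mean(axis=1)
    return np.clip(100.0 * np.exp(-DCT_COEFFICIENT * dct), 0.0, 100.0)


def _group_hypometh(config: GeneratorConfig, group: str, n: int) -> float:
    rng = _eval_rng(config, 1 if group == "PCa" else 2)
    meth, _ = _draw_group_meth(config, group, n, rng)
    measured = _measure_meth(meth / 100.0, config, rng)
    return float(np.mean(100.0 - measured))


def _dc_mean(config: GeneratorConfig, group: str, n: int) -> float:
    rng = _eval_rng(config, 3 if group == "PCa" else 4)
    meth, _ = _draw_group_meth(config, group, n, rng)
    ratio = np.clip(
        config.gel_beta + config.gel_alpha * meth / 100.0
        + rng.normal(0, config.gel_noise_sd, n),
        0.0, 1.2,
    )
    return float(np.mean(ratio))


def _concordance(config: GeneratorConfig, n: int) -> float:
    rng = _eval_rng(config, 5)
    mp, _ = _draw_group_meth(config, "PCa", n // 2, rng)
    mb, _ = _draw_group_meth(config, "BPH", n // 2, rng)
    m = np.concatenate([mp, mb]) / 100.0
    qpcr = _measure_meth(m, config, rng)
    ratio = np.clip(
        config.gel_beta + config.gel_alpha * m
        + rng.normal(0, config.gel_noise_sd, len(m)),
        0.0, 1.2,
    )
    gel = np.clip((ratio - config.gel_beta) / config.gel_alpha * 100.0, 0.0, 100.0)
    r = np.corrcoef(qpcr, gel)[0, 1]
    return float(r * r)


def _pooled_spearman(config: GeneratorConfig, n_rep: int = 30) -> float:
    """Pooled PSA-methylation Spearman at the configured cohort size,
    averaged over replications (the pooled statistic depends on the
    group-size balance, so it is evaluated at the real n)."""
    out = []
    for k in range(n_rep):
        rng = _eval_rng(config, 100 + k)
        vals = []
        for group, n in (("PCa", config.n_pca), ("BPH", config.n_bph)):
            meth, _ = _draw_group_meth(config, group, n, rng)
            key = "pca" if group == "PCa" else "bph"
            psa = _draw_psa(meth, *getattr(config.psa_params, key),
                            config.psa_copula_rho, rng)
            vals.append((meth, psa))
        meth = np.concatenate([v[0] for v in vals])
        psa = np.concatenate([v[1] for v in vals])
        out.append(_sps.spearmanr(psa, meth)[0])
    return float(np.mean(out))


def _strat_r(config: GeneratorConfig, which: str, n_rep: int = 30) -> float:
    out = []
    for k in range(n_rep):
        rng = _eval_rng(config, 200 + k)
        meth, stages, grades = _stratified_pca_meth(config, rng)
        measured_h = 100.0 - _measure_meth(meth / 100.0, config, rng)
        labels = stages if which == "stage" else grades
        order = (config.stage_labels() if which == "stage"
                 else config.grade_labels())
        ordinal = np.array([order.index(l) + 1 for l in labels], dtype=float)
        out.append(_sps.pearsonr(ordinal, measured_h)[0])
    return float(np.mean(out))


def _bisect_knob(
    evaluate: Callable[[float], float],
    target: float,
    lo: float,
    hi: float,
    tol: float,
    target_name: str,
    max_iter: int = 40,
) -> tuple[float, float]:
    """Monotone bounded bisection; raises if the target is unreachable."""
    f_lo, f_hi = evaluate(lo), evaluate(hi)
    sign = 1.0 if f_hi >= f_lo else -1.0
    lo_val, hi_val = min(f_lo, f_hi), max(f_lo, f_hi)
    if not (lo_val - tol <= target <= hi_val + tol):
        raise CalibrationError(
            f"target '{target_name}'={target} unreachable within knob bounds "
            f"[{lo}, {hi}] (achievable range [{lo_val:.4g}, {hi_val:.4g}])"
        )
    a, b = lo, hi
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        val = evaluate(mid)
        if abs(val - target) <= tol:
            return mid, val
        if sign * (val - target) < 0:
            a = mid
        else:
            b = mid
    return mid, val


# target name -> (knob description used in the report)
SUPPORTED_TARGETS = {
    "pca_hypomethylation_mean": "pca_meth mean",
    "bph_hypomethylation_mean": "bph_meth mean",
    "dc_ratio_pca_mean": "gel_alpha/gel_beta",
    "dc_ratio_bph_mean": "gel_alpha/gel_beta",
    "concordance_r2": "gel_noise_sd",
    "psa_spearman_pooled": "psa_copula_rho",
    "stage_regression_r": "within_stratum_sd",
    "grade_regression_r": "stage_grade_weight",
}


def calibrate_generator(
    config: GeneratorConfig,
    targets: Mapping[str, float],
    tolerance: float = 0.02,
    n_eval: int = 10_000,
) -> tuple[GeneratorConfig, CalibrationReport]:
    """Return a config whose simulated large-sample moments hit ``targets``.

    ``tolerance`` is a fraction: unit-scale targets (correlations,
    ratios, R²) are matched to ``tolerance`` absolute, percent-scale
    targets to ``100 * tolerance`` percent points.  Targets already met
    are left untouched (fixed point).  Deterministic given
    ``config.seed``.
    """
    unknown = set(targets) - set(SUPPORTED_TARGETS)
    if unknown:
        raise CalibrationError(f"unsupported calibration targets: {sorted(unknown)}")
    cfg = config.model_copy(deep=True)
    report = CalibrationReport()

    def tol_for(name: str) -> float:
        # percent-scale quantities get the tolerance in percent points
        return 100.0 * tolerance if name.endswith("hypomethylation_mean") else tolerance

    # --- gel affine response: exact two-point solve, no search needed ---
    if "dc_ratio_pca_mean" in targets or "dc_ratio_bph_mean" in targets:
        if not ("dc_ratio_pca_mean" in targets and "dc_ratio_bph_mean" in targets):
            raise CalibrationError(
                "dc_ratio targets must be given for both groups (two-point solve)"
            )
        m_pca = cfg.pca_meth[0] / 100.0
        m_bph = cfg.bph_meth[0] / 100.0
        y_pca = targets["dc_ratio_pca_mean"]
        y_bph = targets["dc_ratio_bph_mean"]
        cur_p, cur_b = _dc_mean(cfg, "PCa", n_eval), _dc_mean(cfg, "BPH", n_eval)
        if abs(cur_p - y_pca) > tolerance or abs(cur_b - y_bph) > tolerance:
            alpha = (y_bph - y_pca) / (m_bph - m_pca)
            beta = y_pca - alpha * m_pca
            cfg = cfg.model_copy(update={"gel_alpha": alpha, "gel_beta": beta})
            report.adjusted["gel_alpha"] = alpha
            report.adjusted["gel_beta"] = beta
        report.achieved["dc_ratio_pca_mean"] = _dc_mean(cfg, "PCa", n_eval)
        report.achieved["dc_ratio_bph_mean"] = _dc_mean(cfg, "BPH", n_eval)

    # --- 1-D monotone knobs ---
    specs = {
        "pca_hypomethylation_mean": dict(
            knob="pca_meth",
            bounds=(1.0, 49.0),
            apply=lambda c, v: c.model_copy(update={"pca_meth": (v, c.pca_meth[1])}),
            measure=lambda c: _group_hypometh(c, "PCa", n_eval),
        ),
        "bph_hypomethylation_mean": dict(
            knob="bph_meth",
            bounds=(61.0, 99.0),
            apply=lambda c, v: c.model_copy(update={"bph_meth": (v, c.bph_meth[1])}),
            measure=lambda c: _group_hypometh(c, "BPH", n_eval),
        ),
        "concordance_r2": dict(
            knob="gel_noise_sd",
            bounds=(0.0, 0.5),
            apply=lambda c, v: c.model_copy(update={"gel_noise_sd": v}),
            measure=lambda c: _concordance(c, n_eval),
        ),
        "psa_spearman_pooled": dict(
            knob="psa_copula_rho",
            bounds=(-0.95, 0.95),
            apply=lambda c, v: c.model_copy(update={"psa_copula_rho": v}),
            measure=lambda c: _pooled_spearman(c),
        ),
        "stage_regression_r": dict(
            knob="within_stratum_sd",
            bounds=(0.0, 25.0),
            apply=lambda c, v: c.model_copy(update={"within_stratum_sd": v}),
            measure=lambda c: _strat_r(c, "stage"),
        ),
        "grade_regression_r": dict(
            knob="stage_grade_weight",
            bounds=(0.0, 1.0),
            apply=lambda c, v: c.model_copy(update={"stage_grade_weight": v}),
            measure=lambda c: _strat_r(c, "grade"),
        ),
    }
    for name, spec in specs.items():
        if name not in targets:
            continue
        target = float(targets[name])
        tol = tol_for(name)
        current = spec["measure"](cfg)
        if abs(current - target) <= tol:  # fixed point: leave untouched
            report.achieved[name] = current
            continue
        holder = {"cfg": cfg}

        def evaluate(v: float, spec=spec, holder=holder) -> float:
            holder["cfg"] = spec["apply"](holder["cfg"], v)
            return spec["measure"](holder["cfg"])

        knob_val, achieved = _bisect_knob(
            evaluate, target, *spec["bounds"], tol, name
        )
        cfg = spec["apply"](cfg, knob_val)
        report.adjusted[spec["knob"]] = knob_val
        report.achieved[name] = achieved
    return cfg, report
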