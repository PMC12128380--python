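"""Threshold classification and ROC analysis from first principles.

The diagnostic rule is fixed by the assay: a sample is called
PCa-like (positive) when its methylation percentage falls strictly
below the cutoff (default 55%), i.e. *lower* scores are *more*
positive.  The ROC machinery is written directly from the definition —
thresholds at midpoints between adjacent distinct scores, trapezoidal
area — so that the area equals the pair-counting (concordance)
probability P(score_pos < score_neg) + 1/2 P(tie) exactly, which the
test suite cross-checks against an exhaustive oracle and an
independent library implementation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import UndefinedRocError

__all__ = [
    "DEFAULT_CUTOFF",
    "RocCurve",
    "ConfusionSummary",
    "classify",
    "roc_curve",
    "confusion_at",
    "auc_confidence",
    "youden_j",
]

DEFAULT_CUTOFF = 55.0


@dataclass
class RocCurve:
    """ROC curve under the lower-is-positive orientation."""

    thresholds: np.ndarray  # strictly increasing, with -inf/+inf sentinels
    sensitivity: np.ndarray  # P(score < thr | positive)
    specificity: np.ndarray  # P(score >= thr | negative)
    auc: float
    n_positive: int
    n_negative: int
    # raw per-class scores retained for resampling-based inference
    pos_scores: np.ndarray = field(repr=False, default=None)
    neg_scores: np.ndarray = field(repr=False, default=None)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)


def classify(methylation_pct: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Strict rule: positive (PCa-like) iff methylation % < cutoff.

    A sample exactly at the cutoff is negative.
    """
    return "positive" if methylation_pct < cutoff else "negative"


def _split_scores(
    scores: Sequence[float], labels: Sequence[str], positive_label: str
) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    mask = np.asarray([lab == positive_label for lab in labels])
    if len(mask) != len(scores):
        raise ValueError("scores and labels must have equal length")
    pos, neg = scores[mask], scores[~mask]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedRocError("ROC requires at least one sample in each class")
    return pos, neg


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str = "positive",
) -> RocCurve:
    """ROC over all midpoint thresholds (lower score = more positive).

    The trapezoidal area over (1 - specificity, sensitivity) equals the
    tie-broken concordance probability; vertical-and-horizontal steps
    contribute rectangles and tied scores contribute diagonal segments,
    which is exactly the 1/2-tie convention.
    """
    pos, neg = _split_scores(scores, labels, positive_label)
    pos_s, neg_s = np.sort(pos), np.sort(neg)
    distinct = np.unique(np.concatenate([pos_s, neg_s]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    # positive call: score < threshold.  Rates are counted positionally
    # in the gaps between adjacent distinct scores (a midpoint between
    # two adjacent floats may round onto one of them, so the reported
    # threshold values are representative while the rates stay exact).
    sens = np.concatenate(
        [[0.0], np.searchsorted(pos_s, distinct, side="right") / len(pos_s)]
    )
    spec = 1.0 - np.concatenate(
        [[0.0], np.searchsorted(neg_s, distinct, side="right") / len(neg_s)]
    )
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_positive=len(pos_s),
        n_negative=len(neg_s),
        pos_scores=pos_s,
        neg_scores=neg_s,
    )


def confusion_at(
    scores: Sequence[float],
    labels: Sequence[str],
    cutoff: float = DEFAULT_CUTOFF,
    positive_label: str = "positive",
) -> ConfusionSummary:
    """Confusion counts of the strict <cutoff rule."""
    pos, neg = _split_scores(scores, labels, positive_label)
    tp = int(np.sum(pos < cutoff))
    fn = len(pos) - tp
    fp = int(np.sum(neg < cutoff))
    tn = len(neg) - fp
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def auc_confidence(
    roc: RocCurve,
    method: str = "hanley-mcneil",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> tuple[float, float, float]:
    """(standard error, 95% CI low, 95% CI high) for the AUC.

    ``hanley-mcneil`` is the closed-form binormal-free SE of the
    concordance statistic (the form classic ROC software reports);
    ``bootstrap`` is a stratified percentile bootstrap resampling each
    class independently.
    """
    a = roc.auc
    n1, n2 = roc.n_positive, roc.n_negative
    if method == "hanley-mcneil":
        if a in (0.0, 1.0):
            warnings.warn(
                "degenerate AUC (perfect separation): Hanley-McNeil SE is 0",
                stacklevel=2,
            )
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (
            n1 * n2
        )
        se = float(np.sqrt(max(var, 0.0)))
        lo = max(0.0, a - 1.96 * se)
        hi = min(1.0, a + 1.96 * se)
        return se, lo, hi
    if method == "bootstrap":
        if n_boot <= 0:
            raise ValueError("n_boot must be positive for bootstrap CIs")
        if seed is None:
            raise ValueError("bootstrap CIs require a seed")
        rng = np.random.default_rng(seed)
        pos, neg = roc.pos_scores, roc.neg_scores
        boots = np.empty(n_boot)
        for b in range(n_boot):
            p = rng.choice(pos, size=n1, replace=True)
            q = rng.choice(neg, size=n2, replace=True)
            # concordance form: P(pos < neg) + 1/2 P(tie)
            less = np.sum(p[:, None] < q[None, :])
            ties = np.sum(p[:, None] == q[None, :])
            boots[b] = (less + 0.5 * ties) / (n1 * n2)
        se = float(np.std(boots, ddof=1))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return se, float(lo), float(hi)
    raise ValueError(f"unknown CI method: {method!r}")


def youden_j(roc: RocCurve) -> tuple[float, float]:
    """(threshold, J) maximizing sensitivity + specificity - 1.

    Provided as a diagnostic utility; the headline operating point of
    the assay is the fixed 55% cutoff, not an optimized one.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    i = int(np.argmax(j))
    return float(roc.thresholds[i]), float(j[i])
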