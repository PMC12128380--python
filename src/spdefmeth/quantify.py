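"""Methylation quantification from raw measurements.

Two assays are supported.  MSRE-qPCR quantifies the methylated fraction
from the cycle-threshold difference between a restriction-digested
aliquot and its undigested control,

    delta_Ct = Ct(digested) - Ct(undigested)
    % methylation = 100 * exp(-0.7 * delta_Ct)

Methylated template survives digestion by a methylation-sensitive
enzyme (HaeIII, GG^CC) and amplifies as efficiently as the undigested
control (delta_Ct near 0); unmethylated template is cleaved, so its
digested aliquot crosses the threshold later.  The -0.7 coefficient is
an empirically fixed assay constant, numerically close to -ln 2, so the
formula coincides with the classic 2^-deltaCt rule to within 1%.

Gel densitometry gives the semi-quantitative counterpart: the ratio of
digested to undigested band intensity (D/C), an affine proxy for the
methylated fraction.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import (
    InsufficientStandardsError,
    InvalidLaneError,
    InvalidSampleError,
)

__all__ = [
    "DCT_COEFFICIENT",
    "QpcrMeasurement",
    "GelMeasurement",
    "CalibrationStandard",
    "MethylationCall",
    "CalibrationFit",
    "compute_delta_ct",
    "methylation_from_delta_ct",
    "hypomethylation",
    "dc_ratio",
    "methylation_from_dc_ratio",
    "call_from_qpcr",
    "call_from_gel",
    "fit_standard_curve",
    "find_recognition_sites",
]

#: Fixed exponential coefficient of the delta-Ct conversion.
DCT_COEFFICIENT = 0.7


@dataclass
class QpcrMeasurement:
    """Paired digested/undigested Ct replicates for one sample.

    ``capped_digested`` marks replicates whose digested reaction never
    amplified within the run (Ct reported at the cycle cap); such
    samples are below the assay's detection floor for methylation.
    """

    sample_id: str
    ct_digested: list[float]
    ct_undigested: list[float]
    capped_digested: list[bool] = field(default_factory=list)
    capped_undigested: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ct_digested or not self.ct_undigested:
            raise InvalidSampleError(
                f"sample {self.sample_id}: at least one replicate per arm required"
            )
        if any(ct <= 0 for ct in list(self.ct_digested) + list(self.ct_undigested)):
            raise InvalidSampleError(
                f"sample {self.sample_id}: Ct values must be positive"
            )
        if not self.capped_digested:
            self.capped_digested = [False] * len(self.ct_digested)
        if not self.capped_undigested:
            self.capped_undigested = [False] * len(self.ct_undigested)


@dataclass
class GelMeasurement:
    """Digested and undigested band intensities (arbitrary units)."""

    sample_id: str
    intensity_digested: float
    intensity_undigested: float

    def __post_init__(self) -> None:
        if self.intensity_digested < 0:
            raise InvalidLaneError(
                f"sample {self.sample_id}: digested intensity must be >= 0"
            )


@dataclass
class CalibrationStandard:
    """Control DNA of known methylated fraction with measured Ct pairs."""

    nominal_meth: float  # percent, conventionally in {0, 25, 50, 75, 100}
    ct_digested: list[float]
    ct_undigested: list[float]
    capped_digested: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.nominal_meth <= 100.0):
            raise ValueError("nominal_meth must lie in [0, 100]")
        if not self.capped_digested:
            self.capped_digested = [False] * len(self.ct_digested)


@dataclass
class MethylationCall:
    """Per-sample methylation and hypomethylation percentages.

    ``methylation_pct + hypomethylation_pct == 100`` exactly by
    construction.  ``below_detection`` marks samples whose digested
    reaction was capped, i.e. the methylated fraction is below the
    assay floor (the computed percentage is then an upper bound).
    """

    sample_id: str
    method: str  # "qPCR" or "MSRE-PCR"
    methylation_pct: float
    delta_ct: Optional[float] = None
    below_detection: bool = False

    @property
    def hypomethylation_pct(self) -> float:
        return 100.0 - self.methylation_pct


@dataclass
class CalibrationFit:
    """OLS fit of delta-Ct against log10(% methylation) of standards."""

    slope: float  # cycles per decade
    intercept: float  # cycles
    r_squared: float
    n_points: int
    zero_control_capped: Optional[bool] = None  # digestion control outcome


def compute_delta_ct(m: QpcrMeasurement) -> float:
    """Replicate-mean delta-Ct: mean(digested) - mean(undigested).

    Replicates are reduced by the arithmetic mean in Ct space (the
    quantity is linear in cycles).  All undigested replicates capped
    means no amplifiable input DNA at all, which is unquantifiable.
    """
    if all(m.capped_undigested):
        raise InvalidSampleError(
            f"sample {m.sample_id}: no amplification in the undigested arm "
            "(no amplifiable input DNA)"
        )
    return float(np.mean(m.ct_digested) - np.mean(m.ct_undigested))


def methylation_from_delta_ct(delta_ct: float) -> float:
    """% methylation = 100 * exp(-0.7 * delta_ct), clamped to [0, 100].

    A negative delta-Ct (digested amplifying earlier than its control)
    can only arise from measurement noise at full methylation; it is
    clamped to 100% with a warning rather than treated as an error.
    """
    if not math.isfinite(delta_ct):
        raise ValueError("delta_ct must be finite")
    if delta_ct < 0:
        warnings.warn(
            f"negative delta-Ct ({delta_ct:.4g}) clamped to 100% methylation",
            stacklevel=2,
        )
        return 100.0
    return min(100.0, 100.0 * math.exp(-DCT_COEFFICIENT * delta_ct))


def hypomethylation(call: MethylationCall) -> float:
    """Hypomethylation % is the exact complement of methylation %."""
    return 100.0 - call.methylation_pct


def dc_ratio(g: GelMeasurement) -> float:
    """Digested/undigested band-intensity ratio (the D/C ratio)."""
    if g.intensity_undigested <= 0:
        raise InvalidLaneError(
            f"sample {g.sample_id}: undigested reference band has zero intensity"
        )
    return g.intensity_digested / g.intensity_undigested


def methylation_from_dc_ratio(ratio: float, alpha: float, beta: float) -> float:
    """Invert the affine densitometry response D/C = beta + alpha * m.

    Returns % methylation clipped to [0, 100]; used to place the gel
    assay on the same scale as qPCR for concordance analysis.
    """
    if alpha == 0:
        raise ValueError("densitometry slope alpha must be non-zero")
    return float(np.clip((ratio - beta) / alpha * 100.0, 0.0, 100.0))


def call_from_qpcr(m: QpcrMeasurement) -> MethylationCall:
    dct = compute_delta_ct(m)
    if dct < 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pct = methylation_from_delta_ct(dct)
    else:
        pct = methylation_from_delta_ct(dct)
    return MethylationCall(
        sample_id=m.sample_id,
        method="qPCR",
        methylation_pct=pct,
        delta_ct=dct,
        below_detection=any(m.capped_digested),
    )


def call_from_gel(g: GelMeasurement, alpha: float, beta: float) -> MethylationCall:
    return MethylationCall(
        sample_id=g.sample_id,
        method="MSRE-PCR",
        methylation_pct=methylation_from_dc_ratio(dc_ratio(g), alpha, beta),
    )


def fit_standard_curve(standards: Sequence[CalibrationStandard]) -> CalibrationFit:
    """Fit delta-Ct against log10(% methylation) by ordinary least squares.

    The 0% standard cannot enter a log-scale fit; it is excluded and
    instead reported as the digestion control (complete digestion should
    leave its digested reaction capped).  At least three positive-level
    standards are required for a meaningful line.
    """
    positive = [s for s in standards if s.nominal_meth > 0]
    if len(positive) < 3:
        raise InsufficientStandardsError(
            f"need >= 3 standards with nominal_meth > 0, got {len(positive)}"
        )
    x = np.log10([s.nominal_meth for s in positive])
    y = np.array(
        [float(np.mean(s.ct_digested) - np.mean(s.ct_undigested)) for s in positive]
    )
    fit = _sps.linregress(x, y)
    zeros = [s for s in standards if s.nominal_meth == 0]
    zero_capped = (
        all(all(s.capped_digested) for s in zeros) if zeros else None
    )
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(positive),
        zero_control_capped=zero_capped,
    )


_VALID_NT = re.compile(r"^[ACGTN]*$")


def find_recognition_sites(sequence: str, motif: str) -> list[int]:
    """All (possibly overlapping) exact-match offsets of ``motif``.

    Case-insensitive over the {A, C, G, T, N} alphabet; an N in either
    the sequence or the motif never matches (an ambiguous base cannot be
    asserted to form a restriction site).  Used to locate HaeIII (GGCC)
    sites when designing an MSRE assay over a promoter sequence.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = sequence.upper()
    mot = motif.upper()
    for name, s in (("sequence", seq), ("motif", mot)):
        if not _VALID_NT.match(s):
            raise ValueError(f"{name} contains characters outside {{A,C,G,T,N}}")
    if "N" in mot:
        return []
    hits = []
    for i in range(len(seq) - len(mot) + 1):
        window = seq[i : i + len(mot)]
        if "N" not in window and window == mot:
            hits.append(i)
    return hits
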