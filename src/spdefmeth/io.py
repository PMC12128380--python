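"""Delimited-table input/output and schema validation.

All pipeline artifacts are plain delimited text (comma by default, tab
selectable) with a header row and fixed, documented column names.
Percent-scale and continuous columns are serialized with 4 decimal
places and a locale-independent decimal point, so byte-identical
reruns are achievable under a fixed seed.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .quantify import GelMeasurement, QpcrMeasurement, CalibrationStandard
from .simulate import Subject

__all__ = [
    "cohort_frame",
    "qpcr_frame",
    "gel_frame",
    "standards_frame",
    "write_table",
    "read_table",
    "qpcr_from_frame",
    "gel_from_frame",
    "standards_from_frame",
    "validate_input",
    "ValidationReport",
    "SCHEMAS",
]

_FLOAT_FORMAT = "%.4f"


def _sep(fmt: str) -> str:
    if fmt not in ("csv", "tsv"):
        raise ValueError("format must be 'csv' or 'tsv'")
    return "," if fmt == "csv" else "\t"


def cohort_frame(subjects: Sequence[Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "true_meth": [s.true_meth for s in subjects],
            "tpsa": [s.tpsa for s in subjects],
            "age": [s.age for s in subjects],
            "prostate_weight": [s.prostate_weight for s in subjects],
            "stage": [s.stage if s.stage is not None else "" for s in subjects],
            "grade": [s.grade if s.grade is not None else "" for s in subjects],
            "is_contaminant": [int(s.is_contaminant) for s in subjects],
        }
    )


def qpcr_frame(measurements: Sequence[QpcrMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for r, (d, u, c) in enumerate(
            zip(m.ct_digested, m.ct_undigested, m.capped_digested), start=1
        ):
            rows.append((m.sample_id, r, d, u, int(c)))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "replicate", "ct_digested", "ct_undigested",
                 "capped_digested"],
    )


def gel_frame(measurements: Sequence[GelMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in measurements],
            "intensity_digested": [g.intensity_digested for g in measurements],
            "intensity_undigested": [g.intensity_undigested for g in measurements],
        }
    )


def standards_frame(standards: Sequence[CalibrationStandard]) -> pd.DataFrame:
    rows = []
    for s in standards:
        for r, (d, u, c) in enumerate(
            zip(s.ct_digested, s.ct_undigested, s.capped_digested), start=1
        ):
            rows.append((s.nominal_meth, r, d, u, int(c)))
    return pd.DataFrame(
        rows,
        columns=["nominal_meth", "replicate", "ct_digested", "ct_undigested",
                 "capped_digested"],
    )


def write_table(df: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    df.to_csv(path, sep=_sep(fmt), index=False, float_format=_FLOAT_FORMAT)


def read_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    if fmt is None:
        fmt = "tsv" if str(path).endswith(".tsv") else "csv"
    return pd.read_csv(path, sep=_sep(fmt))


def qpcr_from_frame(df: pd.DataFrame) -> list[QpcrMeasurement]:
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        capped = (
            grp["capped_digested"].astype(bool).tolist()
            if "capped_digested" in grp
            else []
        )
        out.append(
            QpcrMeasurement(
                sample_id=str(sid),
                ct_digested=grp["ct_digested"].astype(float).tolist(),
                ct_undigested=grp["ct_undigested"].astype(float).tolist(),
                capped_digested=capped,
            )
        )
    return out


def gel_from_frame(df: pd.DataFrame) -> list[GelMeasurement]:
    return [
        GelMeasurement(
            sample_id=str(r.sample_id),
            intensity_digested=float(r.intensity_digested),
            intensity_undigested=float(r.intensity_undigested),
        )
        for r in df.itertuples()
    ]


def standards_from_frame(df: pd.DataFrame) -> list[CalibrationStandard]:
    out = []
    for lv, grp in df.groupby("nominal_meth", sort=True):
        out.append(
            CalibrationStandard(
                nominal_meth=float(lv),
                ct_digested=grp["ct_digested"].astype(float).tolist(),
                ct_undigested=grp["ct_undigested"].astype(float).tolist(),
                capped_digested=(
                    grp["capped_digested"].astype(bool).tolist()
                    if "capped_digested" in grp
                    else []
                ),
            )
        )
    return out


class ValidationReport:
    """Outcome of schema validation: a list of human-readable violations."""

    def __init__(self, table: str, violations: list[str]):
        self.table = table
        self.violations = violations

    @property
    def ok(self) -> bool:
        return not self.violations

    def __repr__(self) -> str:
        status = "ok" if self.ok else f"{len(self.violations)} violation(s)"
        return f"ValidationReport({self.table}: {status})"


# schema: column -> (dtype kind, (min, max) or allowed set or None)
SCHEMAS: dict[str, dict] = {
    "cohort": {
        "sample_id": ("str", None),
        "group": ("str", {"PCa", "BPH"}),
        "true_meth": ("num", (0.0, 1.0)),
        "tpsa": ("num", (0.0, None)),
        "age": ("num", (0.0, None)),
        "prostate_weight": ("num", (0.0, None)),
    },
    "qpcr": {
        "sample_id": ("str", None),
        "ct_digested": ("num", (0.0, None)),
        "ct_undigested": ("num", (0.0, None)),
    },
    "gel": {
        "sample_id": ("str", None),
        "intensity_digested": ("num", (0.0, None)),
        "intensity_undigested": ("num", (0.0, None)),
    },
    "standards": {
        "nominal_meth": ("num", (0.0, 100.0)),
        "ct_digested": ("num", (0.0, None)),
        "ct_undigested": ("num", (0.0, None)),
    },
}


def validate_input(path: str | Path, schema_name: str, fmt: str | None = None) -> ValidationReport:
    """Validate a user-supplied table against a named schema.

    Reports missing columns, non-numeric entries in numeric columns and
    out-of-range values with row and column references.  Never mutates
    the input file.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema_name}'; "
                          f"known: {sorted(SCHEMAS)}")
    try:
        df = read_table(path, fmt)
    except OSError as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    schema = SCHEMAS[schema_name]
    violations: list[str] = []
    for col, (kind, constraint) in schema.items():
        if col not in df.columns:
            violations.append(f"missing column '{col}'")
            continue
        series = df[col]
        if kind == "num":
            coerced = pd.to_numeric(series, errors="coerce")
            bad = series.index[coerced.isna() & series.notna()]
            for i in bad[:10]:
                violations.append(f"column '{col}' row {i}: non-numeric value {series[i]!r}")
            if isinstance(constraint, tuple):
                lo, hi = constraint
                vals = coerced.dropna()
                if lo is not None:
                    for i in vals.index[vals < lo][:10]:
                        violations.append(
                            f"column '{col}' row {i}: value {vals[i]} below minimum {lo}"
                        )
                if hi is not None:
                    for i in vals.index[vals > hi][:10]:
                        violations.append(
                            f"column '{col}' row {i}: value {vals[i]} above maximum {hi}"
                        )
        elif isinstance(constraint, set):
            bad = series.index[~series.astype(str).isin(constraint)]
            for i in bad[:10]:
                violations.append(
                    f"column '{col}' row {i}: value {series[i]!r} not in {sorted(constraint)}"
                )
    return ValidationReport(schema_name, violations)
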