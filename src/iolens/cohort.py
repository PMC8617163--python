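"""Per-eye record types and the tabular cohort container.

A *cohort* is a :class:`pandas.DataFrame` with one row per eye (one eye per
patient) and the canonical columns

    id, lens_model, age, sex, al_mm, k1_d, k2_d, acd_mm, iol_power_d, postop_se_d

``al_mm`` is the axial length, ``k1_d``/``k2_d`` the flat/steep keratometry
readings, ``acd_mm`` the pre-operative anterior chamber depth,
``iol_power_d`` the implanted IOL power and ``postop_se_d`` the achieved
post-operative spherical-equivalent refraction.  The dataclasses below give
a typed view of a single row; module functions validate whole frames at
once and report failures row by row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "REQUIRED_COLUMNS",
    "BIOMETRY_COLUMNS",
    "EyeBiometry",
    "SurgicalOutcome",
    "EyeRecord",
    "validate_cohort",
    "cohort_from_records",
]

REQUIRED_COLUMNS = (
    "id",
    "lens_model",
    "age",
    "sex",
    "al_mm",
    "k1_d",
    "k2_d",
    "acd_mm",
    "iol_power_d",
    "postop_se_d",
)

BIOMETRY_COLUMNS = ("al_mm", "k1_d", "k2_d", "acd_mm")

# field -> (low, high, closed?) physiological bounds
_BOUNDS = {
    "al_mm": (15.0, 40.0, False),
    "k1_d": (30.0, 60.0, False),
    "k2_d": (30.0, 60.0, False),
    "acd_mm": (1.5, 6.0, False),
    "iol_power_d": (-10.0, 40.0, True),
    "postop_se_d": (-10.0, 10.0, True),
}


@dataclass(frozen=True)
class EyeBiometry:
    """Pre-operative biometry for one eye (one eye per patient)."""

    axial_length: float
    k_flat: float
    k_steep: float
    acd_preop: float
    age: Optional[float] = None
    sex: Optional[str] = None
    lens_model: str = ""

    def __post_init__(self) -> None:
        _scalar_check("al_mm", self.axial_length)
        _scalar_check("k1_d", self.k_flat)
        _scalar_check("k2_d", self.k_steep)
        _scalar_check("acd_mm", self.acd_preop)


@dataclass(frozen=True)
class SurgicalOutcome:
    """Implanted IOL power and achieved post-operative refraction."""

    implanted_power: float
    achieved_se: float

    def __post_init__(self) -> None:
        _scalar_check("iol_power_d", self.implanted_power)
        _scalar_check("postop_se_d", self.achieved_se)


@dataclass(frozen=True)
class EyeRecord:
    biometry: EyeBiometry
    outcome: SurgicalOutcome
    id: str


def _scalar_check(field: str, value: float) -> None:
    lo, hi, closed = _BOUNDS[field]
    if not np.isfinite(value):
        raise ValidationError(field, "must be finite")
    ok = (lo <= value <= hi) if closed else (lo < value < hi)
    if not ok:
        bracket = "[]" if closed else "()"
        raise ValidationError(
            field, f"{value} outside {bracket[0]}{lo}, {hi}{bracket[1]}"
        )


def validate_cohort(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Return (row-index, message) pairs for every row violating a bound.

    The frame must already carry the canonical columns; missing columns are
    a schema-level problem handled by :func:`iolens.io.read_cohort_csv`.
    """
    failures: list[tuple[int, str]] = []
    for field, (lo, hi, closed) in _BOUNDS.items():
        col = pd.to_numeric(df[field], errors="coerce")
        bad_num = col.isna()
        ok = (col >= lo) & (col <= hi) if closed else (col > lo) & (col < hi)
        for idx in df.index[bad_num]:
            failures.append((int(idx), f"{field}: not numeric"))
        for idx in df.index[~ok & ~bad_num]:
            failures.append((int(idx), f"{field}: {col[idx]} outside ({lo}, {hi})"))
    dup = df["id"].duplicated()
    for idx in df.index[dup]:
        failures.append((int(idx), f"id: duplicate identifier {df['id'][idx]!r}"))
    return sorted(failures)


def cohort_from_records(records: Iterable[EyeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        b, o = r.biometry, r.outcome
        rows.append(
            dict(
                id=r.id,
                lens_model=b.lens_model,
                age=b.age,
                sex=b.sex,
                al_mm=b.axial_length,
                k1_d=b.k_flat,
                k2_d=b.k_steep,
                acd_mm=b.acd_preop,
                iol_power_d=o.implanted_power,
                postop_se_d=o.achieved_se,
            )
        )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
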