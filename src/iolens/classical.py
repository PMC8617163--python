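"""The four classical IOL-power formulas and their lens-constant optimization.

Haigis, Hoffer Q, Holladay I and SRK/T all share the same thin-lens
vergence skeleton (:mod:`iolens.optics`) and differ in

* how the effective lens position (ELP) is estimated from pre-operative
  biometry — each carries its own tunable per-lens "IOL constant"
  (``a0/a1/a2``, ``pACD``, ``SF``, ``A_constant``), and
* small internal conventions: the corneal index used to convert mean
  keratometry into corneal power, a retinal-thickness correction of the
  axial length, and (for Hoffer Q) a fixed offset between the quoted ELP
  and the vergence-plane depth.

Internals follow the original publications (Retzlaff 1990 with erratum,
Hoffer 1993 with errata, Holladay 1988, Haigis 2000).  Keratometers are
assumed calibrated with index 1.3375, i.e. corneal radius ``r = 337.5 / K``.

Constant optimization reproduces the clinical convention: single-constant
formulas are tuned so that the training-set mean prediction error is zero;
the three Haigis constants are an ordinary least-squares regression of
back-calculated lens positions on ``(1, ACD, AL)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from hashlib import sha256
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import optics
from .errors import ClampWarning, OptimizationError, ValidationError
from .optics import OpticalConstants

__all__ = [
    "Formula",
    "CLASSICAL_FORMULAE",
    "LensConstantSet",
    "estimate_elp",
    "predict_refraction_classical",
    "power_for_target_classical",
    "back_calculate_elp_classical",
    "optimize_constants",
    "ClassicalFormulaModel",
    "ClassicalFormulaResults",
]


class Formula(str, Enum):
    """Identifier of an IOL-power formula (the four comparators + MM)."""

    HAIGIS = "HAIGIS"
    HOFFERQ = "HOFFERQ"
    HOLLADAY1 = "HOLLADAY1"
    SRKT = "SRKT"
    MM = "MM"


CLASSICAL_FORMULAE = (
    Formula.SRKT,
    Formula.HOFFERQ,
    Formula.HOLLADAY1,
    Formula.HAIGIS,
)

# published search intervals for the single personalization constants
CONSTANT_INTERVALS = {
    Formula.HOFFERQ: ("pACD", 2.0, 8.0),
    Formula.HOLLADAY1: ("SF", -2.0, 4.0),
    Formula.SRKT: ("A_constant", 110.0, 125.0),
}

_KERATOMETER_INDEX = 1.3375  # r = 337.5 / K


@dataclass
class LensConstantSet:
    """Per-lens, per-formula personalization constants with provenance.

    Exactly the fields required by ``formula`` must be populated:
    ``pACD`` (Hoffer Q), ``SF`` (Holladay I), ``A_constant`` (SRK/T) or
    ``a0, a1, a2`` (Haigis).
    """

    formula: Formula
    lens_model: str = ""
    pACD: Optional[float] = None
    SF: Optional[float] = None
    A_constant: Optional[float] = None
    a0: Optional[float] = None
    a1: Optional[float] = None
    a2: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    _REQUIRED = {
        Formula.HOFFERQ: ("pACD",),
        Formula.HOLLADAY1: ("SF",),
        Formula.SRKT: ("A_constant",),
        Formula.HAIGIS: ("a0", "a1", "a2"),
    }

    def __post_init__(self) -> None:
        self.formula = Formula(self.formula)
        if self.formula is Formula.MM:
            raise ValidationError(
                "formula", "the MM formula stores its constants in the fitted ensemble"
            )
        for name in self._REQUIRED[self.formula]:
            if getattr(self, name) is None:
                raise ValidationError(name, f"required by {self.formula.value}")

    def to_dict(self) -> dict:
        out = {"formula": self.formula.value, "lens_model": self.lens_model}
        for name in ("pACD", "SF", "A_constant", "a0", "a1", "a2"):
            if getattr(self, name) is not None:
                out[name] = getattr(self, name)
        if self.provenance:
            out["provenance"] = self.provenance
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "LensConstantSet":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# per-formula internals
# ---------------------------------------------------------------------------


def _corneal_radius(k_mean):
    return (1000.0 * (_KERATOMETER_INDEX - 1.0)) / k_mean  # = 337.5 / K


def _clamped_sqrt(disc, what: str):
    disc = np.asarray(disc, dtype=float)
    if np.any(disc < 0):
        warnings.warn(
            f"{what}: negative discriminant clamped to zero for "
            f"{int(np.sum(disc < 0))} eye(s)",
            ClampWarning,
            stacklevel=3,
        )
    return np.sqrt(np.clip(disc, 0.0, None))


def _elp_srkt(al, k_mean, a_constant):
    r = _corneal_radius(k_mean)
    lcor = np.where(al > 24.2, -3.446 + 1.716 * al - 0.0237 * al**2, al)
    cw = -5.41 + 0.58412 * lcor + 0.098 * k_mean  # computed corneal width
    h = r - _clamped_sqrt(r**2 - cw**2 / 4.0, "SRK/T corneal height")
    acd_const = 0.62467 * a_constant - 68.747
    return h + (acd_const - 3.336)


def _elp_hofferq(al, k_mean, pacd):
    al = np.asarray(al, dtype=float)
    clipped = (al < 18.5) | (al > 31.0)
    if np.any(clipped):
        warnings.warn(
            f"Hoffer Q: axial length clamped to [18.5, 31] mm for "
            f"{int(clipped.sum())} eye(s)",
            ClampWarning,
            stacklevel=3,
        )
    alc = np.clip(al, 18.5, 31.0)
    m = np.where(alc <= 23.0, 1.0, -1.0)
    g = np.where(alc <= 23.0, 28.0, 23.5)
    tan_deg = lambda x: np.tan(np.deg2rad(x))  # noqa: E731 - published form uses degrees
    return (
        pacd
        + 0.3 * (alc - 23.5)
        + tan_deg(k_mean) ** 2
        + 0.1 * m * (23.5 - alc) ** 2 * tan_deg(0.1 * (g - alc) ** 2)
        - 0.99166
    )


def _elp_holladay1(al, k_mean, sf):
    r = _corneal_radius(k_mean)
    ag = np.minimum(al * 12.5 / 23.45, 13.5)
    a_acd = 0.56 + r - _clamped_sqrt(r**2 - ag**2 / 4.0, "Holladay I corneal height")
    return a_acd + sf


# formula -> (corneal power from K, optical axial length, vergence-plane ELP offset)
_INTERNALS = {
    Formula.SRKT: (
        lambda k: k * (333.0 / 337.5),  # nc - 1 = 0.333
        lambda al: al + (0.65696 - 0.02029 * al),  # retinal thickness correction
        0.0,
    ),
    Formula.HOFFERQ: (
        lambda k: k,  # mean K used directly
        lambda al: al,
        0.05,  # published ACD + 0.05 in the vergence denominators
    ),
    Formula.HOLLADAY1: (
        lambda k: k * ((1000.0 / 3.0) / 337.5),  # nc = 4/3
        lambda al: al + 0.2,
        0.0,
    ),
    Formula.HAIGIS: (
        lambda k: k * (331.5 / 337.5),  # nc = 1.3315
        lambda al: al,
        0.0,
    ),
}

_VERGENCE_CONSTANTS = OpticalConstants(n_aq=1.336, n_vit=1.336, vertex_distance=0.012)


def estimate_elp(formula: Formula, al, k1, k2, acd, constants: LensConstantSet):
    """Formula-specific effective lens position (mm) from pre-operative biometry.

    ``acd`` (the pre-operative anterior chamber depth) is used only by the
    Haigis formula; the other three depend on ``(K, AL)`` alone.
    """
    formula = Formula(formula)
    if constants.formula is not formula:
        raise ValidationError("constants", f"constants are for {constants.formula.value}")
    k_mean = optics.mean_corneal_power(k1, k2)
    if formula is Formula.HAIGIS:
        if acd is None or np.any(~np.isfinite(np.asarray(acd, dtype=float))):
            raise ValidationError("acd_mm", "Haigis requires the pre-operative ACD")
        return constants.a0 + constants.a1 * np.asarray(acd, dtype=float) + constants.a2 * np.asarray(al, dtype=float)
    if formula is Formula.HOFFERQ:
        return _elp_hofferq(al, k_mean, constants.pACD)
    if formula is Formula.HOLLADAY1:
        return _elp_holladay1(al, k_mean, constants.SF)
    if formula is Formula.SRKT:
        return _elp_srkt(np.asarray(al, dtype=float), k_mean, constants.A_constant)
    raise ValidationError("formula", "MM has no closed-form ELP estimator")


def _effective_geometry(formula: Formula, al, k1, k2, acd, constants: LensConstantSet):
    pc_of_k, al_eff_of, offset = _INTERNALS[Formula(formula)]
    k_mean = optics.mean_corneal_power(k1, k2)
    elp = estimate_elp(formula, al, k1, k2, acd, constants)
    return al_eff_of(np.asarray(al, dtype=float)), elp + offset, pc_of_k(k_mean), offset


def predict_refraction_classical(
    formula: Formula, al, k1, k2, acd, constants: LensConstantSet, power
):
    """Spectacle-plane refraction predicted by a classical formula for implanted ``power``."""
    al_eff, d_eff, pc_eff, _ = _effective_geometry(formula, al, k1, k2, acd, constants)
    return optics.predict_refraction(al_eff, d_eff, pc_eff, power, _VERGENCE_CONSTANTS)


def power_for_target_classical(
    formula: Formula, al, k1, k2, acd, constants: LensConstantSet, target_rx=0.0
):
    """IOL power a classical formula selects for a target refraction (default emmetropia)."""
    al_eff, d_eff, pc_eff, _ = _effective_geometry(formula, al, k1, k2, acd, constants)
    return optics.iol_power_for_refraction(
        al_eff, d_eff, pc_eff, target_rx, _VERGENCE_CONSTANTS
    )


def back_calculate_elp_classical(
    formula: Formula, al, k1, k2, power, rx_achieved, on_failure: str = "raise"
):
    """Lens position implied by an observed refraction under a formula's own optics.

    Used to build the regression targets for Haigis constant optimization;
    the returned depth is on the formula's quoted-ELP scale (vergence-plane
    offset removed).
    """
    pc_of_k, al_eff_of, offset = _INTERNALS[Formula(formula)]
    k_mean = optics.mean_corneal_power(k1, k2)
    d_eff = optics.back_calculate_elp(
        al_eff_of(np.asarray(al, dtype=float)),
        pc_of_k(k_mean),
        power,
        rx_achieved,
        _VERGENCE_CONSTANTS,
        on_failure=on_failure,
    )
    return d_eff - offset


# ---------------------------------------------------------------------------
# constant optimization
# ---------------------------------------------------------------------------


def _training_arrays(cohort: pd.DataFrame):
    return (
        cohort["al_mm"].to_numpy(float),
        cohort["k1_d"].to_numpy(float),
        cohort["k2_d"].to_numpy(float),
        cohort["acd_mm"].to_numpy(float),
        cohort["iol_power_d"].to_numpy(float),
        cohort["postop_se_d"].to_numpy(float),
    )


def _provenance(cohort: pd.DataFrame) -> dict:
    digest = sha256(
        pd.util.hash_pandas_object(cohort[list(("id",) + ("al_mm", "k1_d", "k2_d", "acd_mm", "iol_power_d", "postop_se_d"))], index=False).to_numpy().tobytes()
    ).hexdigest()[:16]
    return {"n_train": int(len(cohort)), "train_hash": digest, "date": date.today().isoformat()}


def optimize_constants(
    formula: Formula,
    cohort: pd.DataFrame,
    min_cohort: int = 30,
    haigis_mode: str = "full",
    tol: float = 1e-6,
) -> LensConstantSet:
    """Personalize a formula's lens constants on a training cohort.

    Single-constant formulas (``pACD``, ``SF``, ``A_constant``) are tuned by
    1-D root-finding so the training mean prediction error is zero to
    ``tol`` diopters.  Haigis fits ``d = a0 + a1 ACD + a2 AL`` by ordinary
    least squares on lens positions back-calculated with Haigis's own
    optics (``haigis_mode="a0_only"`` keeps the published default slopes
    a1 = 0.4, a2 = 0.1 and adjusts the intercept only).
    """
    formula = Formula(formula)
    if len(cohort) < min_cohort:
        raise ValidationError(
            "cohort", f"needs at least {min_cohort} eyes, got {len(cohort)}"
        )
    lens_models = cohort["lens_model"].unique() if "lens_model" in cohort else [""]
    if len(lens_models) > 1:
        raise ValidationError("lens_model", "cohort mixes lens models; fit one at a time")
    lens_model = str(lens_models[0])
    al, k1, k2, acd, power, achieved = _training_arrays(cohort)
    prov = _provenance(cohort)

    if formula is Formula.HAIGIS:
        d = back_calculate_elp_classical(
            formula, al, k1, k2, power, achieved, on_failure="nan"
        )
        ok = np.isfinite(d)
        n_dropped = int((~ok).sum())
        if n_dropped > 0.2 * len(d):
            raise OptimizationError(
                f"Haigis: {n_dropped}/{len(d)} eyes have no plausible "
                "back-calculated lens position"
            )
        d, acd, al = d[ok], acd[ok], al[ok]
        prov["n_dropped_backcalc"] = n_dropped
        if haigis_mode == "a0_only":
            a1, a2 = 0.4, 0.1
            a0 = float(np.mean(d - a1 * acd - a2 * al))
        elif haigis_mode == "full":
            design = np.column_stack([np.ones_like(acd), acd, al])
            if np.linalg.matrix_rank(design) < 3:
                raise OptimizationError("Haigis design matrix is rank deficient")
            coef, *_ = np.linalg.lstsq(design, d, rcond=None)
            a0, a1, a2 = (float(c) for c in coef)
        else:
            raise ValueError("haigis_mode must be 'full' or 'a0_only'")
        prov["mode"] = haigis_mode
        return LensConstantSet(
            Formula.HAIGIS, lens_model, a0=a0, a1=a1, a2=a2, provenance=prov
        )

    name, lo, hi = CONSTANT_INTERVALS[formula]

    def mean_pe(c: float) -> float:
        cs = LensConstantSet(formula, lens_model, **{name: c})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampWarning)
            pred = predict_refraction_classical(formula, al, k1, k2, acd, cs, power)
        return float(np.mean(achieved - pred))

    f_lo, f_hi = mean_pe(lo), mean_pe(hi)
    if f_lo * f_hi > 0:
        raise OptimizationError(
            f"{formula.value}: mean prediction error does not change sign over "
            f"{name} in [{lo}, {hi}] (f({lo})={f_lo:.3f}, f({hi})={f_hi:.3f})"
        )
    root = brentq(mean_pe, lo, hi, xtol=1e-10)
    # polish until the *objective* (mean PE), not just the constant, is below tol
    if abs(mean_pe(root)) > tol:
        root = brentq(mean_pe, max(lo, root - 0.05), min(hi, root + 0.05), xtol=1e-13)
    return LensConstantSet(formula, lens_model, **{name: float(root)}, provenance=prov)


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------


class ClassicalFormulaModel:
    """One classical formula bound to a training cohort.

    ``fit()`` personalizes the lens constants and returns a
    :class:`ClassicalFormulaResults` that predicts refractions and powers
    for new eyes.
    """

    def __init__(
        self,
        formula: Formula,
        cohort: pd.DataFrame,
        min_cohort: int = 30,
        haigis_mode: str = "full",
    ):
        self.formula = Formula(formula)
        self.cohort = cohort.reset_index(drop=True)
        self.min_cohort = min_cohort
        self.haigis_mode = haigis_mode

    def fit(self) -> "ClassicalFormulaResults":
        constants = optimize_constants(
            self.formula, self.cohort, self.min_cohort, self.haigis_mode
        )
        al, k1, k2, acd, power, achieved = _training_arrays(self.cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampWarning)
            pred = predict_refraction_classical(
                self.formula, al, k1, k2, acd, constants, power
            )
        pe = achieved - pred
        return ClassicalFormulaResults(self, constants, pe)


class ClassicalFormulaResults:
    """Personalized constants plus training diagnostics for one formula."""

    def __init__(self, model: ClassicalFormulaModel, constants: LensConstantSet, train_pe):
        self.model = model
        self.constants = constants
        self.train_pe = np.asarray(train_pe, dtype=float)

    @property
    def formula(self) -> Formula:
        return self.model.formula

    def estimate_elp(self, cohort: pd.DataFrame):
        return estimate_elp(
            self.formula,
            cohort["al_mm"].to_numpy(float),
            cohort["k1_d"].to_numpy(float),
            cohort["k2_d"].to_numpy(float),
            cohort["acd_mm"].to_numpy(float),
            self.constants,
        )

    def predict_refraction(self, cohort: pd.DataFrame, power=None):
        if power is None:
            power = cohort["iol_power_d"].to_numpy(float)
        return predict_refraction_classical(
            self.formula,
            cohort["al_mm"].to_numpy(float),
            cohort["k1_d"].to_numpy(float),
            cohort["k2_d"].to_numpy(float),
            cohort["acd_mm"].to_numpy(float),
            self.constants,
            power,
        )

    def recommend_power(self, cohort: pd.DataFrame, target_rx: float = 0.0, step: float = 0.5):
        raw = power_for_target_classical(
            self.formula,
            cohort["al_mm"].to_numpy(float),
            cohort["k1_d"].to_numpy(float),
            cohort["k2_d"].to_numpy(float),
            cohort["acd_mm"].to_numpy(float),
            self.constants,
            target_rx,
        )
        return np.round(np.asarray(raw) / step) * step, raw

    def summary(self) -> str:
        c = self.constants
        lines = [
            f"Classical formula results — {self.formula.value}",
            "=" * 46,
            f"lens model        : {c.lens_model or '(unspecified)'}",
            f"n (training eyes) : {len(self.train_pe)}",
        ]
        for nm in ("pACD", "SF", "A_constant", "a0", "a1", "a2"):
            v = getattr(c, nm)
            if v is not None:
                lines.append(f"{nm:<18}: {v:.6f}")
        lines += [
            f"train mean PE (D) : {np.mean(self.train_pe):+.6f}",
            f"train SD PE (D)   : {np.std(self.train_pe, ddof=1):.4f}",
            f"train MAE (D)     : {np.mean(np.abs(self.train_pe)):.4f}",
        ]
        return "\n".join(lines)
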