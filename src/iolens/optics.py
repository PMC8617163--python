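"""Thin-lens vergence optics of the pseudophakic eye.

The operated eye is modelled as a two-lens system (cornea + implanted
intraocular lens, IOL) with an optional spectacle lens in front.  All axial
distances are kept in millimetres and every vergence term therefore uses
``1000 * n`` so that powers come out directly in diopters; the spectacle
vertex distance ``b`` is stored in metres because it multiplies diopters.

Symbols used throughout:

``AL``
    axial length of the eye, corneal apex to retina (mm).
``d`` (ELP)
    effective lens position — corneal apex to IOL optical centre (mm).
``Pc``
    corneal power (D), here the mean keratometry ``K = (K1 + K2) / 2``.
``P``
    IOL power (D).
``Rx``
    spectacle-plane spherical-equivalent refraction (D).

The emmetropic power of an IOL placed at depth ``d`` is

    P = 1000 n_vit / (AL - d) - 1000 n_aq / (1000 n_aq / Pc - d)

and a non-zero refractive target enters by moving ``Rx`` to the corneal
plane, ``S = Rx / (1 - b Rx)``, and replacing ``Pc`` with ``Pc + S``.  The
module also provides the closed-form inversions of that relation for the
predicted refraction given an implanted power and for the lens position
given an observed refraction (a quadratic in ``d``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    AmbiguousRootWarning,
    NoSolutionError,
    SingularGeometryError,
    ValidationError,
)

__all__ = [
    "OpticalConstants",
    "DEFAULT_CONSTANTS",
    "PLAUSIBLE_ELP_WINDOW",
    "mean_corneal_power",
    "spectacle_to_cornea",
    "cornea_to_spectacle",
    "emmetropic_iol_power",
    "iol_power_for_refraction",
    "predict_refraction",
    "back_calculate_elp",
]

#: Anatomically plausible pseudophakic lens-position window (mm).
PLAUSIBLE_ELP_WINDOW = (1.5, 8.0)

_EPS = 1e-9  # mm; degenerate-denominator threshold


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices and vertex distance shared by all vergence computations.

    Parameters
    ----------
    n_aq : float
        Refractive index of the aqueous humor (in front of the IOL).
    n_vit : float
        Refractive index of the vitreous humor (behind the IOL).
    vertex_distance : float
        Spectacle vertex distance ``b`` in **metres** (default 12 mm).

    The default 1.336 for both indices is the standard pseudophakic
    convention; classical comparator formulas override pieces of this via
    their own published internal constants.
    """

    n_aq: float = 1.336
    n_vit: float = 1.336
    vertex_distance: float = 0.012

    def __post_init__(self) -> None:
        if not 1.2 < self.n_aq < 1.5:
            raise ValidationError("n_aq", f"must be in (1.2, 1.5), got {self.n_aq}")
        if not 1.2 < self.n_vit < 1.5:
            raise ValidationError("n_vit", f"must be in (1.2, 1.5), got {self.n_vit}")
        if not 0 < self.vertex_distance < 0.02:
            raise ValidationError(
                "vertex_distance",
                f"must be in (0, 0.02) metres, got {self.vertex_distance}",
            )


DEFAULT_CONSTANTS = OpticalConstants()


def _check_range(name: str, value, lo: float, hi: float) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(name, "must be finite")
    if np.any(arr <= lo) or np.any(arr >= hi):
        raise ValidationError(name, f"must be in ({lo}, {hi})")
    return arr


def mean_corneal_power(k_flat, k_steep):
    """Mean keratometry ``K = (K1 + K2) / 2`` in diopters.

    Both readings must lie in the physiological (30, 60) D range; the flat /
    steep roles are fixed by argument name, ``k_flat <= k_steep`` is not
    enforced (values are stored as measured).
    """
    k1 = _check_range("k_flat", k_flat, 30.0, 60.0)
    k2 = _check_range("k_steep", k_steep, 30.0, 60.0)
    out = (k1 + k2) / 2.0
    return float(out) if out.ndim == 0 else out


def spectacle_to_cornea(rx, vertex_distance: float = 0.012):
    """Move a spectacle-plane refraction to the corneal plane: ``S = Rx / (1 - b Rx)``."""
    rx = np.asarray(rx, dtype=float)
    den = 1.0 - vertex_distance * rx
    if np.any(np.abs(den) < 1e-9):
        raise SingularGeometryError("vertex singularity: 1 - b*Rx is numerically zero")
    out = rx / den
    return float(out) if out.ndim == 0 else out


def cornea_to_spectacle(s, vertex_distance: float = 0.012):
    """Inverse of :func:`spectacle_to_cornea`: ``Rx = S / (1 + b S)``."""
    s = np.asarray(s, dtype=float)
    den = 1.0 + vertex_distance * s
    if np.any(np.abs(den) < 1e-9):
        raise SingularGeometryError("vertex singularity: 1 + b*S is numerically zero")
    out = s / den
    return float(out) if out.ndim == 0 else out


def _vergence_power(al, elp, pc_eff, constants: OpticalConstants):
    """Core two-lens vergence chain (corneal power already at the corneal plane)."""
    na, nv = 1000.0 * constants.n_aq, 1000.0 * constants.n_vit
    den1 = al - elp
    den2 = na / pc_eff - elp
    if np.any(np.abs(den1) < _EPS) or np.any(np.abs(den2) < _EPS):
        raise SingularGeometryError(
            "degenerate vergence denominator (ELP coincides with axial length "
            "or with the corneal focal plane)"
        )
    return nv / den1 - na / den2


def emmetropic_iol_power(al, elp, pc, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """IOL power (D) that makes the eye emmetropic for a lens at depth ``elp``.

    Parameters are the axial length ``al`` (mm), the effective lens position
    ``elp`` (mm) and the corneal power ``pc`` (D).
    """
    al = np.asarray(al, dtype=float)
    elp = np.asarray(elp, dtype=float)
    pc = np.asarray(pc, dtype=float)
    if np.any(pc <= 0):
        raise ValidationError("pc", "corneal power must be positive")
    if np.any(elp >= al):
        raise SingularGeometryError("elp must be smaller than the axial length")
    out = _vergence_power(al, elp, pc, constants)
    return float(out) if out.ndim == 0 else out


def iol_power_for_refraction(
    al, elp, pc, rx=0.0, constants: OpticalConstants = DEFAULT_CONSTANTS
):
    """IOL power (D) that leaves the eye at target refraction ``rx`` (spectacle plane).

    At ``rx = 0`` this reduces exactly to :func:`emmetropic_iol_power`.
    """
    s = spectacle_to_cornea(rx, constants.vertex_distance)
    return emmetropic_iol_power(al, elp, np.asarray(pc, dtype=float) + s, constants)


def predict_refraction(
    al, elp, pc, power, constants: OpticalConstants = DEFAULT_CONSTANTS
):
    """Spectacle-plane refraction (D) left by an IOL of given ``power`` at depth ``elp``.

    Closed-form inversion of :func:`iol_power_for_refraction` in ``Rx``:
    the post-IOL vergence requirement gives ``z = 1000 n_vit/(AL-d) - P``,
    chaining back through the IOL plane yields the corneal-plane refraction
    ``S`` and the vertex transform returns it to the spectacle plane.
    """
    al = np.asarray(al, dtype=float)
    elp = np.asarray(elp, dtype=float)
    pc = np.asarray(pc, dtype=float)
    power = np.asarray(power, dtype=float)
    if np.any(elp >= al):
        raise SingularGeometryError("elp must be smaller than the axial length")
    na, nv = 1000.0 * constants.n_aq, 1000.0 * constants.n_vit
    z = nv / (al - elp) - power  # vergence entering the IOL plane
    if np.any(np.abs(z) < _EPS):
        raise SingularGeometryError(
            "post-IOL vergence is zero: power exactly cancels the axial vergence"
        )
    t = na / z + elp  # distance (mm) from cornea to the required object plane
    if np.any(np.abs(t) < _EPS):
        raise SingularGeometryError("corneal vergence stage degenerate (t = 0)")
    s = na / t - pc  # corneal-plane refractive error
    out = cornea_to_spectacle(s, constants.vertex_distance)
    return float(out) if np.ndim(out) == 0 else out


def back_calculate_elp(
    al,
    pc,
    power,
    rx_achieved,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    window: tuple[float, float] = PLAUSIBLE_ELP_WINDOW,
    on_failure: str = "raise",
):
    """Lens position ``d`` (mm) consistent with an observed post-operative refraction.

    Expanding the vergence relation in ``d`` gives the quadratic

        P d^2 + [n'_vit - n'_aq - P (AL + q)] d
              + [P AL q - n'_vit q + n'_aq AL] = 0,

    with ``q = 1000 n_aq / (Pc + S)``, ``S`` the corneal-plane refraction and
    primes denoting the ``x1000`` scaling.  The anatomically plausible root
    inside ``window`` is returned; if both roots fall inside, the one closer
    to 5.0 mm is chosen and an :class:`AmbiguousRootWarning` is issued.

    ``on_failure`` controls rows with no plausible real root: ``"raise"``
    (default) raises :class:`NoSolutionError`, ``"nan"`` returns NaN for the
    failing elements (used when auditing whole cohorts).
    """
    if on_failure not in ("raise", "nan"):
        raise ValueError("on_failure must be 'raise' or 'nan'")
    al = np.atleast_1d(np.asarray(al, dtype=float))
    pc = np.atleast_1d(np.asarray(pc, dtype=float))
    power = np.atleast_1d(np.asarray(power, dtype=float))
    rx = np.atleast_1d(np.asarray(rx_achieved, dtype=float))
    al, pc, power, rx = np.broadcast_arrays(al, pc, power, rx)
    scalar = al.ndim == 1 and al.size == 1 and np.ndim(rx_achieved) == 0

    if np.any(power == 0):
        raise NoSolutionError("P = 0: the quadratic degenerates, no IOL to locate")

    na, nv = 1000.0 * constants.n_aq, 1000.0 * constants.n_vit
    s = spectacle_to_cornea(rx, constants.vertex_distance)
    q = na / (pc + s)

    a = power.astype(float)
    b = nv - na - power * (al + q)
    c = power * al * q - nv * q + na * al

    disc = b * b - 4 * a * c
    lo, hi = window
    d_out = np.full(al.shape, np.nan)
    bad = disc < 0
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(np.where(bad, np.nan, disc))
        r1 = (-b - sq) / (2 * a)
        r2 = (-b + sq) / (2 * a)
    in1 = (~bad) & (r1 > lo) & (r1 < hi)
    in2 = (~bad) & (r2 > lo) & (r2 < hi)
    both = in1 & in2
    if np.any(both):
        warnings.warn(
            f"{int(both.sum())} back-calculation(s) had two anatomically "
            f"plausible roots; chose the root closer to 5.0 mm",
            AmbiguousRootWarning,
            stacklevel=2,
        )
    d_out[in1] = r1[in1]
    d_out[in2] = r2[in2]
    pick_r1 = both & (np.abs(r1 - 5.0) <= np.abs(r2 - 5.0))
    d_out[pick_r1] = r1[pick_r1]

    failed = ~(in1 | in2)
    if np.any(failed) and on_failure == "raise":
        raise NoSolutionError(
            f"{int(failed.sum())} back-calculation(s) had no real root in the "
            f"plausible window ({lo}, {hi}) mm"
        )
    return float(d_out[0]) if scalar else d_out
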