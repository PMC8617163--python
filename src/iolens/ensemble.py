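"""The MM formula: ensemble regression of the effective lens position.

Instead of the single ad-hoc linear ELP model of the classical formulas,
the MM formula trains an ensemble of regression trees mapping the four
pre-operative predictors

    (K1 flat keratometry, K2 steep keratometry, pre-operative ACD, AL)

to the effective lens position, then plugs the predicted ELP into the same
thin-lens vergence chain (:mod:`iolens.optics`) to predict refraction or
recommend an IOL power.  Training targets are lens positions back-calculated
from retrospective outcomes (implanted power + achieved refraction).

The ensemble effectively stores a very large number of implicit lens
constants per lens model; fitting is deterministic given (hyperparameters,
seed) and fitted models persist to disk with a version guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor, GradientBoostingRegressor
from sklearn.tree import DecisionTreeRegressor

from . import optics
from .errors import ClampWarning, DataQualityError, ModelStateError, ValidationError
from .optics import DEFAULT_CONSTANTS, PLAUSIBLE_ELP_WINDOW, OpticalConstants

__all__ = [
    "FEATURE_COLUMNS",
    "DEFAULT_HYPERPARAMS",
    "MODEL_FORMAT_VERSION",
    "build_training_table",
    "ELPEnsembleModel",
    "ELPEnsembleResults",
]

#: Predictor order expected by every fitted model.
FEATURE_COLUMNS = ("k1_d", "k2_d", "acd_mm", "al_mm")

#: Default ensemble for ~150-300-eye tabular cohorts: an ordinary
#: least-squares baseline in the four predictors plus gradient-boosted
#: trees on its residuals, with early stopping so the tree stage only
#: spends capacity where a reproducible non-linear signal exists.  The
#: back-calculated ELP targets carry ~0.3 mm of propagated refraction
#: noise, so the tree stage is deliberately shallow and strongly
#: regularized; the linear baseline keeps the variance floor at the level
#: of a classical linear ELP model.
DEFAULT_HYPERPARAMS = {
    "family": "gbrt_linear",
    "n_estimators": 300,
    "max_depth": 2,
    "learning_rate": 0.05,
    "subsample": 0.8,
    "min_samples_leaf": 20,
    "early_stopping": True,
}

MODEL_FORMAT_VERSION = "iolens-elp-1"


def build_training_table(
    cohort: pd.DataFrame,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    max_failure_fraction: float = 0.20,
):
    """Back-calculate per-eye ELP targets from retrospective outcomes.

    Returns ``(features, targets, audit)`` where ``features`` is a frame
    with :data:`FEATURE_COLUMNS`, ``targets`` the back-calculated lens
    positions (mm) and ``audit`` counts rows dropped because the
    back-calculation had no anatomically plausible solution.  More than
    ``max_failure_fraction`` of failures raises :class:`DataQualityError`.
    """
    k_mean = optics.mean_corneal_power(
        cohort["k1_d"].to_numpy(float), cohort["k2_d"].to_numpy(float)
    )
    d = optics.back_calculate_elp(
        cohort["al_mm"].to_numpy(float),
        k_mean,
        cohort["iol_power_d"].to_numpy(float),
        cohort["postop_se_d"].to_numpy(float),
        constants,
        on_failure="nan",
    )
    ok = np.isfinite(d)
    n_failed = int((~ok).sum())
    if len(cohort) and n_failed / len(cohort) > max_failure_fraction:
        raise DataQualityError(
            f"{n_failed}/{len(cohort)} eyes failed ELP back-calculation "
            f"(> {max_failure_fraction:.0%})"
        )
    features = cohort.loc[ok, list(FEATURE_COLUMNS)].reset_index(drop=True)
    audit = {"n_input": int(len(cohort)), "n_used": int(ok.sum()), "n_failed": n_failed}
    return features, d[ok], audit


class LinearBoostedTrees:
    """Ensemble of regression models: OLS baseline + boosted-tree residuals.

    The linear stage fits ELP on ``(1, K1, K2, ACD, AL)`` by least squares;
    a gradient-boosted tree stage then models its residuals.  With early
    stopping the tree stage degenerates gracefully to (almost) nothing when
    the residuals are pure noise, so the ensemble never does worse than the
    linear model it nests by more than estimation noise.
    """

    def __init__(self, seed: int = 0, **hp):
        self.seed = seed
        self.hp = hp

    def _tree_stage(self) -> GradientBoostingRegressor:
        extra = (
            {"n_iter_no_change": 10, "validation_fraction": 0.15}
            if self.hp.get("early_stopping", True)
            else {}
        )
        return GradientBoostingRegressor(
            n_estimators=self.hp.get("n_estimators", 300),
            max_depth=self.hp.get("max_depth", 2),
            learning_rate=self.hp.get("learning_rate", 0.05),
            subsample=self.hp.get("subsample", 0.8),
            min_samples_leaf=self.hp.get("min_samples_leaf", 20),
            loss=self.hp.get("loss", "squared_error"),
            random_state=self.seed,
            **extra,
        )

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        design = np.column_stack([np.ones(len(x)), x])
        self.coef_, *_ = np.linalg.lstsq(design, np.asarray(y, dtype=float), rcond=None)
        self.tree_stage_ = self._tree_stage()
        self.tree_stage_.fit(x, y - design @ self.coef_)
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        design = np.column_stack([np.ones(len(x)), x])
        return design @ self.coef_ + self.tree_stage_.predict(x)


def _make_estimator(hyperparams: dict, seed: int):
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    family = hp.pop("family")
    if family == "gbrt_linear":
        return LinearBoostedTrees(seed, **hp)
    if family == "gbrt":
        return GradientBoostingRegressor(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"],
            subsample=hp["subsample"],
            min_samples_leaf=hp.get("min_samples_leaf", 1),
            loss=hp.get("loss", "squared_error"),
            random_state=seed,
        )
    if family == "bagging":
        return BaggingRegressor(
            estimator=DecisionTreeRegressor(max_depth=hp.get("max_depth") or None),
            n_estimators=hp["n_estimators"],
            random_state=seed,
        )
    raise ValidationError("family", f"unknown ensemble family {family!r}")


@dataclass
class TrainingSummary:
    n: int
    target_mean: float
    target_sd: float
    n_failed_backcalc: int = 0


class ELPEnsembleModel:
    """Unfitted MM ensemble bound to a training table.

    Parameters
    ----------
    features : DataFrame
        One row per eye with columns :data:`FEATURE_COLUMNS`.
    targets : array-like
        Back-calculated effective lens positions (mm), all inside the
        plausible window.
    hyperparams : dict, optional
        Overrides of :data:`DEFAULT_HYPERPARAMS` (including ``family``:
        ``"gbrt"`` or ``"bagging"``).  Fixed at construction, never tuned
        per fold.
    min_rows : int
        Training floor; below it, fitting refuses and advises a
        Haigis-style linear model instead.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        targets,
        hyperparams: Optional[dict] = None,
        lens_model: str = "",
        min_rows: int = 50,
        constants: OpticalConstants = DEFAULT_CONSTANTS,
    ):
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise ValidationError("features", f"missing columns {missing}")
        self.features = features[list(FEATURE_COLUMNS)].reset_index(drop=True)
        self.targets = np.asarray(targets, dtype=float)
        if len(self.features) != len(self.targets):
            raise ValidationError("targets", "length mismatch with features")
        lo, hi = PLAUSIBLE_ELP_WINDOW
        if self.targets.size and (self.targets.min() <= lo or self.targets.max() >= hi):
            raise ValidationError("targets", f"ELP targets must lie in ({lo}, {hi}) mm")
        if len(self.features) < min_rows:
            raise ValidationError(
                "features",
                f"{len(self.features)} rows < floor {min_rows}; too few eyes for an "
                "ensemble — fall back to a Haigis-style linear ELP model",
            )
        self.hyperparams = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
        self.lens_model = lens_model
        self.constants = constants
        self.audit: dict = {}

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        constants: OpticalConstants = DEFAULT_CONSTANTS,
        hyperparams: Optional[dict] = None,
        min_rows: int = 50,
    ) -> "ELPEnsembleModel":
        features, targets, audit = build_training_table(cohort, constants)
        lens_model = (
            str(cohort["lens_model"].iloc[0]) if "lens_model" in cohort and len(cohort) else ""
        )
        model = cls(features, targets, hyperparams, lens_model, min_rows, constants)
        model.audit = audit
        return model

    def fit(self, seed: int = 0) -> "ELPEnsembleResults":
        est = _make_estimator(self.hyperparams, seed)
        est.fit(self.features.to_numpy(float), self.targets)
        summary = TrainingSummary(
            n=len(self.targets),
            target_mean=float(np.mean(self.targets)),
            target_sd=float(np.std(self.targets, ddof=1)),
            n_failed_backcalc=int(self.audit.get("n_failed", 0)),
        )
        return ELPEnsembleResults(
            estimator=est,
            hyperparams=dict(self.hyperparams),
            lens_model=self.lens_model,
            train_seed=seed,
            training_summary=summary,
            constants=self.constants,
        )


@dataclass
class ELPEnsembleResults:
    """A fitted MM model: deterministic ELP predictor + vergence optics."""

    estimator: object
    hyperparams: dict
    lens_model: str
    train_seed: int
    training_summary: TrainingSummary
    constants: OpticalConstants = DEFAULT_CONSTANTS
    version: str = MODEL_FORMAT_VERSION
    clamp_window: tuple = PLAUSIBLE_ELP_WINDOW

    # -- feature plumbing ---------------------------------------------------
    @staticmethod
    def _feature_matrix(x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            missing = [c for c in FEATURE_COLUMNS if c not in x.columns]
            if missing:
                raise ValidationError("features", f"missing columns {missing}")
            mat = x[list(FEATURE_COLUMNS)].to_numpy(float)
        else:
            mat = np.atleast_2d(np.asarray(x, dtype=float))
        if mat.shape[1] != len(FEATURE_COLUMNS):
            raise ValidationError("features", f"expected {len(FEATURE_COLUMNS)} columns")
        if not np.all(np.isfinite(mat)):
            raise ValidationError("features", "all four predictors must be finite")
        return mat

    def predict_elp(self, features, return_clamp_flag: bool = False):
        """Predicted effective lens position (mm), clamped to the plausible window."""
        if self.estimator is None:
            raise ModelStateError("model has no fitted estimator")
        mat = self._feature_matrix(features)
        raw = np.asarray(self.estimator.predict(mat), dtype=float)
        lo, hi = self.clamp_window
        clamped = (raw < lo) | (raw > hi)
        if np.any(clamped):
            warnings.warn(
                f"{int(clamped.sum())} ELP prediction(s) clamped to ({lo}, {hi}) mm",
                ClampWarning,
                stacklevel=2,
            )
        out = np.clip(raw, lo, hi)
        if return_clamp_flag:
            return out, clamped
        return out

    def _geometry(self, cohort: pd.DataFrame):
        elp = self.predict_elp(cohort)
        k_mean = optics.mean_corneal_power(
            cohort["k1_d"].to_numpy(float), cohort["k2_d"].to_numpy(float)
        )
        return cohort["al_mm"].to_numpy(float), elp, k_mean

    # -- optics closure -----------------------------------------------------
    def predict_refraction(self, cohort: pd.DataFrame, power=None):
        """Predicted spectacle-plane refraction for each eye, given implanted power."""
        al, elp, k_mean = self._geometry(cohort)
        if power is None:
            power = cohort["iol_power_d"].to_numpy(float)
        return optics.predict_refraction(al, elp, k_mean, power, self.constants)

    def recommend_power(self, cohort: pd.DataFrame, target_rx: float = 0.0, step: float = 0.5):
        """IOL power for a target refraction, rounded to the manufacturing step.

        Returns ``(rounded, raw)`` so the pre-rounding value stays available.
        """
        al, elp, k_mean = self._geometry(cohort)
        raw = optics.iol_power_for_refraction(al, elp, k_mean, target_rx, self.constants)
        raw = np.asarray(raw, dtype=float)
        return np.round(raw / step) * step, raw

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        joblib.dump(
            {
                "version": self.version,
                "estimator": self.estimator,
                "hyperparams": self.hyperparams,
                "lens_model": self.lens_model,
                "train_seed": self.train_seed,
                "training_summary": self.training_summary,
                "constants": self.constants,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ELPEnsembleResults":
        payload = joblib.load(path)
        if payload.get("version") != MODEL_FORMAT_VERSION:
            raise ModelStateError(
                f"model file version {payload.get('version')!r} is incompatible "
                f"with {MODEL_FORMAT_VERSION!r}"
            )
        return cls(
            estimator=payload["estimator"],
            hyperparams=payload["hyperparams"],
            lens_model=payload["lens_model"],
            train_seed=payload["train_seed"],
            training_summary=payload["training_summary"],
            constants=payload["constants"],
        )

    def summary(self) -> str:
        ts = self.training_summary
        hp = ", ".join(f"{k}={v}" for k, v in sorted(self.hyperparams.items()))
        return "\n".join(
            [
                "MM formula — fitted ELP ensemble",
                "=" * 40,
                f"lens model         : {self.lens_model or '(unspecified)'}",
                f"ensemble           : {hp}",
                f"train seed         : {self.train_seed}",
                f"n (training eyes)  : {ts.n}",
                f"ELP target mean/sd : {ts.target_mean:.3f} / {ts.target_sd:.3f} mm",
                f"back-calc failures : {ts.n_failed_backcalc}",
                f"clamp window (mm)  : {self.clamp_window}",
            ]
        )
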