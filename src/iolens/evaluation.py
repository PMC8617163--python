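"""Monte-Carlo cross-validation benchmark and prediction-error metrics.

The benchmark repeats a random train/test split ``k`` times; within every
repetition the four classical formulas have their lens constants
re-optimized *and* the MM ensemble is re-trained on the same training
split, so no information leaks from test eyes into any formula.  Held-out
prediction errors are accumulated across repetitions (one eye can appear
in several repetitions' test sets), matching the accumulated-sample
convention of cross-validated formula comparisons; the last-repetition-only
alternative is available behind a flag.

Prediction error is ``PE = achieved - predicted`` refraction (positive =
hyperopic surprise).  Metrics are reported per formula and per axial-length
stratum: short (AL < 22), medium (22 <= AL <= 24.5), long-medium
(24.5 < AL <= 26), long (AL > 26) and all eyes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from . import classical, ensemble
from .classical import CLASSICAL_FORMULAE, Formula
from .errors import ClampWarning, CrossValidationError, ValidationError
from .optics import DEFAULT_CONSTANTS, OpticalConstants

__all__ = [
    "CVConfig",
    "AL_STRATA",
    "PE_BANDS",
    "prediction_error",
    "stratum_of",
    "stratify_by_axial_length",
    "monte_carlo_crossval",
    "MetricsSummary",
    "compute_metrics",
    "metrics_frame",
    "FormulaBenchmark",
    "BenchmarkResults",
]

logger = logging.getLogger(__name__)

#: Axial-length strata: label -> (low, high, low_closed, high_closed), mm.
AL_STRATA = {
    "short": (-np.inf, 22.0, False, False),
    "medium": (22.0, 24.5, True, True),
    "long_medium": (24.5, 26.0, False, True),
    "long": (26.0, np.inf, False, False),
}

#: Accuracy bands (D) for "% of eyes within +/- x D" (closed bands).
PE_BANDS = (0.5, 1.0, 1.5)

ALL_FORMULAE = CLASSICAL_FORMULAE + (Formula.MM,)


@dataclass(frozen=True)
class CVConfig:
    """Monte-Carlo cross-validation settings.

    ``k`` repetitions of a random ``test_fraction`` holdout; all formulas
    in ``formulae`` are refit per repetition.  ``accumulate=False`` keeps
    only the final repetition's records instead of pooling all of them.
    """

    k: int = 100
    test_fraction: float = 0.20
    seed: int = 0
    formulae: tuple = ALL_FORMULAE
    accumulate: bool = True
    min_cohort: int = 30
    min_rows_mm: int = 50
    haigis_mode: str = "full"
    hyperparams: Optional[dict] = None
    max_failed_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k", "must be >= 1")
        if not 0 < self.test_fraction < 0.5:
            raise ValidationError("test_fraction", "must be in (0, 0.5)")
        object.__setattr__(self, "formulae", tuple(Formula(f) for f in self.formulae))


def prediction_error(achieved_se, predicted_rx):
    """``PE = achieved - predicted`` (D); positive means a hyperopic surprise."""
    achieved = np.asarray(achieved_se, dtype=float)
    predicted = np.asarray(predicted_rx, dtype=float)
    if not (np.all(np.isfinite(achieved)) and np.all(np.isfinite(predicted))):
        raise ValidationError("prediction_error", "inputs must be finite")
    out = achieved - predicted
    return float(out) if out.ndim == 0 else out


def stratum_of(al) -> np.ndarray:
    """Vectorized stratum label for axial length(s)."""
    al = np.atleast_1d(np.asarray(al, dtype=float))
    out = np.empty(al.shape, dtype=object)
    for label, (lo, hi, lo_closed, hi_closed) in AL_STRATA.items():
        ge = al >= lo if lo_closed else al > lo
        le = al <= hi if hi_closed else al < hi
        out[ge & le] = label
    return out


def stratify_by_axial_length(cohort: pd.DataFrame, al_column: str = "al_mm") -> dict:
    """Partition a frame by axial-length stratum; also returns the 'all' view."""
    labels = stratum_of(cohort[al_column].to_numpy(float))
    out = {
        label: cohort.loc[labels == label].reset_index(drop=True) for label in AL_STRATA
    }
    out["all"] = cohort.reset_index(drop=True)
    return out


def _fit_all(
    train: pd.DataFrame, config: CVConfig, constants: OpticalConstants, fit_seed: int
):
    fitted = {}
    for formula in config.formulae:
        if formula is Formula.MM:
            model = ensemble.ELPEnsembleModel.from_cohort(
                train,
                constants,
                hyperparams=config.hyperparams,
                min_rows=config.min_rows_mm,
            )
            fitted[formula] = model.fit(seed=fit_seed)
        else:
            fitted[formula] = classical.optimize_constants(
                formula, train, config.min_cohort, config.haigis_mode
            )
    return fitted


def _predict(formula: Formula, fitted, test: pd.DataFrame):
    power = test["iol_power_d"].to_numpy(float)
    if formula is Formula.MM:
        return fitted.predict_refraction(test, power)
    return classical.predict_refraction_classical(
        formula,
        test["al_mm"].to_numpy(float),
        test["k1_d"].to_numpy(float),
        test["k2_d"].to_numpy(float),
        test["acd_mm"].to_numpy(float),
        fitted,
        power,
    )


def monte_carlo_crossval(
    cohort: pd.DataFrame,
    config: CVConfig = CVConfig(),
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Run the benchmark; returns the accumulated per-eye prediction records.

    Columns: ``eye_id, formula, fold, al_mm, predicted_rx, achieved_rx, pe``.
    A repetition that fails (e.g. an optimization cannot bracket a root on
    an extreme split) is skipped and audited; more than
    ``config.max_failed_fraction`` of failed repetitions aborts the run.
    """
    cohort = cohort.reset_index(drop=True)
    n = len(cohort)
    n_test = max(1, int(round(n * config.test_fraction)))
    if n - n_test < max(config.min_cohort, config.min_rows_mm):
        raise ValidationError(
            "cohort", "training split smaller than the formula fitting floors"
        )
    rng = np.random.default_rng(config.seed)
    chunks: list[pd.DataFrame] = []
    n_failed = 0
    for fold in range(config.k):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        fit_seed = int(rng.integers(0, 2**31 - 1))
        train = cohort.iloc[train_idx]
        test = cohort.iloc[test_idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ClampWarning)
                fitted = _fit_all(train, config, constants, fit_seed)
                records = []
                for formula in config.formulae:
                    predicted = np.asarray(
                        _predict(formula, fitted[formula], test), dtype=float
                    )
                    achieved = test["postop_se_d"].to_numpy(float)
                    records.append(
                        pd.DataFrame(
                            {
                                "eye_id": test["id"].to_numpy(),
                                "formula": formula.value,
                                "fold": fold,
                                "al_mm": test["al_mm"].to_numpy(float),
                                "predicted_rx": predicted,
                                "achieved_rx": achieved,
                                "pe": prediction_error(achieved, predicted),
                            }
                        )
                    )
        except Exception as exc:  # noqa: BLE001 - audited, bounded below
            n_failed += 1
            logger.warning("fold %d failed: %s", fold, exc)
            continue
        chunk = pd.concat(records, ignore_index=True)
        logger.info(
            "fold %d: n_train=%d n_test=%d formulas=%d",
            fold,
            len(train),
            len(test),
            len(config.formulae),
        )
        if config.accumulate:
            chunks.append(chunk)
        else:
            chunks = [chunk]
    if n_failed / config.k > config.max_failed_fraction:
        raise CrossValidationError(
            f"{n_failed}/{config.k} Monte-Carlo repetitions failed"
        )
    out = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame()
    out.attrs["n_failed_folds"] = n_failed
    return out


@dataclass
class MetricsSummary:
    """Prediction-error metrics for one formula in one stratum."""

    n: int
    mpe: float
    sd: float
    medpe: float
    range_pe: tuple
    mae: float
    mae_sd: float
    medae: float
    pct_within: dict = dc_field(default_factory=dict)

    @classmethod
    def from_errors(cls, pe) -> "MetricsSummary":
        pe = np.asarray(pe, dtype=float)
        if pe.size == 0:
            raise ValidationError("pe", "cannot summarize an empty cell")
        ae = np.abs(pe)
        sd = float(np.std(pe, ddof=1)) if pe.size > 1 else 0.0
        ae_sd = float(np.std(ae, ddof=1)) if pe.size > 1 else 0.0
        return cls(
            n=int(pe.size),
            mpe=float(np.mean(pe)),
            sd=sd,
            medpe=float(np.median(pe)),
            range_pe=(float(pe.min()), float(pe.max())),
            mae=float(np.mean(ae)),
            mae_sd=ae_sd,
            medae=float(np.median(ae)),
            pct_within={b: float(100.0 * np.mean(ae <= b)) for b in PE_BANDS},
        )


def compute_metrics(records: pd.DataFrame) -> dict:
    """Map ``(formula, stratum) -> MetricsSummary`` from accumulated records.

    Empty cells (no eyes in a stratum) are simply absent from the result.
    """
    out: dict = {}
    strata = stratify_by_axial_length(records)
    for stratum, sub in strata.items():
        for formula, grp in sub.groupby("formula", sort=False):
            if len(grp):
                out[(formula, stratum)] = MetricsSummary.from_errors(grp["pe"])
    return out


def metrics_frame(metrics: dict) -> pd.DataFrame:
    """Tidy one-row-per-(formula, stratum) view of :func:`compute_metrics` output."""
    rows = []
    for (formula, stratum), m in metrics.items():
        row = {
            "formula": formula,
            "stratum": stratum,
            "n": m.n,
            "mpe": m.mpe,
            "sd": m.sd,
            "medpe": m.medpe,
            "pe_min": m.range_pe[0],
            "pe_max": m.range_pe[1],
            "mae": m.mae,
            "mae_sd": m.mae_sd,
            "medae": m.medae,
        }
        for b, pct in m.pct_within.items():
            row[f"pct_within_{b}"] = pct
        rows.append(row)
    order = {f.value: i for i, f in enumerate(ALL_FORMULAE)}
    strat_order = {s: i for i, s in enumerate(list(AL_STRATA) + ["all"])}
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(
            ["stratum", "formula"],
            key=lambda col: col.map(strat_order if col.name == "stratum" else order),
        ).reset_index(drop=True)
    return frame


class FormulaBenchmark:
    """Benchmark model: a cohort plus a CV configuration.

    ``fit()`` runs the Monte-Carlo cross-validation and returns a
    :class:`BenchmarkResults` carrying the accumulated prediction records,
    the metric tables and the statistical comparison battery.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        config: CVConfig = CVConfig(),
        constants: OpticalConstants = DEFAULT_CONSTANTS,
    ):
        self.cohort = cohort.reset_index(drop=True)
        self.config = config
        self.constants = constants

    def fit(self) -> "BenchmarkResults":
        records = monte_carlo_crossval(self.cohort, self.config, self.constants)
        return BenchmarkResults(self, records)


class BenchmarkResults:
    """Accumulated cross-validation records with metric and test accessors."""

    def __init__(self, model: FormulaBenchmark, records: pd.DataFrame):
        self.model = model
        self.records = records

    def metrics(self) -> dict:
        return compute_metrics(self.records)

    def metrics_frame(self) -> pd.DataFrame:
        return metrics_frame(self.metrics())

    def paired_table(self, value: str = "abs_pe", stratum: str = "all") -> pd.DataFrame:
        """Wide (eye, fold) x formula table of |PE| or PE, paired across formulas."""
        rec = self.records
        if stratum != "all":
            rec = rec.loc[stratum_of(rec["al_mm"].to_numpy(float)) == stratum]
        col = rec["pe"].abs() if value == "abs_pe" else rec["pe"]
        wide = rec.assign(_v=col).pivot_table(
            index=["eye_id", "fold"], columns="formula", values="_v", aggfunc="first"
        )
        wide = wide.dropna()
        return wide[[f.value for f in self.model.config.formulae]]

    def compare_absolute_errors(self, stratum: str = "all"):
        from . import stats

        return stats.compare_absolute_errors(self.paired_table("abs_pe", stratum))

    def compare_accuracy(self, band: float = 0.5, stratum: str = "all"):
        from . import stats

        table = self.paired_table("abs_pe", stratum)
        return stats.compare_accuracy((table <= band).astype(int), band)

    def summary(self) -> str:
        frame = self.metrics_frame()
        lines = [
            "Monte-Carlo cross-validation benchmark",
            "=" * 46,
            f"cohort eyes        : {len(self.model.cohort)}",
            f"repetitions (k)    : {self.model.config.k}",
            f"test fraction      : {self.model.config.test_fraction}",
            f"failed repetitions : {self.records.attrs.get('n_failed_folds', 0)}",
            "",
            frame.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
                columns=[
                    "formula",
                    "stratum",
                    "n",
                    "mpe",
                    "sd",
                    "medpe",
                    "mae",
                    "medae",
                    "pct_within_0.5",
                    "pct_within_1.0",
                    "pct_within_1.5",
                ],
            ),
        ]
        return "\n".join(lines)
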