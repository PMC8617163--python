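"""Non-parametric comparison battery for accumulated prediction errors.

Formula comparisons on clinical prediction errors are paired by eye and
the error distributions are heavy-tailed, so everything here is
rank/contingency based, evaluated at significance level 0.05:

* Shapiro-Wilk as the normality screen that justifies the battery;
* one-sample Wilcoxon signed-rank for "is the median error zero";
* Friedman across all formulas' absolute errors, then pairwise
  signed-rank tests of the reference (MM) formula against each comparator;
* Cochran's Q across the formulas' within-band accuracy indicators, then
  pairwise McNemar tests with an outperformed/underperformed direction
  label driven by the discordant counts.

Zero differences are dropped before signed-rank tests and tied absolute
values share average ranks; the exact signed-rank distribution is
enumerated for n <= 25 (ties included) and the tie-corrected normal
approximation is used above.  McNemar is the exact binomial test below 25
discordant pairs and the continuity-corrected chi-square otherwise.
P-values are reported unadjusted (a Holm flag is available for the
pairwise batteries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import cochrans_q, mcnemar

from .errors import DegenerateSampleError, ValidationError

__all__ = [
    "ALPHA",
    "TestReport",
    "normality_screen",
    "wilcoxon_signed_rank",
    "median_zero_test",
    "compare_absolute_errors",
    "compare_accuracy",
    "holm_adjust",
]

ALPHA = 0.05

EXACT_WILCOXON_MAX_N = 25
EXACT_MCNEMAR_MAX_DISCORDANT = 25


@dataclass
class TestReport:
    """One hypothesis-test outcome with its method bookkeeping."""

    test_name: str
    groups: tuple
    statistic: float
    p_value: float
    n: int
    method_detail: str
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value", f"{self.p_value} outside [0, 1]")

    @property
    def verdict(self) -> str:
        return "significant" if self.p_value < self.alpha else "not_significant"

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "groups": list(self.groups),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "method_detail": self.method_detail,
            **self.extra,
        }


def normality_screen(values, name: str = "sample") -> TestReport:
    """Shapiro-Wilk normality screen (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValidationError("values", f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample: normality is undefined")
    stat, p = sps.shapiro(x)
    return TestReport(
        "shapiro_wilk", (name,), float(stat), float(p), int(x.size), "exact (scipy)"
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact tie-aware enumeration
# ---------------------------------------------------------------------------


def _signed_ranks(diff: np.ndarray) -> np.ndarray:
    """Average ranks of |diff| (zeros already dropped)."""
    return sps.rankdata(np.abs(diff))


def _exact_signed_rank_p(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p for W+ by dynamic programming over doubled ranks.

    Average ranks are multiples of 1/2; doubling them makes every rank an
    integer so the distribution of 2*W+ under random sign flips is a
    polynomial convolution — exact even with ties.
    """
    ranks = _signed_ranks(diff)
    w_plus = float(ranks[diff > 0].sum())
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    # pmf over 2*W+ in units of 2^-n
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(2 * w_plus))
    p_le = float(pmf[: w2 + 1].sum())
    p_ge = float(pmf[w2:].sum())
    return w_plus, min(1.0, 2.0 * min(p_le, p_ge))


def _approx_signed_rank_p(diff: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie correction for W+."""
    ranks = _signed_ranks(diff)
    n = diff.size
    w_plus = float(ranks[diff > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        raise DegenerateSampleError("all absolute differences tied; variance is zero")
    z = (w_plus - mean) / np.sqrt(var)
    return w_plus, float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    x, y=None, groups: tuple = ("x", "y"), name: str = "wilcoxon_signed_rank"
) -> TestReport:
    """Two-sided signed-rank test of ``median(x - y) = 0`` (or ``median(x) = 0``).

    Exact zeros are dropped (Wilcoxon's original treatment); the exact
    distribution is enumerated for n <= 25 non-zero differences and the
    tie-corrected normal approximation is used above.
    """
    x = np.asarray(x, dtype=float)
    diff = x if y is None else x - np.asarray(y, dtype=float)
    if diff.size == 0:
        raise DegenerateSampleError("empty sample")
    diff = diff[diff != 0]
    if diff.size == 0:
        raise DegenerateSampleError("all differences are exactly zero")
    if diff.size <= EXACT_WILCOXON_MAX_N:
        stat, p = _exact_signed_rank_p(diff)
        detail = "exact (tie-aware enumeration)"
    else:
        stat, p = _approx_signed_rank_p(diff)
        detail = "asymptotic (normal, tie-corrected)"
    return TestReport(name, groups, stat, p, int(diff.size), detail)


def median_zero_test(pe_values, group: str = "pe") -> TestReport:
    """Is the median prediction error zero?  One-sample signed-rank test."""
    return wilcoxon_signed_rank(
        pe_values, None, groups=(group, "zero"), name="wilcoxon_median_zero"
    )


# ---------------------------------------------------------------------------
# omnibus + pairwise batteries
# ---------------------------------------------------------------------------


def _paired_frame(table, expected_binary: bool = False) -> pd.DataFrame:
    df = pd.DataFrame(table)
    if df.isna().any().any():
        raise ValidationError("table", "columns must be paired by eye with no gaps")
    if df.shape[1] < 2:
        raise ValidationError("table", "need at least two formula columns")
    if expected_binary:
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("table", "accuracy indicators must be 0/1")
    return df


def holm_adjust(reports: Sequence[TestReport]) -> None:
    """Holm step-down adjustment applied in place (records the raw p in extra)."""
    order = np.argsort([r.p_value for r in reports])
    m = len(reports)
    running = 0.0
    for rank, idx in enumerate(order):
        r = reports[idx]
        adj = min(1.0, (m - rank) * r.p_value)
        running = max(running, adj)
        r.extra["p_raw"] = r.p_value
        r.p_value = running
        r.method_detail += " + Holm"


def compare_absolute_errors(
    abs_pe_table, reference: str = "MM", holm: bool = False
) -> tuple[TestReport, list[TestReport]]:
    """Friedman omnibus over paired |PE| columns + reference-vs-each pairwise tests.

    ``abs_pe_table`` is a DataFrame with one column per formula, rows
    paired by eye.  Pairwise signed-rank tests compare ``reference``
    against every other column; p-values are unadjusted unless ``holm``.
    """
    df = _paired_frame(abs_pe_table)
    cols = list(df.columns)
    n = len(df)
    spread = np.ptp(df.to_numpy(), axis=1)
    if np.all(spread == 0):
        friedman = TestReport(
            "friedman", tuple(cols), 0.0, 1.0, n, "degenerate: identical columns"
        )
    else:
        stat, p = sps.friedmanchisquare(*[df[c] for c in cols])
        friedman = TestReport(
            "friedman", tuple(cols), float(stat), float(p), n, "asymptotic chi-square"
        )
    pairwise: list[TestReport] = []
    if reference in cols:
        for other in cols:
            if other == reference:
                continue
            try:
                rep = wilcoxon_signed_rank(
                    df[reference].to_numpy(),
                    df[other].to_numpy(),
                    groups=(reference, other),
                    name="wilcoxon_paired",
                )
            except DegenerateSampleError:
                rep = TestReport(
                    "wilcoxon_paired",
                    (reference, other),
                    0.0,
                    1.0,
                    n,
                    "degenerate: identical columns",
                )
            pairwise.append(rep)
        if holm:
            holm_adjust(pairwise)
    return friedman, pairwise


def _mcnemar_direction(ref_col, other_col, p: float) -> str:
    if p >= ALPHA:
        return "no_difference"
    return "mm_outperformed" if ref_col.sum() > other_col.sum() else "mm_underperformed"


def compare_accuracy(
    within_band_table, band: float, reference: str = "MM", holm: bool = False
) -> tuple[TestReport, list[TestReport]]:
    """Cochran's Q over paired 0/1 accuracy columns + pairwise McNemar tests.

    Each pairwise report carries the discordant counts ``b`` (reference
    accurate only) and ``c`` (comparator accurate only) and a direction
    label: ``no_difference`` when not significant, else
    ``mm_outperformed`` / ``mm_underperformed`` by which formula has the
    larger within-band count.
    """
    df = _paired_frame(within_band_table, expected_binary=True)
    cols = list(df.columns)
    n = len(df)
    if np.all(np.ptp(df.to_numpy(), axis=1) == 0):
        q_rep = TestReport(
            "cochrans_q", tuple(cols), 0.0, 1.0, n, "degenerate: identical columns",
            extra={"band": band},
        )
    else:
        res = cochrans_q(df.to_numpy())
        q_rep = TestReport(
            "cochrans_q",
            tuple(cols),
            float(res.statistic),
            float(res.pvalue),
            n,
            "asymptotic chi-square",
            extra={"band": band},
        )
    pairwise: list[TestReport] = []
    if reference in cols:
        ref = df[reference].to_numpy()
        for other in cols:
            if other == reference:
                continue
            oth = df[other].to_numpy()
            b = int(np.sum((ref == 1) & (oth == 0)))
            c = int(np.sum((ref == 0) & (oth == 1)))
            table = np.array(
                [
                    [np.sum((ref == 1) & (oth == 1)), b],
                    [c, np.sum((ref == 0) & (oth == 0))],
                ]
            )
            if b + c == 0:
                stat, p, detail = 0.0, 1.0, "degenerate: no discordant pairs"
            elif b + c < EXACT_MCNEMAR_MAX_DISCORDANT:
                res = mcnemar(table, exact=True)
                stat, p, detail = float(res.statistic), float(res.pvalue), "exact binomial"
            else:
                res = mcnemar(table, exact=False, correction=True)
                stat, p, detail = (
                    float(res.statistic),
                    float(res.pvalue),
                    "chi-square with continuity correction",
                )
            rep = TestReport(
                "mcnemar",
                (reference, other),
                stat,
                p,
                n,
                detail,
                extra={"band": band, "b": b, "c": c},
            )
            rep.extra["direction"] = _mcnemar_direction(df[reference], df[other], p)
            pairwise.append(rep)
        if holm:
            holm_adjust(pairwise)
            for rep in pairwise:
                rep.extra["direction"] = _mcnemar_direction(
                    df[reference], df[rep.groups[1]], rep.p_value
                )
    return q_rep, pairwise
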