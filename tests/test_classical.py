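"""Classical formulas: published-form oracles, self-consistency, optimization."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from iolens import classical, optics, synthetic
from iolens.classical import CLASSICAL_FORMULAE, Formula, LensConstantSet
from iolens.errors import ClampWarning, OptimizationError, ValidationError


# --- independent oracles: single-expression published forms ----------------


def srkt_power_oracle(al, k, a_constant, ref=0.0, v=12.0):
    """SRK/T power in the published closed form (different algebra from the
    package's generic vergence chain)."""
    na, ncm1 = 1.336, 0.333
    r = 337.5 / k
    lcor = al if al <= 24.2 else -3.446 + 1.716 * al - 0.0237 * al**2
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    h = r - np.sqrt(max(r**2 - cw**2 / 4.0, 0.0))
    acd_est = h + 0.62467 * a_constant - 68.747 - 3.336
    rethick = 0.65696 - 0.02029 * al
    lopt = al + rethick
    s1 = na * r - ncm1 * lopt
    s2 = lopt - acd_est
    s3 = na * r - ncm1 * acd_est
    num = 1000.0 * na * (s1 - 0.001 * ref * (v * s1 + lopt * r))
    den = s2 * (s3 - 0.001 * ref * (v * s3 + acd_est * r))
    return num / den


def hofferq_power_oracle(al, k, pacd, acd_est, rx=0.0):
    """Hoffer's published forward power formula (ELP supplied separately)."""
    r_corneal = rx / (1 - 0.012 * rx)
    return 1336.0 / (al - acd_est - 0.05) - 1336.0 / (
        1336.0 / (k + r_corneal) - (acd_est + 0.05)
    )


class TestELPEstimators:
    def test_haigis_linear_form(self):
        cs = LensConstantSet(Formula.HAIGIS, a0=0.4, a1=0.1, a2=0.1)
        elp = classical.estimate_elp(Formula.HAIGIS, 23.8, 43.0, 43.0, 3.2, cs)
        assert elp == pytest.approx(0.4 + 0.1 * 3.2 + 0.1 * 23.8)

    def test_haigis_constant_degenerate(self):
        cs = LensConstantSet(Formula.HAIGIS, a0=5.1, a1=0.0, a2=0.0)
        al = np.array([21.0, 24.0, 28.0])
        elp = classical.estimate_elp(Formula.HAIGIS, al, 43.0, 44.0, 3.2, cs)
        np.testing.assert_allclose(elp, 5.1)

    def test_haigis_requires_acd(self):
        cs = LensConstantSet(Formula.HAIGIS, a0=0.4, a1=0.1, a2=0.1)
        with pytest.raises(ValidationError, match="acd_mm"):
            classical.estimate_elp(Formula.HAIGIS, 23.8, 43.0, 43.0, np.nan, cs)

    def test_acd_invariance_except_haigis(self):
        """Only Haigis reacts to the pre-operative ACD; the other three are
        functions of (K, AL) alone."""
        acds = np.array([2.4, 3.2, 4.2])
        sets = {
            Formula.SRKT: LensConstantSet(Formula.SRKT, A_constant=118.4),
            Formula.HOFFERQ: LensConstantSet(Formula.HOFFERQ, pACD=5.2),
            Formula.HOLLADAY1: LensConstantSet(Formula.HOLLADAY1, SF=1.2),
            Formula.HAIGIS: LensConstantSet(Formula.HAIGIS, a0=0.9, a1=0.4, a2=0.1),
        }
        for formula, cs in sets.items():
            elp = classical.estimate_elp(formula, 23.8, 43.0, 43.9, acds, cs)
            if formula is Formula.HAIGIS:
                assert np.ptp(elp) > 0.5
            else:
                assert np.ptp(np.atleast_1d(elp)) == 0.0

    def test_hofferq_al_clamp_warns_not_raises(self):
        cs = LensConstantSet(Formula.HOFFERQ, pACD=5.2)
        with pytest.warns(ClampWarning):
            elp = classical.estimate_elp(Formula.HOFFERQ, np.array([17.0]), 43.0, 43.0, 3.2, cs)
        assert np.isfinite(elp).all()

    def test_constant_set_field_requirements(self):
        with pytest.raises(ValidationError, match="pACD"):
            LensConstantSet(Formula.HOFFERQ)
        with pytest.raises(ValidationError, match="a1"):
            LensConstantSet(Formula.HAIGIS, a0=1.0, a2=0.1)

    def test_constant_set_json_roundtrip(self):
        cs = LensConstantSet(Formula.HAIGIS, "SN60WF", a0=1.1, a1=0.35, a2=0.09)
        clone = LensConstantSet.from_dict(cs.to_dict())
        assert clone == cs


class TestAgainstPublishedForms:
    @pytest.mark.parametrize("al,k,a", [(23.8, 43.45, 118.4), (21.2, 46.0, 119.0), (27.5, 41.0, 118.0), (24.8, 44.2, 118.7)])
    def test_srkt_emmetropic_power_matches_oracle(self, al, k, a):
        cs = LensConstantSet(Formula.SRKT, A_constant=a)
        got = classical.power_for_target_classical(
            Formula.SRKT, al, k, k, 3.2, cs, 0.0
        )
        assert got == pytest.approx(srkt_power_oracle(al, k, a), abs=1e-9)

    @pytest.mark.parametrize("ref", [-1.0, -0.5, 0.5])
    def test_srkt_target_refraction_matches_oracle(self, ref):
        al, k, a = 23.8, 43.45, 118.4
        cs = LensConstantSet(Formula.SRKT, A_constant=a)
        got = classical.power_for_target_classical(Formula.SRKT, al, k, k, 3.2, cs, ref)
        assert got == pytest.approx(srkt_power_oracle(al, k, a, ref), abs=1e-6)

    def test_hofferq_worked_case_matches_oracle(self):
        al, k, pacd, p = 23.5, 43.5, 5.2, 20.5
        cs = LensConstantSet(Formula.HOFFERQ, pACD=pacd)
        elp = float(classical.estimate_elp(Formula.HOFFERQ, al, k, k, 3.2, cs))
        oracle_rx = brentq(
            lambda rx: hofferq_power_oracle(al, k, pacd, elp, rx) - p, -9, 9, xtol=1e-12
        )
        got = classical.predict_refraction_classical(Formula.HOFFERQ, al, k, k, 3.2, cs, p)
        assert got == pytest.approx(oracle_rx, abs=1e-9)

    @pytest.mark.parametrize("formula", CLASSICAL_FORMULAE)
    def test_self_consistency_power_then_refraction(self, formula):
        sets = {
            Formula.SRKT: LensConstantSet(Formula.SRKT, A_constant=118.4),
            Formula.HOFFERQ: LensConstantSet(Formula.HOFFERQ, pACD=5.2),
            Formula.HOLLADAY1: LensConstantSet(Formula.HOLLADAY1, SF=1.2),
            Formula.HAIGIS: LensConstantSet(Formula.HAIGIS, a0=0.9, a1=0.4, a2=0.1),
        }
        cs = sets[formula]
        al, k1, k2, acd = 23.8, 43.0, 43.9, 3.2
        p = classical.power_for_target_classical(formula, al, k1, k2, acd, cs, 0.0)
        rx = classical.predict_refraction_classical(formula, al, k1, k2, acd, cs, p)
        assert rx == pytest.approx(0.0, abs=1e-9)


def _haigis_generated_cohort(a0, a1, a2, n, seed, noise_sd=0.0):
    """Cohort whose outcomes follow the Haigis model *under Haigis optics*."""
    rng = np.random.default_rng(seed)
    b = synthetic.sample_biometry(synthetic.default_profile("SN60WF"), n, seed=seed)
    al, k1, k2, acd = (b[c].to_numpy() for c in ("al_mm", "k1_d", "k2_d", "acd_mm"))
    d = a0 + a1 * acd + a2 * al
    pc = (k1 + k2) / 2 * (331.5 / 337.5)
    p = optics.iol_power_for_refraction(al, d, pc, 0.0)
    rx = optics.predict_refraction(al, d, pc, p)
    if noise_sd:
        rx = rx + rng.normal(0, noise_sd, n)
    out = b.copy()
    out["iol_power_d"] = p
    out["postop_se_d"] = rx
    out.insert(0, "id", [str(i) for i in range(len(out))])
    return out


class TestOptimization:
    def test_haigis_exact_recovery_without_noise(self):
        cohort = _haigis_generated_cohort(1.1, 0.35, 0.09, 400, seed=7)
        cs = classical.optimize_constants(Formula.HAIGIS, cohort)
        assert cs.a0 == pytest.approx(1.1, abs=1e-6)
        assert cs.a1 == pytest.approx(0.35, abs=1e-6)
        assert cs.a2 == pytest.approx(0.09, abs=1e-6)

    def test_haigis_recovery_is_noise_limited(self):
        """With 0.25 D refraction noise the 20-seed average of each estimated
        constant stays within 0.15 of the truth (estimator bias ~ 0)."""
        est = []
        for seed in range(20):
            cohort = _haigis_generated_cohort(1.1, 0.35, 0.09, 250, seed=seed, noise_sd=0.25)
            cs = classical.optimize_constants(Formula.HAIGIS, cohort)
            est.append([cs.a0, cs.a1, cs.a2])
        bias = np.mean(est, axis=0) - np.array([1.1, 0.35, 0.09])
        assert np.all(np.abs(bias) < 0.15)

    def test_haigis_a0_only_mode(self):
        cohort = _haigis_generated_cohort(1.1, 0.4, 0.1, 200, seed=3)
        cs = classical.optimize_constants(Formula.HAIGIS, cohort, haigis_mode="a0_only")
        assert (cs.a1, cs.a2) == (0.4, 0.1)
        assert cs.a0 == pytest.approx(1.1, abs=1e-6)

    @pytest.mark.parametrize("formula", [Formula.SRKT, Formula.HOFFERQ, Formula.HOLLADAY1])
    def test_single_constant_zeroes_mean_pe(self, formula, sn60wf_cohort):
        res = classical.ClassicalFormulaModel(formula, sn60wf_cohort).fit()
        assert np.mean(res.train_pe) == pytest.approx(0.0, abs=1e-6)

    def test_cohort_floor(self, sn60wf_cohort):
        with pytest.raises(ValidationError, match="at least 30"):
            classical.optimize_constants(Formula.SRKT, sn60wf_cohort.head(10))

    def test_unbracketed_root_reports_interval(self, sn60wf_cohort):
        broken = sn60wf_cohort.copy()
        broken["postop_se_d"] = 9.0  # no constant can zero this mean error
        with pytest.raises(OptimizationError, match=r"\[110.0, 125.0\]"):
            classical.optimize_constants(Formula.SRKT, broken)

    def test_mixed_lens_models_rejected(self, sn60wf_cohort):
        mixed = sn60wf_cohort.copy()
        mixed.loc[mixed.index[:5], "lens_model"] = "other"
        with pytest.raises(ValidationError, match="lens_model"):
            classical.optimize_constants(Formula.SRKT, mixed)

    def test_results_summary_mentions_constant(self, sn60wf_cohort):
        res = classical.ClassicalFormulaModel(Formula.HOFFERQ, sn60wf_cohort).fit()
        text = res.summary()
        assert "pACD" in text and "train mean PE" in text


def test_haigis_on_its_own_zero_noise_data_has_zero_pe():
    """A formula optimized on data generated by its own model predicts it
    perfectly (closure of generation + optimization + prediction)."""
    cohort = _haigis_generated_cohort(0.95, 0.4, 0.1, 150, seed=9)
    res = classical.ClassicalFormulaModel(Formula.HAIGIS, cohort).fit()
    assert np.max(np.abs(res.train_pe)) < 1e-8
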