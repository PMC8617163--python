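"""MM ensemble: training-table construction, fitting, prediction, persistence."""

import numpy as np
import pandas as pd
import pytest

from iolens import optics, synthetic
from iolens.ensemble import (
    FEATURE_COLUMNS,
    ELPEnsembleModel,
    ELPEnsembleResults,
    build_training_table,
)
from iolens.errors import ClampWarning, DataQualityError, ModelStateError, ValidationError

COLS = list(FEATURE_COLUMNS)


def _features_frame(x):
    return pd.DataFrame(np.asarray(x), columns=COLS)


class TestBuildTrainingTable:
    def test_zero_noise_targets_equal_true_elp(self, zero_noise_linear_cohort):
        features, targets, audit = build_training_table(zero_noise_linear_cohort)
        np.testing.assert_allclose(
            targets, zero_noise_linear_cohort["elp_true_mm"], atol=1e-9
        )
        assert audit["n_failed"] == 0
        assert list(features.columns) == COLS

    def test_single_bad_record_dropped_with_audit(self, sn60wf_cohort):
        cohort = sn60wf_cohort.copy()
        cohort.loc[cohort.index[0], "postop_se_d"] = 9.5  # unreachable refraction
        features, targets, audit = build_training_table(cohort)
        assert audit == {
            "n_input": len(cohort),
            "n_used": len(cohort) - 1,
            "n_failed": 1,
        }
        assert len(features) == len(targets) == len(cohort) - 1

    def test_excessive_failures_raise(self, sn60wf_cohort):
        cohort = sn60wf_cohort.copy()
        n_bad = int(0.3 * len(cohort))
        cohort.loc[cohort.index[:n_bad], "postop_se_d"] = 9.5
        with pytest.raises(DataQualityError):
            build_training_table(cohort)

    def test_haigis_generated_targets_are_linear(self):
        """Back-calculated targets from a linear ground truth refit by OLS
        with R^2 = 1 (oracle: the generating linear model)."""
        cohort = synthetic.generate_cohort(
            "SN60WF", n=150, gt_kind="linear", seed=31,
            noise=synthetic.NoiseModel(0.0, 0.0, 0.0), elp_noise_sd=0.0,
        )
        features, targets, _ = build_training_table(cohort)
        design = np.column_stack(
            [np.ones(len(features)), features["acd_mm"], features["al_mm"]]
        )
        coef, res, *_ = np.linalg.lstsq(design, targets, rcond=None)
        pred = design @ coef
        ss_res = np.sum((targets - pred) ** 2)
        ss_tot = np.sum((targets - targets.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 1 - 1e-12


class TestFitAndPredict:
    def test_constant_targets_recovered(self, rng):
        x = _features_frame(
            np.column_stack(
                [
                    rng.uniform(40, 46, 80),
                    rng.uniform(41, 47, 80),
                    rng.uniform(2.5, 4.0, 80),
                    rng.uniform(21, 27, 80),
                ]
            )
        )
        res = ELPEnsembleModel(x, np.full(80, 5.0)).fit(seed=0)
        np.testing.assert_allclose(res.predict_elp(x), 5.0, atol=1e-6)

    def test_linear_targets_heldout_mae(self):
        prof = synthetic.default_profile("SN60WF")
        b = synthetic.sample_biometry(prof, 600, seed=41)
        y = 0.9 + 0.4 * b["acd_mm"].to_numpy() + 0.08 * b["al_mm"].to_numpy()
        res = ELPEnsembleModel(b[COLS].head(400), y[:400]).fit(seed=0)
        mae = np.abs(res.predict_elp(b[COLS].tail(200)) - y[400:]).mean()
        assert mae < 0.05

    def test_nonlinear_truth_beats_linear_model(self):
        """With a saturating bend in AL the ensemble outpredicts a pure
        linear ELP model on held-out eyes (10 seeded replicates)."""
        prof = synthetic.default_profile("SN60WF")
        gt = synthetic.default_ground_truth("nonlinear")
        wins = 0
        for seed in range(10):
            b = synthetic.sample_biometry(prof, 600, seed=seed)
            x = b[COLS].to_numpy()
            y = gt(
                b["al_mm"].to_numpy(), b["k1_d"].to_numpy(),
                b["k2_d"].to_numpy(), b["acd_mm"].to_numpy(),
            ) + np.random.default_rng(seed).normal(0, 0.05, 600)
            res = ELPEnsembleModel(_features_frame(x[:400]), y[:400]).fit(seed)
            mm_mae = np.abs(res.predict_elp(_features_frame(x[400:])) - y[400:]).mean()
            design = np.column_stack([np.ones(400), x[:400]])
            coef, *_ = np.linalg.lstsq(design, y[:400], rcond=None)
            lin_mae = np.abs(
                np.column_stack([np.ones(200), x[400:]]) @ coef - y[400:]
            ).mean()
            wins += mm_mae < lin_mae
        assert wins >= 8

    def test_determinism_given_seed(self, sn60wf_cohort):
        a = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=7)
        b = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=7)
        x = sn60wf_cohort[COLS]
        assert np.array_equal(a.predict_elp(x), b.predict_elp(x))

    def test_row_floor(self, sn60wf_cohort):
        with pytest.raises(ValidationError, match="linear"):
            ELPEnsembleModel.from_cohort(sn60wf_cohort.head(10))

    def test_targets_outside_window_rejected(self, rng):
        x = _features_frame(np.tile([43.0, 44.0, 3.2, 23.8], (60, 1)))
        with pytest.raises(ValidationError, match="targets"):
            ELPEnsembleModel(x, np.full(60, 9.0))

    def test_extrapolation_clamped_with_flag(self, rng):
        # a steep ELP/AL slope makes extrapolation overshoot the window
        al = rng.uniform(21, 27, 100)
        x = _features_frame(
            np.column_stack(
                [np.full(100, 43.0), np.full(100, 44.0), rng.uniform(2.5, 4, 100), al]
            )
        )
        res = ELPEnsembleModel(x, 2.0 + 0.5 * (al - 21.0)).fit(seed=0)
        extreme = _features_frame([[43.0, 44.0, 5.9, 39.5]])
        with pytest.warns(ClampWarning):
            elp, flag = res.predict_elp(extreme, return_clamp_flag=True)
        assert flag.all() and elp[0] in (1.5, 8.0)

    def test_unfitted_estimator_raises_state_error(self, sn60wf_cohort):
        res = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=0)
        res.estimator = None
        with pytest.raises(ModelStateError):
            res.predict_elp(sn60wf_cohort[COLS])


class TestOpticsClosure:
    def test_zero_noise_pipeline_gives_zero_pe(self, zero_noise_linear_cohort):
        res = ELPEnsembleModel.from_cohort(zero_noise_linear_cohort).fit(seed=0)
        pe = zero_noise_linear_cohort["postop_se_d"].to_numpy() - res.predict_refraction(
            zero_noise_linear_cohort
        )
        assert np.max(np.abs(pe)) < 1e-6

    def test_recommended_power_rounding(self, sn60wf_cohort):
        res = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=0)
        rounded, raw = res.recommend_power(sn60wf_cohort, target_rx=0.0, step=0.5)
        assert np.allclose(rounded % 0.5, 0.0)
        assert np.max(np.abs(rounded - raw)) <= 0.25 + 1e-12
        assert np.round(19.78 / 0.5) * 0.5 == 20.0  # the manufacturing-step rule

    def test_target_rx_zero_equals_emmetropic_power(self, sn60wf_cohort):
        res = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=0)
        _, raw = res.recommend_power(sn60wf_cohort, target_rx=0.0)
        elp = res.predict_elp(sn60wf_cohort)
        k = optics.mean_corneal_power(
            sn60wf_cohort["k1_d"].to_numpy(), sn60wf_cohort["k2_d"].to_numpy()
        )
        expected = optics.emmetropic_iol_power(
            sn60wf_cohort["al_mm"].to_numpy(), elp, k
        )
        np.testing.assert_allclose(raw, expected, atol=1e-10)

    def test_al_perturbation_changes_refraction_boundedly(self, sn60wf_cohort):
        """+/- 0.1 mm of axial-length measurement error moves the predicted
        refraction by well under 0.5 D on physiological eyes."""
        res = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=0)
        base = res.predict_refraction(sn60wf_cohort)
        for delta in (-0.1, 0.1):
            shifted = sn60wf_cohort.copy()
            shifted["al_mm"] = shifted["al_mm"] + delta
            moved = res.predict_refraction(shifted)
            assert np.max(np.abs(moved - base)) < 0.5


class TestPersistence:
    def test_save_load_identical(self, sn60wf_cohort, tmp_path):
        res = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=5)
        path = tmp_path / "mm.joblib"
        res.save(path)
        clone = ELPEnsembleResults.load(path)
        x = sn60wf_cohort[COLS]
        np.testing.assert_allclose(
            clone.predict_elp(x), res.predict_elp(x), atol=1e-12
        )
        assert clone.lens_model == res.lens_model
        assert clone.train_seed == 5

    def test_version_guard(self, sn60wf_cohort, tmp_path):
        import joblib

        res = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=5)
        path = tmp_path / "mm.joblib"
        res.save(path)
        payload = joblib.load(path)
        payload["version"] = "someone-elses-format"
        joblib.dump(payload, path)
        with pytest.raises(ModelStateError, match="version"):
            ELPEnsembleResults.load(path)

    def test_summary_mentions_ensemble_and_cohort(self, sn60wf_cohort):
        res = ELPEnsembleModel.from_cohort(sn60wf_cohort).fit(seed=5)
        text = res.summary()
        assert "SN60WF" in text and "training eyes" in text
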