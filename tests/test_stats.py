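import numpy as np
import pytest

from vptsim import (
    FitError,
    GenerativeLMMConfig,
    effect_size_r,
    fit_baseline_ols,
    fit_random_intercept_lmm,
    generate_tidy_direct,
    lrt,
    model_ladder,
    summarize_conditions,
)


@pytest.fixture(scope="module")
def calibrated_tidy():
    return generate_tidy_direct(GenerativeLMMConfig(missing_rate=0.0), seed=101)


class TestEffectSize:
    def test_reported_method_row(self):
        assert round(effect_size_r(-7.42, 316), 2) == 0.39

    def test_reported_intercept_row(self):
        assert round(effect_size_r(71.78, 316), 2) == 0.97

    def test_zero_t_gives_zero_r(self):
        assert effect_size_r(0.0, 100) == 0.0

    def test_r_bounded(self):
        assert 0.0 <= effect_size_r(123.0, 3) <= 1.0
        with pytest.raises(ValueError):
            effect_size_r(1.0, 0)


class TestRandomInterceptFit:
    def test_df_convention(self):
        """DF = n_obs - n_groups - (p - 1): 350 - 30 - 4 = 316."""
        tidy = generate_tidy_direct(GenerativeLMMConfig(missing_rate=0.0), seed=5)
        tidy = tidy.drop(tidy.index[:10])  # 350 usable rows
        fit = fit_random_intercept_lmm(tidy, estimation="REML")
        assert fit.n_obs == 350 and fit.n_groups == 30
        assert all(fe.df == 316 for fe in fit.fixed_effects)

    def test_noiseless_data_recovers_betas_exactly(self):
        cfg = GenerativeLMMConfig(tau_participant=0.0, sigma_resid=0.0,
                                  missing_rate=0.0)
        tidy = generate_tidy_direct(cfg, seed=6)
        fit = fit_random_intercept_lmm(tidy, estimation="ML")
        assert fit.coef("Intercept").b == pytest.approx(112.17, abs=1e-6)
        assert fit.coef("[375").b == pytest.approx(7.78, abs=1e-6)
        assert fit.coef("[500").b == pytest.approx(13.80, abs=1e-6)
        assert fit.coef("staircase").b == pytest.approx(-4.91, abs=1e-6)
        assert fit.coef("ring").b == pytest.approx(-1.47, abs=1e-6)

    def test_large_sample_recovery_with_noise(self):
        tidy = generate_tidy_direct(GenerativeLMMConfig(missing_rate=0.0),
                                    n_participants=400, seed=7)
        fit = fit_random_intercept_lmm(tidy, estimation="REML")
        assert fit.coef("staircase").b == pytest.approx(-4.91, abs=0.25)
        assert np.sqrt(fit.tau2) == pytest.approx(10.0, rel=0.15)
        assert np.sqrt(fit.sigma2) == pytest.approx(6.0, rel=0.05)

    def test_reml_and_ml_betas_agree_on_balanced_data(self, calibrated_tidy):
        ml = fit_random_intercept_lmm(calibrated_tidy, estimation="ML")
        reml = fit_random_intercept_lmm(calibrated_tidy, estimation="REML")
        for a, b in zip(ml.fixed_effects, reml.fixed_effects):
            assert b.b == pytest.approx(a.b, rel=0.01, abs=0.01)

    def test_ci_brackets_estimate(self, calibrated_tidy):
        fit = fit_random_intercept_lmm(calibrated_tidy)
        for fe in fit.fixed_effects:
            assert fe.ci_low < fe.b < fe.ci_high
            assert 0.0 <= fe.r <= 1.0

    def test_reference_level_reparameterization(self, calibrated_tidy):
        """375 Hz coefficient under a 500 Hz reference equals b375 - b500."""
        fit = fit_random_intercept_lmm(calibrated_tidy, estimation="REML")
        fit_r = fit_random_intercept_lmm(calibrated_tidy, estimation="REML",
                                         reference_levels={"frequency_hz": 500.0})
        expected = fit.coef("[375").b - fit.coef("[500").b
        assert fit_r.coef("[375").b == pytest.approx(expected, abs=1e-4)

    def test_degenerate_input_raises(self):
        tidy = generate_tidy_direct(n_participants=2, seed=8)
        tidy = tidy[tidy.participant_id == "P01"]
        with pytest.raises(FitError):
            fit_random_intercept_lmm(tidy)

    def test_invalid_estimation_flag(self, calibrated_tidy):
        with pytest.raises(ValueError):
            fit_random_intercept_lmm(calibrated_tidy, estimation="GLS")


class TestLikelihoodRatio:
    def test_identical_models_give_zero_chisq(self, calibrated_tidy):
        f1 = fit_random_intercept_lmm(calibrated_tidy, estimation="ML")
        f2 = fit_random_intercept_lmm(calibrated_tidy, estimation="ML")
        res = lrt(f1, f2)
        assert res.chisq == pytest.approx(0.0, abs=1e-6)
        assert res.p == 1.0

    def test_reml_fits_rejected(self, calibrated_tidy):
        reml = fit_random_intercept_lmm(calibrated_tidy, estimation="REML")
        ml = fit_random_intercept_lmm(calibrated_tidy, estimation="ML")
        with pytest.raises(ValueError):
            lrt(reml, ml)

    def test_random_intercept_detected(self, calibrated_tidy):
        base = fit_baseline_ols(calibrated_tidy)
        ri = fit_random_intercept_lmm(calibrated_tidy, fixed_factors=(),
                                      estimation="ML")
        res = lrt(base, ri)
        assert res.df == 1
        assert res.p < 1e-6

    def test_true_method_effect_detected(self, calibrated_tidy):
        reduced = fit_random_intercept_lmm(
            calibrated_tidy, fixed_factors=("frequency_hz",), estimation="ML")
        full = fit_random_intercept_lmm(
            calibrated_tidy, fixed_factors=("frequency_hz", "method"),
            estimation="ML")
        res = lrt(reduced, full)
        assert res.df == 1
        assert res.p < 0.001

    def test_null_effect_type_i_rate(self):
        """Adding a truly null gender effect rejects at ~alpha."""
        rejections = 0
        n_reps = 60
        for rep in range(n_reps):
            tidy = generate_tidy_direct(
                GenerativeLMMConfig(missing_rate=0.0), n_participants=30,
                seed=9000 + rep)
            reduced = fit_random_intercept_lmm(
                tidy, fixed_factors=("frequency_hz", "method", "location"),
                estimation="ML")
            full = fit_random_intercept_lmm(
                tidy, fixed_factors=("frequency_hz", "method", "location", "gender"),
                estimation="ML")
            if lrt(reduced, full).p < 0.05:
                rejections += 1
        assert rejections / n_reps <= 0.15  # ~5% nominal, binomial slack


class TestModelLadder:
    def test_ladder_selects_true_effects(self):
        # location effect enlarged so every true step has near-certain power;
        # gender stays truly null
        tidy = generate_tidy_direct(
            GenerativeLMMConfig(beta_ring=-4.0, missing_rate=0.0), seed=101)
        ladder = model_ladder(tidy)
        assert ladder.selected_factors == ("frequency_hz", "method", "location")
        names = [s.name for s in ladder.steps]
        assert names == ["baseline", "random_intercept", "+frequency_hz",
                         "+method", "+location", "+gender"]
        assert ladder.final.estimation == "REML"
        by_name = {s.name: s for s in ladder.steps}
        assert by_name["+frequency_hz"].lrt_vs_previous.df == 2
        assert by_name["+method"].lrt_vs_previous.p < 0.001

    def test_ladder_requires_enough_groups(self):
        tidy = generate_tidy_direct(n_participants=2, seed=10)
        tidy = tidy[tidy.participant_id == "P01"]
        with pytest.raises(FitError):
            model_ladder(tidy)


class TestConditionSummaries:
    def test_known_normal_cell(self):
        rng = np.random.default_rng(0)
        import pandas as pd

        tidy = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(500)],
            "method": "bekesy", "frequency_hz": 250.0, "location": "index",
            "vpt_db": rng.normal(110.0, 12.0, size=500),
        })
        row = summarize_conditions(tidy, "vpt_db").iloc[0]
        assert row["n"] == 500
        assert row["mean"] == pytest.approx(110.0, abs=1.1)
        assert row["sd"] == pytest.approx(12.0, abs=0.8)
        assert row["ci95_low"] < row["mean"] < row["ci95_high"]

    def test_single_row_cell_has_no_sd(self):
        import pandas as pd

        tidy = pd.DataFrame({
            "participant_id": ["P1"], "method": ["bekesy"],
            "frequency_hz": [250.0], "location": ["index"], "vpt_db": [100.0]})
        row = summarize_conditions(tidy).iloc[0]
        assert row["mean"] == 100.0 and np.isnan(row["sd"])

    def test_constant_cell_collapses_ci(self):
        import pandas as pd

        tidy = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(5)],
            "method": "bekesy", "frequency_hz": 250.0, "location": "index",
            "vpt_db": 100.0})
        row = summarize_conditions(tidy).iloc[0]
        assert row["sd"] == 0.0
        assert row["ci95_low"] == row["ci95_high"] == row["mean"]

    def test_missing_excluded_per_cell(self, calibrated_tidy):
        tidy = calibrated_tidy.copy()
        tidy.loc[tidy.index[:5], "vpt_db"] = np.nan
        table = summarize_conditions(tidy)
        assert table["n"].sum() == len(tidy) - 5
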