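import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ticonomics.cohort import CohortConfig, generate_cohort
from ticonomics.mapping import (
    BETA_LOGIT,
    GAUSSIAN_IDENTITY,
    MODEL_PREDICTORS,
    FittedMapping,
    FittingError,
    MappingSpec,
    ValidationMetrics,
    compare_models,
    fit_mapping,
    invert_boundary_transform,
    predict_utility,
    reference_model1,
    reference_predictor,
    screen_covariates,
    transform_boundaries,
    validation_metrics,
)


class TestTransformBoundaries:
    def test_upper_boundary(self):
        assert transform_boundaries([1.0], 144)[0] == pytest.approx(143.5 / 144)

    def test_lower_boundary(self):
        assert transform_boundaries([0.0], 144)[0] == pytest.approx(0.5 / 144)

    @pytest.mark.parametrize("n", [2, 10, 144, 1000])
    def test_half_is_fixed_point(self, n):
        assert transform_boundaries([0.5], n)[0] == pytest.approx(0.5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            transform_boundaries([0.5], 1)

    @settings(max_examples=50, deadline=None)
    @given(
        y=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20),
        n=st.integers(min_value=2, max_value=500),
    )
    def test_range_and_order(self, y, n):
        out = transform_boundaries(y, n)
        assert np.all(out > 0.0) and np.all(out < 1.0)
        assert np.all(out >= 0.5 / n - 1e-12) and np.all(out <= 1 - 0.5 / n + 1e-12)
        order = np.argsort(y)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_inverse_round_trip(self):
        y = np.linspace(0, 1, 11)
        assert invert_boundary_transform(transform_boundaries(y, 144), 144) == pytest.approx(y)


class TestFit:
    def test_noiseless_recovery_exact(self):
        records = generate_cohort(CohortConfig(n=144, seed=3, noise_sd=0.0))
        fit = fit_mapping(records, MappingSpec(GAUSSIAN_IDENTITY, 1))
        assert fit.coefficients["intercept"] == pytest.approx(0.9881, abs=1e-4)
        assert fit.coefficients["ygtss_total"] == pytest.approx(-0.0035, abs=1e-4)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_matches_closed_form_simple_regression(self):
        # hand-rolled oracle: slope = cov(x, y) / var(x), intercept from means
        records = generate_cohort(CohortConfig(n=40, seed=11))
        x = np.array([r.ygtss_total for r in records], dtype=float)
        y = np.array([r.eq5dy_utility for r in records], dtype=float)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        fit = fit_mapping(records, MappingSpec(GAUSSIAN_IDENTITY, 1))
        assert fit.coefficients["ygtss_total"] == pytest.approx(slope, rel=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(intercept, rel=1e-10)

    def test_recovery_with_negligible_censoring(self):
        records = generate_cohort(CohortConfig(n=1000, seed=4, noise_sd=0.005))
        fit = fit_mapping(records, MappingSpec(GAUSSIAN_IDENTITY, 1))
        assert abs(fit.coefficients["ygtss_total"] + 0.0035) < 3 * fit.standard_errors["ygtss_total"]
        assert abs(fit.coefficients["intercept"] - 0.9881) < 3 * fit.standard_errors["intercept"]

    def test_beta_slope_negative(self, default_cohort):
        fit = fit_mapping(default_cohort, MappingSpec(BETA_LOGIT, 1))
        assert fit.coefficients["ygtss_total"] < 0
        assert fit.boundary_n == 144
        assert fit.precision is not None and fit.precision > 0

    def test_all_terms_have_estimates(self, default_cohort):
        for family in (GAUSSIAN_IDENTITY, BETA_LOGIT):
            for model, terms in MODEL_PREDICTORS.items():
                fit = fit_mapping(default_cohort, MappingSpec(family, model))
                expected = {"intercept", *terms}
                assert set(fit.coefficients) == expected
                assert set(fit.standard_errors) == expected
                assert fit.n_used == 144

    def test_rows_with_missing_covariates_dropped(self):
        records = generate_cohort(CohortConfig(n=144, seed=5, height_missing_rate=0.3))
        fit = fit_mapping(records, MappingSpec(GAUSSIAN_IDENTITY, 1))
        assert fit.n_used == 144  # height is not a model predictor

    def test_constant_predictor_rejected(self):
        records = generate_cohort(CohortConfig(n=60, seed=6, male_fraction=1.0))
        with pytest.raises(FittingError, match="sex"):
            fit_mapping(records, MappingSpec(GAUSSIAN_IDENTITY, 3))

    def test_too_few_rows_rejected(self, default_cohort):
        with pytest.raises(FittingError, match="at least"):
            fit_mapping(default_cohort[:5], MappingSpec(GAUSSIAN_IDENTITY, 1))

    def test_adjusted_r2_at_most_one(self, default_cohort):
        for family in (GAUSSIAN_IDENTITY, BETA_LOGIT):
            for model in MODEL_PREDICTORS:
                fit = fit_mapping(default_cohort, MappingSpec(family, model))
                assert fit.adj_r2 <= 1.0

    def test_json_round_trip(self, tmp_path, default_cohort):
        fit = fit_mapping(default_cohort, MappingSpec(BETA_LOGIT, 3))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        loaded = FittedMapping.from_json(path)
        assert loaded == fit

    def test_json_is_plain_text(self, tmp_path, default_cohort):
        fit = fit_mapping(default_cohort, MappingSpec(GAUSSIAN_IDENTITY, 1))
        payload = json.loads(fit.to_json())
        assert payload["spec"] == {"family": GAUSSIAN_IDENTITY, "model": 1}


class TestPredict:
    def test_reference_at_zero(self):
        assert reference_predictor(0.0) == pytest.approx(0.9881)
        fit = reference_model1()
        assert predict_utility(fit, {"ygtss_total": 0.0})[0] == pytest.approx(0.9881)

    def test_reference_at_baseline_severity(self):
        assert reference_predictor(30.37) == pytest.approx(0.881805)

    def test_beta_all_zero_coefficients_give_half(self):
        fit = FittedMapping(
            spec=MappingSpec(BETA_LOGIT, 1),
            coefficients={"intercept": 0.0, "ygtss_total": 0.0},
            standard_errors={"intercept": 0.0, "ygtss_total": 0.0},
            p_values={},
            n_used=144,
            aic=0.0,
            bic=0.0,
            adj_r2=0.0,
            boundary_n=144,
        )
        assert predict_utility(fit, {"ygtss_total": 37.0})[0] == pytest.approx(0.5)

    def test_missing_covariate_rejected(self):
        fit = reference_model1()
        with pytest.raises(ValueError, match="missing covariates"):
            predict_utility(fit, {"sex": 1})

    def test_gaussian_predictions_unclipped(self):
        fit = FittedMapping(
            spec=MappingSpec(GAUSSIAN_IDENTITY, 1),
            coefficients={"intercept": 1.2, "ygtss_total": 0.0},
            standard_errors={"intercept": 0.0, "ygtss_total": 0.0},
            p_values={},
            n_used=20,
            aic=0.0,
            bic=0.0,
            adj_r2=0.0,
        )
        assert predict_utility(fit, {"ygtss_total": 0.0})[0] == pytest.approx(1.2)


class TestValidationMetrics:
    def test_perfect_predictor(self):
        records = generate_cohort(CohortConfig(n=50, seed=3, noise_sd=0.0))
        fit = fit_mapping(records, MappingSpec(GAUSSIAN_IDENTITY, 1))
        metrics = validation_metrics(fit, records)
        assert metrics.mae == pytest.approx(0.0, abs=1e-10)
        assert metrics.rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_predictor_oracle(self, default_cohort):
        constant = 0.9
        fit = FittedMapping(
            spec=MappingSpec(GAUSSIAN_IDENTITY, 1),
            coefficients={"intercept": constant, "ygtss_total": 0.0},
            standard_errors={"intercept": 0.0, "ygtss_total": 0.0},
            p_values={},
            n_used=2,
            aic=0.0,
            bic=0.0,
            adj_r2=0.0,
        )
        two = default_cohort[:2]
        metrics = validation_metrics(fit, two)
        expected = np.mean([abs(r.eq5dy_utility - constant) for r in two])
        assert metrics.mae == pytest.approx(expected)

    def test_rmse_tracks_noise_scale(self, big_cohort):
        fit = fit_mapping(big_cohort, MappingSpec(GAUSSIAN_IDENTITY, 1))
        metrics = validation_metrics(fit, big_cohort)
        noise_sd = CohortConfig().noise_sd
        assert abs(metrics.rmse - noise_sd) / noise_sd < 0.25

    def test_mae_never_exceeds_rmse(self, default_cohort):
        for family in (GAUSSIAN_IDENTITY, BETA_LOGIT):
            for model in MODEL_PREDICTORS:
                fit = fit_mapping(default_cohort, MappingSpec(family, model))
                metrics = validation_metrics(fit, default_cohort)
                assert metrics.mae <= metrics.rmse

    def test_metrics_invariant_rejected(self):
        with pytest.raises(ValueError):
            ValidationMetrics(mae=0.5, rmse=0.1)

    def test_invert_boundary_switch_changes_beta_metrics(self, default_cohort):
        fit = fit_mapping(default_cohort, MappingSpec(BETA_LOGIT, 1))
        raw = validation_metrics(fit, default_cohort)
        inverted = validation_metrics(fit, default_cohort, invert_boundary=True)
        assert raw != inverted


class TestCompareModels:
    def _fits_and_metrics(self, records, specs):
        fits = [fit_mapping(records, spec) for spec in specs]
        metrics = [validation_metrics(fit, records) for fit in fits]
        return fits, metrics

    def test_identical_fits_tie(self, default_cohort):
        fits, metrics = self._fits_and_metrics(
            default_cohort, [MappingSpec(GAUSSIAN_IDENTITY, 1), MappingSpec(GAUSSIAN_IDENTITY, 1)]
        )
        table = compare_models(fits, metrics)
        assert table["best_aic"].all()
        assert list(table["model"]) == [1, 1]

    def test_sex_effect_improves_model3(self):
        records = generate_cohort(CohortConfig(n=2000, seed=8, sex_effect=-0.036))
        fits, metrics = self._fits_and_metrics(
            records, [MappingSpec(GAUSSIAN_IDENTITY, 1), MappingSpec(GAUSSIAN_IDENTITY, 3)]
        )
        table = compare_models(fits, metrics)
        assert table.loc[1, "adj_r2"] > table.loc[0, "adj_r2"]
        assert table.loc[1, "p_sex"] < 0.05

    def test_aic_prefers_smaller_model_without_effect(self):
        # sex carries no effect here, so model 3's extra term is pure noise
        wins = 0
        for seed in range(100):
            records = generate_cohort(CohortConfig(n=500, seed=seed, sex_effect=0.0))
            fit1 = fit_mapping(records, MappingSpec(GAUSSIAN_IDENTITY, 1))
            fit3 = fit_mapping(records, MappingSpec(GAUSSIAN_IDENTITY, 3))
            wins += fit1.aic < fit3.aic
        assert wins > 50

    def test_different_record_sets_rejected(self, default_cohort):
        other = generate_cohort(CohortConfig(n=144, seed=99))
        fit_a = fit_mapping(default_cohort, MappingSpec(GAUSSIAN_IDENTITY, 1))
        fit_b = fit_mapping(other, MappingSpec(GAUSSIAN_IDENTITY, 1))
        metrics = [validation_metrics(fit_a, default_cohort), validation_metrics(fit_b, other)]
        with pytest.raises(ValueError, match="different record sets"):
            compare_models([fit_a, fit_b], metrics)

    def test_reports_p_values(self, default_cohort):
        fits, metrics = self._fits_and_metrics(
            default_cohort, [MappingSpec(GAUSSIAN_IDENTITY, 1), MappingSpec(GAUSSIAN_IDENTITY, 3)]
        )
        table = compare_models(fits, metrics)
        assert "p_ygtss_total" in table.columns
        assert "p_sex" in table.columns


class TestScreenCovariates:
    def test_detects_injected_sex_effect(self):
        records = generate_cohort(CohortConfig(n=2000, seed=8, sex_effect=-0.036))
        table = screen_covariates(records)
        assert table.loc["sex", "significant"]

    def test_reports_all_demographics(self, default_cohort):
        table = screen_covariates(default_cohort)
        assert set(table.index) == {"sex", "age", "height", "weight"}
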