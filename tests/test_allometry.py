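"""Equation families, BIC, enumeration, selection and the combined model."""

import math

import numpy as np
import pandas as pd
import pytest

from shrubvol import (
    FittedModel,
    GeneratorConfig,
    ModelSpec,
    bic,
    enumerate_models,
    fit_combined_volume_model,
    fit_model,
    format_equation,
    generate_stands,
    generate_trees,
    predict,
    prediction_interval,
    select_models,
)
from shrubvol.errors import DomainError, SelectionError, UnsupportedModelError

from .oracles import power_fit_gridsearch


def make_fit(bic_value, n_predictors, family="linear", response="total"):
    """Hand-built FittedModel for selection-rule tests."""
    spec = ModelSpec(response, tuple("VAHD"[:n_predictors]), family)
    return FittedModel(
        spec=spec, params={"a": 0.0}, n=30, rss=1.0, rmse=0.18,
        bic=bic_value, converged=True,
    )


class TestFitModel:
    def test_exact_line(self):
        data = pd.DataFrame({"V": np.arange(1.0, 11.0)})
        data["total_dry"] = 2 + 3 * data.V
        fit = fit_model(ModelSpec("total", ("V",), "linear"), data)
        assert fit.params["a"] == pytest.approx(2.0, abs=1e-9)
        assert fit.params["b_V"] == pytest.approx(3.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.bic == -np.inf

    def test_exact_ln_line(self):
        x = np.linspace(1, 20, 25)
        data = pd.DataFrame({"V": x, "total_dry": 1 + 2 * np.log(x)})
        fit = fit_model(ModelSpec("total", ("V",), "ln_linear"), data)
        assert fit.params["b_V"] == pytest.approx(2.0, abs=1e-10)

    def test_noiseless_power_recovery_to_four_decimals(self):
        x = np.linspace(0.5, 9, 40)
        data = pd.DataFrame({"V": x, "total_dry": 1 + 2 * x**1.5})
        fit = fit_model(ModelSpec("total", ("V",), "power_sum"), data)
        assert fit.converged
        assert fit.params["a"] == pytest.approx(1.0, abs=1e-4)
        assert fit.params["b_V"] == pytest.approx(2.0, abs=1e-4)
        assert fit.params["c_V"] == pytest.approx(1.5, abs=1e-4)

    def test_power_fit_matches_gridsearch_oracle(self, rng):
        x = rng.uniform(1, 30, 80)
        y = 3 + 0.8 * x**1.3 + rng.normal(0, 1.0, 80)
        data = pd.DataFrame({"V": x, "total_dry": y})
        fit = fit_model(ModelSpec("total", ("V",), "power_sum"), data)
        a, b, c, rss = power_fit_gridsearch(x, y)
        assert fit.rss <= rss + 1e-6  # LM should do at least as well as the grid
        assert fit.params["c_V"] == pytest.approx(c, abs=0.002)

    def test_domain_errors(self):
        data = pd.DataFrame({"V": [1.0, -1.0, 2.0, 3.0], "total_dry": [1, 2, 3, 4.0]})
        for family in ("ln_linear", "power_sum"):
            with pytest.raises(DomainError):
                fit_model(ModelSpec("total", ("V",), family), data)
        tiny = pd.DataFrame({"V": [1.0, 2.0], "total_dry": [1.0, 2.0]})
        with pytest.raises(DomainError):
            fit_model(ModelSpec("total", ("V",), "linear"), tiny)


class TestBic:
    def test_arithmetic_example(self):
        assert bic(10, 10.0, 3) == pytest.approx(10 * math.log(1) + 3 * math.log(10))
        assert bic(10, 10.0, 3) == pytest.approx(6.9078, abs=1e-4)

    def test_extra_parameter_costs_ln_n(self):
        assert bic(50, 4.0, 5) - bic(50, 4.0, 4) == pytest.approx(math.log(50))

    def test_monotone_in_rss(self):
        assert bic(20, 5.0, 3) < bic(20, 6.0, 3)

    def test_perfect_fit_sentinel(self):
        assert bic(20, 0.0, 3) == -np.inf


class TestEnumeration:
    def test_tree_and_stand_counts(self):
        trees = enumerate_models("trees", "total")
        stands = enumerate_models("stands", "total")
        assert len(trees) == 42  # (C(4,1)+C(4,2)+C(4,3)) * 3 families
        assert len(stands) == 90  # (C(5,1)+...+C(5,4)) * 3 families
        assert len(set(trees)) == 42 and len(set(stands)) == 90

    def test_unknown_kind(self):
        with pytest.raises(DomainError):
            enumerate_models("plots", "total")


class TestSelection:
    def test_single_candidate(self):
        f = make_fit(12.0, 1)
        best, pars = select_models([f])
        assert best is f and pars is f

    def test_equal_bic_tie_prefers_fewer_predictors(self):
        f1, f2 = make_fit(10.0, 1), make_fit(10.0, 2)
        best, pars = select_models([f1, f2])
        assert best is f1 and pars is f1

    def test_large_gap_rejects_smaller_model(self):
        f1, f2 = make_fit(100.0, 1), make_fit(85.0, 2)
        best, pars = select_models([f1, f2])
        assert best is f2 and pars is f2  # delta 15 > 10: 1-var not defensible

    def test_small_gap_accepts_smaller_model(self):
        f1, f2 = make_fit(92.0, 1), make_fit(85.0, 2)
        best, pars = select_models([f1, f2])
        assert best is f2 and pars is f1  # delta 7 <= 10

    def test_no_converged_fit(self):
        bad = make_fit(np.nan, 1)
        bad.converged = False
        with pytest.raises(SelectionError):
            select_models([bad])


class TestCombinedModel:
    def test_pooled_perfect_line(self):
        trees = pd.DataFrame({"V": [1.0, 2, 3], "total_dry": [2.0, 3, 4]})
        stands = pd.DataFrame({"V": [10.0, 20], "total_dry": [11.0, 21]})
        fit = fit_combined_volume_model(trees, stands)
        assert fit.params["a"] == pytest.approx(1.0, abs=1e-9)
        assert fit.params["b_V"] == pytest.approx(1.0, abs=1e-10)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_defaults_land_in_field_regime(self):
        trees = generate_trees(GeneratorConfig(seed=42, n_trees=300))
        stands, _ = generate_stands(GeneratorConfig(seed=42, grid_resolution_m=0.1))
        fit = fit_combined_volume_model(trees, stands)
        assert 0.5 <= fit.params["b_V"] <= 1.5
        assert fit.params["a"] > 0

    def test_worked_prediction_from_published_coefficients(self):
        pred = 6.297 + 0.982 * 31_711
        assert pred == pytest.approx(31_146.5, abs=0.1)
        # the campaign printed 31,141 kg from unrounded coefficients: within 0.02%
        assert pred == pytest.approx(31_141, rel=2e-4)

    def test_empty_inputs_rejected(self):
        t = pd.DataFrame({"V": [1.0], "total_dry": [1.0]})
        with pytest.raises(DomainError):
            fit_combined_volume_model(t, t.iloc[:0])


class TestPredictionInterval:
    @staticmethod
    def _line_fit(n=5, sigma=0.3):
        rng = np.random.default_rng(3)
        x = np.linspace(1, 5, n)
        y = 1 + 2 * x + rng.normal(0, sigma, n)
        data = pd.DataFrame({"V": x, "total_dry": y})
        return x, y, fit_model(ModelSpec("total", ("V",), "linear"), data)

    def test_predict_at_zero_returns_intercept(self):
        *_, fit = self._line_fit()
        assert predict(fit, {"V": [0.0]})[0] == pytest.approx(fit.params["a"])

    def test_interval_matches_textbook_closed_form(self):
        from scipy import stats

        x, y, fit = self._line_fit()
        x0 = 3.2
        lo, hi = prediction_interval(fit, {"V": [x0]})[0]
        # closed form for the mean-response CI of simple OLS
        yhat = fit.params["a"] + fit.params["b_V"] * x0
        resid = y - (fit.params["a"] + fit.params["b_V"] * x)
        s = math.sqrt((resid @ resid) / (len(x) - 2))
        sxx = ((x - x.mean()) ** 2).sum()
        half = stats.t.ppf(0.975, len(x) - 2) * s * math.sqrt(1 / len(x) + (x0 - x.mean()) ** 2 / sxx)
        assert lo == pytest.approx(yhat - half, rel=1e-9)
        assert hi == pytest.approx(yhat + half, rel=1e-9)

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (10, 100, 1000):
            rng = np.random.default_rng(1)
            x = np.linspace(1, 5, n)
            y = 1 + 2 * x + rng.normal(0, 0.3, n)
            fit = fit_model(
                ModelSpec("total", ("V",), "linear"),
                pd.DataFrame({"V": x, "total_dry": y}),
            )
            lo, hi = prediction_interval(fit, {"V": [3.0]})[0]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_interval_unsupported_for_power_family(self):
        x = np.linspace(1, 9, 30)
        data = pd.DataFrame({"V": x, "total_dry": 1 + 2 * x**1.5})
        fit = fit_model(ModelSpec("total", ("V",), "power_sum"), data)
        with pytest.raises(UnsupportedModelError):
            prediction_interval(fit, {"V": [2.0]})


def test_format_equation_is_readable():
    data = pd.DataFrame({"V": [1.0, 2, 3, 4], "total_dry": [2.5, 4, 5.5, 7]})
    fit = fit_model(ModelSpec("total", ("V",), "linear"), data)
    assert format_equation(fit) == "Y ~ 1 + 1.5*V"
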