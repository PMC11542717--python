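"""Simple-OLS fitting, model recovery from published pairs, prediction."""

import math

import numpy as np
import pytest

from iamtox.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    MissingDescriptorError,
)
from iamtox.dataset_io import CompoundRecord
from iamtox.qsar_models import (
    fit_simple_ols,
    predict_endpoint,
    recover_model_from_pairs,
)
from iamtox.synthetic import SyntheticConfig, gen_training_set


def _normal_equations(x, y):
    """Independent OLS oracle."""
    X = np.column_stack([np.ones(len(x)), x])
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))


class TestFitSimpleOls:
    def test_exact_line(self):
        model = fit_simple_ols([0, 1, 2], [1, 3, 5])
        assert model.beta0 == pytest.approx(1.0)
        assert model.beta1 == pytest.approx(2.0)
        assert model.stats.r2 == pytest.approx(1.0)
        assert model.stats.s == pytest.approx(0.0, abs=1e-12)

    def test_four_point_example_against_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 0.0])
        model = fit_simple_ols(x, y)
        beta = _normal_equations(x, y)
        assert model.beta0 == pytest.approx(beta[0]) == pytest.approx(0.6)
        assert model.beta1 == pytest.approx(beta[1]) == pytest.approx(0.1)
        sse = np.sum((y - beta[0] - beta[1] * x) ** 2)
        assert model.stats.s == pytest.approx(math.sqrt(sse / 2)) == pytest.approx(
            math.sqrt(1.35)
        )
        assert model.stats.r2 == pytest.approx(0.0181818, abs=1e-6)

    def test_parameter_recovery_at_published_noise_scale(self):
        config = SyntheticConfig(seed=7, n=200, beta0=2.4, beta1=0.048, noise_sd=0.384)
        x, y = gen_training_set(config)
        model = fit_simple_ols(x, y)
        s_xx = np.sum((x - x.mean()) ** 2)
        se_b1 = model.stats.s / math.sqrt(s_xx)
        se_b0 = model.stats.s * math.sqrt(1 / len(x) + x.mean() ** 2 / s_xx)
        assert abs(model.beta1 - 0.048) < 3 * se_b1
        assert abs(model.beta0 - 2.4) < 3 * se_b0
        assert 0.33 <= model.stats.s <= 0.44

    def test_residuals_sum_zero_and_anova_identity(self, rng):
        x = rng.uniform(0, 60, 25)
        y = 2.4 + 0.05 * x + rng.normal(0, 0.4, 25)
        model = fit_simple_ols(x, y)
        e = y - (model.beta0 + model.beta1 * x)
        assert np.sum(e) == pytest.approx(0.0, abs=1e-9)
        sst = np.sum((y - y.mean()) ** 2)
        ssr = np.sum((model.beta0 + model.beta1 * x - y.mean()) ** 2)
        assert sst == pytest.approx(ssr + np.sum(e**2), rel=1e-9)

    def test_fisher_statistic_consistency(self, rng):
        x = rng.uniform(0, 60, 29)
        y = 2.4 + 0.05 * x + rng.normal(0, 0.4, 29)
        stats = fit_simple_ols(x, y).stats
        assert stats.f == pytest.approx(stats.r2 * (stats.n - 2) / (1 - stats.r2))
        assert stats.r2_adj <= stats.r2

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDesignError):
            fit_simple_ols([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fit_simple_ols([0.0, 1.0], [0.0, 1.0])


class TestRecoverModelFromPairs:
    def test_identity_line(self):
        model = recover_model_from_pairs(
            [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)], "fish_pLC50", "chi_iam"
        )
        assert model.beta0 == pytest.approx(0.0, abs=1e-12)
        assert model.beta1 == pytest.approx(1.0)
        assert not model.warnings

    def test_fish_model_recovered_from_published_pairs(self, registry):
        model = registry[("fish_pLC50", "chi_iam")]
        assert model.beta0 == pytest.approx(2.404, abs=0.002)
        assert model.beta1 == pytest.approx(0.0481, abs=0.0002)
        assert not model.warnings

    def test_daphnia_model_recovered_from_published_pairs(self, registry):
        model = registry[("daphnia_pEC50", "chi_iam")]
        assert model.beta0 == pytest.approx(2.688, abs=0.002)
        assert model.beta1 == pytest.approx(0.0381, abs=0.0002)
        assert not model.warnings

    def test_logp_models_flagged_nonlinear(self, registry):
        # published log P predictions are not collinear with the descriptor table
        assert "non_linear_in_descriptor" in registry[("fish_pLC50", "log_p")].warnings
        assert "non_linear_in_descriptor" in registry[("daphnia_pEC50", "log_p")].warnings

    def test_recovery_matches_brute_force_ols(self, chi_by_name, fish_table):
        pairs = [
            (chi_by_name[n], p)
            for n, p in zip(fish_table["name"], fish_table["chi_model"])
        ]
        model = recover_model_from_pairs(pairs, "fish_pLC50", "chi_iam")
        beta = _normal_equations([p[0] for p in pairs], [p[1] for p in pairs])
        assert model.beta0 == pytest.approx(beta[0], abs=1e-10)
        assert model.beta1 == pytest.approx(beta[1], abs=1e-10)

    def test_leave_one_out_stability_of_chi_slopes(self, chi_by_name, daphnia_table):
        """The published pairs are collinear to rounding: LOO moves beta1 < 2%."""
        pairs = [
            (chi_by_name[n], p)
            for n, p in zip(daphnia_table["name"], daphnia_table["chi_model"])
        ]
        full = recover_model_from_pairs(pairs, "daphnia_pEC50", "chi_iam")
        for i in range(len(pairs)):
            loo = recover_model_from_pairs(
                pairs[:i] + pairs[i + 1 :], "daphnia_pEC50", "chi_iam"
            )
            assert abs(loo.beta1 - full.beta1) / abs(full.beta1) < 0.02

    def test_needs_two_distinct_descriptor_values(self):
        with pytest.raises(InsufficientDataError):
            recover_model_from_pairs([(1.0, 2.0), (1.0, 2.1)], "fish_pLC50", "chi_iam")


class TestPredictEndpoint:
    def test_meradimate_fish_prediction(self, registry):
        rec = CompoundRecord(name="Meradimate", mw=275, chi_iam=56.9)
        ev = predict_endpoint(registry[("fish_pLC50", "chi_iam")], rec)
        assert ev.source == "chi_model"
        assert round(ev.p_value, 2) == 5.14

    def test_homosalate_daphnia_prediction(self, registry):
        rec = CompoundRecord(name="Homosalate", mw=262, chi_iam=56.8)
        ev = predict_endpoint(registry[("daphnia_pEC50", "chi_iam")], rec)
        assert round(ev.p_value, 2) == 4.85

    def test_zero_slope_model_returns_intercept(self):
        from iamtox.qsar_models import LinearModel

        model = LinearModel("fish_pLC50", "chi_iam", beta0=3.3, beta1=0.0)
        rec = CompoundRecord(name="x", mw=100, chi_iam=123.0)
        assert predict_endpoint(model, rec).p_value == 3.3

    def test_missing_descriptor_names_compound(self, registry):
        rec = CompoundRecord(name="NoChi", mw=100)
        with pytest.raises(MissingDescriptorError, match="NoChi"):
            predict_endpoint(registry[("fish_pLC50", "chi_iam")], rec)


def test_published_fit_statistics_imply_n29_for_chi_models(registry):
    """F = R^2 (n-2)/(1-R^2) applied to the published (F, R^2) pins n ~ 29."""
    for endpoint in ("fish_pLC50", "daphnia_pEC50"):
        assert registry[(endpoint, "chi_iam")].stats.n == 29
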