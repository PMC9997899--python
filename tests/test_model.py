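"""Likelihood families, linear predictor, priors — closed forms and oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from routetrend.model import (ModelSpec, ParameterState, linear_predictor,
                              log_posterior, negbin_log_pmf, select_family,
                              zip_log_pmf)


def _toy_table():
    """Three observations on two routes, one year."""
    return pd.DataFrame({
        "y": [0, 3, 1],
        "x_focal": [1.0, 1.0, 0.0],
        "grass250": [0.2, 0.6, 0.4],
        "grass2500": [0.5, 0.5, 0.3],
        "route_idx": [0, 0, 1],
        "year_idx": [0, 0, 0],
        "route_year_idx": [0, 0, 1],
    })


def _toy_state(omega=0.4):
    return ParameterState(
        beta=np.array([0.1, -0.2, 0.3]),
        eps=np.array([[0.15], [-0.05]]),
        alpha=np.array([0.1, 0.0]),
        mu=0.05, sigma=0.5, tau=0.8, omega=omega,
    )


class TestSelectFamily:
    def test_zero_fraction_threshold(self):
        zip_counts = np.array([0] * 26 + [1] * 74)
        pois_counts = np.array([0] * 24 + [1] * 76)
        assert select_family(zip_counts) == "zip"
        assert select_family(pois_counts) == "poisson"

    def test_exactly_at_threshold_is_poisson(self):
        # the rule is strictly greater-than 25 %
        assert select_family(np.array([0] * 25 + [1] * 75)) == "poisson"

    def test_overdispersion_override(self):
        rng = np.random.default_rng(0)
        y = rng.negative_binomial(0.5, 0.1, size=1000)  # heavy overdispersion
        y[y == 0] = 1  # keep zero fraction low
        y[:10] = 0
        assert select_family(y, auto_negbin=True) == "negbin"
        assert select_family(y, auto_negbin=False) == "poisson"

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            select_family(np.array([]))


class TestZipLogPmf:
    def test_certain_structural_zero(self):
        assert zip_log_pmf(0, 5.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_poisson_at_omega_zero(self):
        y = np.arange(0, 30)
        assert np.allclose(zip_log_pmf(y, 3.7, 0.0), stats.poisson.logpmf(y, 3.7))

    def test_closed_form_mixture_value(self):
        # y=0, lambda=2, omega=0.5 -> log(0.5 + 0.5 e^{-2})
        expected = np.log(0.5 + 0.5 * np.exp(-2.0))
        assert zip_log_pmf(0, 2.0, 0.5) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-0.5662, abs=5e-5)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0])
    @pytest.mark.parametrize("omega", [0.0, 0.3, 0.9])
    def test_normalization(self, lam, omega):
        y = np.arange(0, 501)
        total = np.exp(zip_log_pmf(y, lam, omega)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            zip_log_pmf(0, 1.0, 1.5)
        with pytest.raises(ValueError):
            zip_log_pmf(-1, 1.0, 0.5)


class TestNegbinLogPmf:
    def test_geometric_closed_forms(self):
        # r = 1, lambda = 1 -> geometric with p = 1/2
        assert negbin_log_pmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)
        assert negbin_log_pmf(1, 1.0, 1.0) == pytest.approx(np.log(0.25), abs=1e-12)

    def test_large_dispersion_matches_poisson(self):
        # the r -> inf error is O(y^2 / r), so 1e-4 agreement holds for y <= 14
        y = np.arange(0, 15)
        for lam in (0.5, 3.0, 10.0):
            assert np.allclose(negbin_log_pmf(y, lam, 1e6),
                               stats.poisson.logpmf(y, lam), atol=1e-4)

    def test_mean_and_variance_parameterization(self):
        lam, r = 4.0, 2.0
        y = np.arange(0, 400)
        p = np.exp(negbin_log_pmf(y, lam, r))
        mean = (y * p).sum()
        var = ((y - mean) ** 2 * p).sum()
        assert mean == pytest.approx(lam, rel=1e-8)
        assert var == pytest.approx(lam + lam ** 2 / r, rel=1e-6)

    @pytest.mark.parametrize("r", [0.5, 2.0, 50.0])
    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0])
    def test_normalization(self, lam, r):
        y = np.arange(0, 2001)
        assert np.exp(negbin_log_pmf(y, lam, r)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            negbin_log_pmf(0, 1.0, 0.0)


class TestLinearPredictor:
    def test_null_state_gives_unit_lambda(self):
        state = _toy_state()
        state.beta = np.zeros(3)
        state.eps = np.zeros_like(state.eps)
        assert np.allclose(linear_predictor(state, _toy_table()), 1.0)

    def test_effect_sizes_compose_on_log_scale(self):
        # beta = (0.078, 0.196, 0.908) at x_focal=1, grass250=grass2500=0.5
        state = _toy_state()
        state.beta = np.array([0.078, 0.196, 0.908])
        state.eps = np.zeros_like(state.eps)
        table = _toy_table().assign(x_focal=1.0, grass250=0.5, grass2500=0.5)
        lam = linear_predictor(state, table)
        assert np.allclose(lam, np.exp(0.630))
        assert lam[0] == pytest.approx(1.8776, abs=5e-4)

    def test_additive_eps_multiplies_lambda(self):
        state = _toy_state()
        base = linear_predictor(state, _toy_table())
        state.eps = state.eps + np.log(2.0)
        assert np.allclose(linear_predictor(state, _toy_table()), 2.0 * base)


class TestLogPosterior:
    def test_matches_term_by_term_oracle(self):
        """Brute-force sum of every density term on the 3-observation toy."""
        table, state = _toy_table(), _toy_state()
        spec = ModelSpec(family="zip")
        lam = np.exp(state.beta[0] * table["x_focal"]
                     + state.beta[1] * table["grass250"]
                     + state.beta[2] * table["grass2500"]
                     + state.eps.reshape(-1)[table["route_year_idx"]])
        obs = 0.0
        for y, l in zip(table["y"], lam):
            if y == 0:
                obs += np.log(state.omega + (1 - state.omega) * stats.poisson.pmf(0, l))
            else:
                obs += np.log(1 - state.omega) + stats.poisson.logpmf(y, l)
        expected = (
            obs
            + stats.norm.logpdf(state.eps, state.alpha[:, None], state.sigma).sum()
            + stats.norm.logpdf(state.alpha, state.mu, state.tau).sum()
            + stats.norm.logpdf(state.beta, 0.0, np.sqrt(1000.0)).sum()
            + stats.norm.logpdf(state.mu, 0.0, np.sqrt(1000.0))
        )
        assert log_posterior(state, table, spec) == pytest.approx(expected, rel=1e-12)

    def test_zip_omega_zero_equals_poisson(self):
        table = _toy_table()
        state = _toy_state(omega=0.0)
        assert log_posterior(state, table, ModelSpec(family="zip")) == pytest.approx(
            log_posterior(state, table, ModelSpec(family="poisson")), rel=1e-12)

    def test_invariant_to_observation_order(self):
        table, state = _toy_table(), _toy_state()
        spec = ModelSpec(family="zip")
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert log_posterior(state, table, spec) == pytest.approx(
            log_posterior(state, shuffled, spec), rel=1e-12)

    def test_out_of_support_returns_neg_inf_not_exception(self):
        table, state = _toy_table(), _toy_state()
        spec = ModelSpec(family="zip")
        state.sigma = 0.0
        assert log_posterior(state, table, spec) == -np.inf
        state.sigma, state.tau = 0.5, 11.0
        assert log_posterior(state, table, spec) == -np.inf

    def test_certain_zero_inflation_contributes_nothing(self):
        # one y=0 observation with omega=1: observation term is log(1) = 0
        table = _toy_table().iloc[:1]
        state = _toy_state(omega=1.0)
        spec = ModelSpec(family="zip")
        expected = (
            stats.norm.logpdf(state.eps, state.alpha[:, None], state.sigma).sum()
            + stats.norm.logpdf(state.alpha, state.mu, state.tau).sum()
            + stats.norm.logpdf(state.beta, 0.0, np.sqrt(1000.0)).sum()
            + stats.norm.logpdf(state.mu, 0.0, np.sqrt(1000.0))
        )
        assert log_posterior(state, table, spec) == pytest.approx(expected, rel=1e-12)


class TestModelSpec:
    def test_roundtrip_serialization(self):
        spec = ModelSpec(family="negbin", r_upper=25.0)
        assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(effect_prior_variance=0.0)
        with pytest.raises(ValueError):
            ModelSpec(family="zip", sigma_upper=-1.0)
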