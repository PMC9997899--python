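"""Trend statistic algebra, posterior summaries and response curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import routetrend as rt
from routetrend.mcmc import PosteriorDraws
from routetrend.trends import (predict_response_curve, route_year_abundance,
                               summarize_posterior, trend_statistics)

SC2 = {"F01": "focal", "P01": "paired"}


def _draws(params, route_ids=("F01", "P01"), years=(2001, 2002), family="poisson"):
    return PosteriorDraws(params=params, route_ids=list(route_ids),
                          years=list(years), family=family)


class TestTrendStatistics:
    def test_constant_abundance_is_stable(self):
        lam = np.full((5, 2, 4), 3.7)
        est = trend_statistics(lam, ["F01", "P01"], SC2)
        assert np.allclose(est.route_R, 0.0)
        assert np.allclose(est.overall_R, 0.0)

    def test_doubling_every_year_gives_unit_growth(self):
        lam = np.array([[[1, 2, 4, 8], [5, 10, 20, 40]]], dtype=float)
        est = trend_statistics(lam, ["F01", "P01"], SC2)
        assert np.allclose(est.route_R, 1.0)
        assert np.allclose(est.overall_R, 1.0)

    def test_crash_and_recovery_cancels(self):
        # (100, 50, 100): ratios (0.5, 2), geometric mean 1 -> R = 0
        lam = np.array([[[100.0, 50.0, 100.0]]])
        est = trend_statistics(lam, ["F01"], {"F01": "focal"})
        assert est.route_R[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_group_of_one_route_equals_route_trend(self):
        rng = np.random.default_rng(3)
        lam = rng.uniform(1, 10, size=(20, 2, 5))
        est = trend_statistics(lam, ["F01", "P01"], SC2)
        assert np.allclose(est.focal_R, est.route_R[:, 0])
        assert np.allclose(est.paired_R, est.route_R[:, 1])

    def test_route_constant_rescaling_leaves_R_unchanged(self):
        rng = np.random.default_rng(4)
        lam = rng.uniform(1, 10, size=(10, 3, 6))
        sc = {"F01": "focal", "F02": "focal", "P01": "paired"}
        base = trend_statistics(lam, ["F01", "F02", "P01"], sc)
        scaled = lam * np.array([2.0, 0.5, 7.0])[None, :, None]
        out = trend_statistics(scaled, ["F01", "F02", "P01"], sc)
        assert np.allclose(out.route_R, base.route_R)
        assert np.allclose(out.overall_R, base.overall_R)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_overall_R_bounded_by_route_extremes(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(0.5, 20.0, size=(4, 3, 5))
        sc = {"F01": "focal", "F02": "focal", "P01": "paired"}
        est = trend_statistics(lam, ["F01", "F02", "P01"], sc)
        lo = est.route_R.min(axis=1) - 1e-12
        hi = est.route_R.max(axis=1) + 1e-12
        assert np.all((est.overall_R >= lo) & (est.overall_R <= hi))

    def test_nonpositive_lambda_rejected(self):
        lam = np.ones((1, 1, 3))
        lam[0, 0, 1] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            trend_statistics(lam, ["F01"], {"F01": "focal"})

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            trend_statistics(np.ones((1, 1, 1)), ["F01"], {"F01": "focal"})

    def test_summary_table_structure(self):
        lam = np.full((8, 2, 3), 2.0)
        df = trend_statistics(lam, ["F01", "P01"], SC2).summary()
        assert set(df["level"]) == {"route", "focal", "paired", "overall"}
        assert list(df.columns) == ["level", "unit", "median", "lower95",
                                    "upper95", "pr_direction"]


class TestRouteYearAbundance:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["x_focal", "grass250", "grass2500",
                                         "route_year_idx"])
        return df

    def _one_draw(self, beta, eps, K, T):
        params = {
            "beta1": np.full((1, 1), beta[0]),
            "beta2": np.full((1, 1), beta[1]),
            "beta3": np.full((1, 1), beta[2]),
            "mu": np.zeros((1, 1)), "sigma": np.full((1, 1), 0.3),
            "tau": np.full((1, 1), 0.3),
            "alpha": np.zeros((1, 1, K)),
            "eps": np.asarray(eps, dtype=float).reshape(1, 1, K, T),
        }
        return _draws(params, route_ids=[f"R{k}" for k in range(K)],
                      years=list(range(2001, 2001 + T)))

    def test_single_point_route_passes_lambda_through(self):
        table = self._table([(0.0, 0.5, 0.5, 0)])
        draws = self._one_draw((0.0, 1.0, 0.0), [[0.2]], 1, 1)
        lam = route_year_abundance(draws, table)
        assert lam[0, 0, 0] == pytest.approx(np.exp(0.5 + 0.2), rel=1e-12)

    def test_points_average_arithmetically(self):
        # two points with lambda 2 and 4 -> cell index 3
        eps = [[np.log(2.0)]]
        table = self._table([(0.0, 0.0, 0.0, 0), (0.0, np.log(2.0), 0.0, 0)])
        draws = self._one_draw((0.0, 1.0, 0.0), eps, 1, 1)
        lam = route_year_abundance(draws, table)
        assert lam[0, 0, 0] == pytest.approx(3.0, rel=1e-12)

    def test_pure_random_effect_abundance(self):
        # all beta = 0, eps = log 2 -> lambda = 2 for every route-year
        table = self._table([(1.0, 0.3, 0.7, 0), (0.0, 0.9, 0.1, 1)])
        draws = self._one_draw((0.0, 0.0, 0.0), [[np.log(2.0)], [np.log(2.0)]], 2, 1)
        lam = route_year_abundance(draws, table)
        assert np.allclose(lam, 2.0)

    def test_empty_cell_rejected(self):
        table = self._table([(0.0, 0.5, 0.5, 0)])  # cell 1 has no points
        draws = self._one_draw((0.0, 0.0, 0.0), [[0.0, 0.0]], 1, 2)
        with pytest.raises(ValueError, match="zero points"):
            route_year_abundance(draws, table)


class TestSummarizePosterior:
    def _scalar_draws(self, values):
        return _draws({"beta1": np.asarray(values, dtype=float).reshape(1, -1)})

    def test_all_positive_draws_give_f_one(self):
        df = summarize_posterior(self._scalar_draws([0.5, 1.2, 0.1, 2.0]))
        assert df.loc[0, "f"] == 1.0

    def test_symmetric_draws_give_f_half(self):
        df = summarize_posterior(self._scalar_draws([-2.0, -1.0, 1.0, 2.0]))
        assert df.loc[0, "f"] == 0.5

    def test_direct_count(self):
        df = summarize_posterior(self._scalar_draws([-1.0, 2.0, 3.0, 4.0]))
        assert df.loc[0, "f"] == 0.75

    def test_interval_orders(self, small_fit):
        draws, _ = small_fit
        df = summarize_posterior(draws)
        assert (df["lower95"] <= df["median"]).all()
        assert (df["median"] <= df["upper95"]).all()
        assert df["f"].between(0.5, 1.0).all()


class TestResponseCurve:
    def _table(self):
        return pd.DataFrame({"x_focal": [1.0, 0.0], "grass250": [0.2, 0.6],
                             "grass2500": [0.5, 0.3]})

    def test_zero_effect_gives_flat_curve(self):
        params = {"beta1": np.zeros((1, 3)), "beta2": np.zeros((1, 3)),
                  "beta3": np.ones((1, 3)), "mu": np.zeros((1, 3))}
        curve = predict_response_curve(_draws(params), self._table(), "grass250")
        assert np.allclose(curve["median"], curve["median"].iloc[0])

    def test_single_draw_exponential_curve(self):
        # beta2 = 1 and all other terms zero -> curve is exp(grid) exactly
        params = {"beta1": np.zeros((1, 1)), "beta2": np.ones((1, 1)),
                  "beta3": np.zeros((1, 1)), "mu": np.zeros((1, 1))}
        table = pd.DataFrame({"x_focal": [0.0], "grass250": [0.5], "grass2500": [0.0]})
        grid = np.linspace(0, 1, 11)
        curve = predict_response_curve(_draws(params), table, "grass250", grid)
        assert np.allclose(curve["median"], np.exp(grid))
        assert np.allclose(curve["lower95"], curve["upper95"])  # single draw: no band

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="grass250 or grass2500"):
            predict_response_curve(_draws({"beta1": np.zeros((1, 1))}),
                                   self._table(), "elevation")

    def test_grid_outside_unit_interval_rejected(self):
        params = {"beta1": np.zeros((1, 1)), "beta2": np.zeros((1, 1)),
                  "beta3": np.zeros((1, 1)), "mu": np.zeros((1, 1))}
        with pytest.raises(ValueError, match="0, 1"):
            predict_response_curve(_draws(params), self._table(), "grass250",
                                   np.array([-0.2, 0.5]))
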