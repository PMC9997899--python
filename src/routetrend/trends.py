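"""Derived quantities: route-year abundance, growth-rate trends, summaries.

The trend statistic for a route is the proportional year-over-year change
R[k,t] = lambda[k,t+1] / lambda[k,t] - 1, aggregated across years (and
routes, for group trends) by the geometric mean of the growth ratios
g = lambda[t+1] / lambda[t], reported as GM(g) - 1.  R = 0 is a stable
population, R > 0 growing, R < 0 declining.  All trend quantities are
computed within each posterior draw and summarized across draws, so their
credible intervals propagate the full posterior uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws


@dataclass
class TrendEstimate:
    """Per-draw trend statistics and their posterior summary table."""

    route_R: np.ndarray        # (n_draws, K)
    focal_R: np.ndarray        # (n_draws,)
    paired_R: np.ndarray       # (n_draws,)
    overall_R: np.ndarray      # (n_draws,)
    route_ids: list[str]
    site_class: dict[str, str]

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, rid in enumerate(self.route_ids):
            rows.append(_summary_row("route", rid, self.route_R[:, k]))
        rows.append(_summary_row("focal", "focal", self.focal_R))
        rows.append(_summary_row("paired", "paired", self.paired_R))
        rows.append(_summary_row("overall", "all", self.overall_R))
        return pd.DataFrame(rows)


def _summary_row(level: str, unit: str, x: np.ndarray) -> dict:
    return {
        "level": level,
        "unit": unit,
        "median": float(np.median(x)),
        "lower95": float(np.quantile(x, 0.025)),
        "upper95": float(np.quantile(x, 0.975)),
        "pr_direction": float(max((x > 0).mean(), (x < 0).mean())),
    }


def route_year_abundance(draws: PosteriorDraws, table, chunk: int = 500) -> np.ndarray:
    """Per-draw route-year relative abundance lambda[k,t].

    For each saved draw, lambda[k,t] is the arithmetic mean over the
    route's points of exp(linear predictor) — a positive relative-abundance
    index.  Returns an array of shape (n_total_draws, K, T), pooled across
    chains.
    """
    X = np.column_stack([
        table["x_focal"].to_numpy(dtype=float),
        table["grass250"].to_numpy(dtype=float),
        table["grass2500"].to_numpy(dtype=float),
    ])
    ryi = table["route_year_idx"].to_numpy(dtype=np.int64)
    beta = np.column_stack([draws.pooled("beta1"), draws.pooled("beta2"),
                            draws.pooled("beta3")])          # (N, 3)
    eps = draws.pooled("eps")                                  # (N, K, T)
    N, K, T = eps.shape
    n_cells = K * T
    counts = np.bincount(ryi, minlength=n_cells)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise ValueError(f"route-year cells with zero points: {empty.tolist()}")

    order = np.argsort(ryi, kind="stable")
    bounds = np.concatenate([[0], np.cumsum(counts)[:-1]])
    Xo = X[order]

    lam_kt = np.empty((N, K, T))
    for s in range(0, N, chunk):
        e = min(s + chunk, N)
        eta = Xo @ beta[s:e].T                                 # (n, c)
        eta += eps[s:e].reshape(e - s, n_cells)[:, ryi[order]].T
        lam = np.exp(eta)
        sums = np.add.reduceat(lam, bounds, axis=0)            # (n_cells, c)
        lam_kt[s:e] = (sums / counts[:, None]).T.reshape(e - s, K, T)
    return lam_kt


def trend_statistics(lam_kt: np.ndarray, route_ids: list[str],
                     site_class: dict[str, str]) -> TrendEstimate:
    """Geometric-mean growth-rate trends at route, group and overall levels.

    Per draw: growth ratios g[k,t] = lambda[k,t+1] / lambda[k,t]; a route's
    trend is GM over years of g minus 1; focal / paired / overall trends
    are GM over years and member routes minus 1.  Requires >= 2 years and
    strictly positive lambda.
    """
    lam = np.asarray(lam_kt, dtype=float)
    if lam.ndim != 3 or lam.shape[2] < 2:
        raise ValueError("need lambda of shape (draws, routes, >=2 years)")
    if np.any(lam <= 0):
        raise ValueError("non-positive route-year abundance")
    if len(route_ids) != lam.shape[1]:
        raise ValueError("route_ids length does not match lambda")

    log_g = np.diff(np.log(lam), axis=2)                       # (N, K, T-1)
    route_R = np.exp(log_g.mean(axis=2)) - 1.0                 # (N, K)
    focal_mask = np.array([site_class[r] == "focal" for r in route_ids])
    if focal_mask.any():
        focal_R = np.exp(log_g[:, focal_mask, :].mean(axis=(1, 2))) - 1.0
    else:
        focal_R = np.full(lam.shape[0], np.nan)
    if (~focal_mask).any():
        paired_R = np.exp(log_g[:, ~focal_mask, :].mean(axis=(1, 2))) - 1.0
    else:
        paired_R = np.full(lam.shape[0], np.nan)
    overall_R = np.exp(log_g.mean(axis=(1, 2))) - 1.0
    return TrendEstimate(route_R=route_R, focal_R=focal_R, paired_R=paired_R,
                         overall_R=overall_R, route_ids=list(route_ids),
                         site_class=dict(site_class))


def summarize_posterior(draws: PosteriorDraws, parameters: list[str] | None = None,
                        ) -> pd.DataFrame:
    """Posterior medians, central 95 % credible intervals and f per scalar.

    ``f`` is the proportion of pooled draws above zero for effects with a
    positive median, below zero otherwise — the posterior mass supporting
    the estimated direction of the effect.
    """
    names = parameters if parameters is not None else draws.scalar_names()
    rows = []
    for name in names:
        x = draws.pooled(name)
        if x.size == 0:
            raise ValueError(f"no draws for parameter {name}")
        rows.append({
            "parameter": name,
            "median": float(np.median(x)),
            "lower95": float(np.quantile(x, 0.025)),
            "upper95": float(np.quantile(x, 0.975)),
            "f": float(max((x > 0).mean(), (x < 0).mean())),
        })
    return pd.DataFrame(rows)


def predict_response_curve(draws: PosteriorDraws, table, which: str,
                           grid: np.ndarray | None = None) -> pd.DataFrame:
    """Predicted relative abundance across a grassland-cover gradient.

    For each grid value of ``which`` (grass250 or grass2500), the other
    covariates sit at their observed means, the random-effect level at the
    hypermean mu of each draw, and lambda = exp(eta) is summarized by the
    posterior median and central 95 % interval.
    """
    cov_names = ["x_focal", "grass250", "grass2500"]
    if which not in ("grass250", "grass2500"):
        raise ValueError("which must be grass250 or grass2500")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 21)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid values must lie in [0, 1] (cover proportions)")

    means = {c: float(table[c].mean()) for c in cov_names}
    beta = np.column_stack([draws.pooled("beta1"), draws.pooled("beta2"),
                            draws.pooled("beta3")])            # (N, 3)
    mu = draws.pooled("mu")                                    # (N,)
    j = cov_names.index(which)
    base = sum(beta[:, i] * means[c] for i, c in enumerate(cov_names) if i != j) + mu
    rows = []
    for g in grid:
        lam = np.exp(base + beta[:, j] * g)
        rows.append({
            "covariate": which,
            "value": float(g),
            "median": float(np.median(lam)),
            "lower95": float(np.quantile(lam, 0.025)),
            "upper95": float(np.quantile(lam, 0.975)),
        })
    return pd.DataFrame(rows)
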