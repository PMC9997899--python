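"""Synthetic roadside point-count surveys with known generative truth.

Emulates a paired-landscape monitoring design: ``n_pairs`` focal routes
(landscapes under grassland management) each matched to one unmanaged
paired route, every route surveyed at ``n_points`` roadside stops once per
year.  Counts are drawn from the same hierarchical model the package fits
(Poisson, zero-inflated Poisson, or negative binomial on top of a
log-linear predictor with route and route-year random effects), so the
generator doubles as the ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
import json
import math

import numpy as np
import pandas as pd

FAMILIES = ("poisson", "zip", "negbin")

COUNT_COLUMNS = ["route_id", "site_class", "point_id", "year", "species", "count"]


@dataclass(frozen=True)
class SurveyDesign:
    """Layout of a paired focal/reference roadside survey.

    Parameters
    ----------
    n_pairs
        Number of focal/paired route pairs (default 9, i.e. 18 routes).
    n_points
        Roadside point-count stops per route (default 50).
    years
        Ordered survey years (default 2001-2017 inclusive).
    """

    n_pairs: int = 9
    n_points: int = 50
    years: tuple[int, ...] = tuple(range(2001, 2018))

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        yrs = tuple(int(y) for y in self.years)
        if len(yrs) == 0:
            raise ValueError("years must be non-empty")
        if any(b <= a for a, b in zip(yrs, yrs[1:])):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "years", yrs)

    @property
    def n_routes(self) -> int:
        return 2 * self.n_pairs

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_rows(self) -> int:
        return self.n_routes * self.n_points * self.n_years

    def routes(self) -> list[tuple[str, str]]:
        """Route labels with site class, focal route first in each pair."""
        out: list[tuple[str, str]] = []
        for i in range(1, self.n_pairs + 1):
            out.append((f"F{i:02d}", "focal"))
            out.append((f"P{i:02d}", "paired"))
        return out


@dataclass
class TruthRecord:
    """True parameter values behind a simulated survey.

    ``beta1`` is the focal-area effect, ``beta2``/``beta3`` the grassland
    effects at the point (250-m) and route (2,500-m) scales; covariates
    enter as proportions in [0, 1].  Route means ``alpha[k] ~ N(mu, tau^2)``
    and route-year deviations ``eps[k,t] ~ N(alpha[k] + t*log(year_multiplier),
    sigma^2)`` act on the log scale.  ``year_multiplier`` injects a known
    deterministic trend (0.97 = 3 %/yr decline) for trend-recovery tests;
    with ``sigma = 0`` the injected trend is exact.

    After :func:`generate_survey` the realized ``alpha``, ``eps``, ``z`` and
    the complete (pre-withholding) covariate tables are stored back here.
    """

    family: str = "zip"
    beta1: float = 0.2
    beta2: float = 1.0
    beta3: float = 2.0
    mu: float = 0.0
    sigma: float = 0.3
    tau: float = 0.3
    omega: float = 0.3
    r: float = 2.0
    year_multiplier: float = 1.0
    # covariate generator: per-location intercept ~ U(range), per-year slope
    # ~ U(range), N(0, noise_sd) noise, clamped to [0, 1]
    cov_intercept_range: tuple[float, float] = (0.2, 0.8)
    cov_slope_range: tuple[float, float] = (-0.01, 0.01)
    cov_noise_sd: float = 0.02
    # covariate rows for years strictly before this are withheld from the
    # returned table (they exist in the truth) to exercise extrapolation
    missing_before: int | None = None
    species: str = "synthetic_species"
    seed: int = 0
    # realized values, filled by generate_survey
    alpha: np.ndarray | None = None
    eps: np.ndarray | None = None
    z: np.ndarray | None = None
    route_order: list[str] | None = None
    year_order: list[int] | None = None
    full_point_covariates: pd.DataFrame | None = None
    full_route_covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        for name in ("beta1", "beta2", "beta3", "mu", "sigma", "tau", "omega", "r"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.sigma < 0 or self.tau < 0:
            raise ValueError("sigma and tau must be >= 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if self.family == "negbin" and self.r <= 0:
            raise ValueError("negbin dispersion r must be > 0")
        if self.year_multiplier <= 0:
            raise ValueError("year_multiplier must be > 0")

    def to_json(self) -> str:
        """Serialize scalars (not realized arrays) for the run manifest."""
        d = asdict(self)
        for key in (
            "alpha",
            "eps",
            "z",
            "route_order",
            "year_order",
            "full_point_covariates",
            "full_route_covariates",
        ):
            d.pop(key, None)
        return json.dumps(d, indent=2, default=lambda o: list(o))


def _simulate_covariates(design: SurveyDesign, truth: TruthRecord, rng: np.random.Generator):
    """Per-location linear-in-year grassland trajectories, clamped to [0, 1]."""
    lo, hi = truth.cov_intercept_range
    slo, shi = truth.cov_slope_range
    years = np.asarray(design.years)
    t_idx = years - years[0]
    routes = design.routes()

    point_rows = []
    route_rows = []
    for route_id, _cls in routes:
        # route-level landscape cover
        b0 = rng.uniform(lo, hi)
        b1 = rng.uniform(slo, shi)
        g2500 = b0 + b1 * t_idx + rng.normal(0.0, truth.cov_noise_sd, size=len(years))
        g2500 = np.clip(g2500, 0.0, 1.0)
        for y, g in zip(years, g2500):
            route_rows.append((route_id, int(y), float(g)))
        # point-level local cover
        for a in range(1, design.n_points + 1):
            p0 = rng.uniform(lo, hi)
            p1 = rng.uniform(slo, shi)
            g250 = p0 + p1 * t_idx + rng.normal(0.0, truth.cov_noise_sd, size=len(years))
            g250 = np.clip(g250, 0.0, 1.0)
            for y, g in zip(years, g250):
                point_rows.append((route_id, a, int(y), float(g)))

    point = pd.DataFrame(point_rows, columns=["route_id", "point_id", "year", "grass250"])
    route = pd.DataFrame(route_rows, columns=["route_id", "year", "grass2500"])
    return point, route


def generate_survey(design: SurveyDesign, truth: TruthRecord):
    """Simulate one species' counts and covariates under ``truth``.

    Returns ``(counts, covariates, truth)`` where ``counts`` is a long-format
    DataFrame (one row per route x point x year), ``covariates`` is a
    :class:`~routetrend.covariates.CovariateTable` (with pre-cutoff years
    withheld when ``truth.missing_before`` is set), and ``truth`` is a copy
    carrying all realized latent values.
    """
    from .covariates import CovariateTable

    rng = np.random.default_rng(truth.seed)
    truth = replace(truth)

    point_cov, route_cov = _simulate_covariates(design, truth, rng)

    routes = design.routes()
    K = design.n_routes
    T = design.n_years
    years = np.asarray(design.years)

    alpha = rng.normal(truth.mu, truth.tau, size=K)
    trend = np.log(truth.year_multiplier) * np.arange(T)
    eps = rng.normal(alpha[:, None] + trend[None, :], truth.sigma, size=(K, T))

    # long-format frame aligned with the covariate tables
    route_ids = [r for r, _ in routes]
    site_class = {r: c for r, c in routes}
    frame = point_cov.merge(route_cov, on=["route_id", "year"], how="left")
    frame["site_class"] = frame["route_id"].map(site_class)
    k_idx = frame["route_id"].map({r: i for i, r in enumerate(route_ids)}).to_numpy()
    t_idx = frame["year"].map({int(y): i for i, y in enumerate(years)}).to_numpy()

    x_focal = (frame["site_class"] == "focal").to_numpy(dtype=float)
    log_lam = (
        truth.beta1 * x_focal
        + truth.beta2 * frame["grass250"].to_numpy()
        + truth.beta3 * frame["grass2500"].to_numpy()
        + eps[k_idx, t_idx]
    )
    lam = np.exp(log_lam)

    if truth.family == "zip":
        z = (rng.random(lam.size) < truth.omega).astype(np.int8)
        y = rng.poisson(lam * (1 - z))
        truth.z = z
    elif truth.family == "poisson":
        y = rng.poisson(lam)
    else:  # negbin, mean lam and variance lam + lam^2 / r
        p = truth.r / (truth.r + lam)
        y = rng.negative_binomial(truth.r, p)

    counts = pd.DataFrame(
        {
            "route_id": frame["route_id"],
            "site_class": frame["site_class"],
            "point_id": frame["point_id"],
            "year": frame["year"],
            "species": truth.species,
            "count": y.astype(np.int64),
        }
    )
    counts = counts.sort_values(["route_id", "point_id", "year"], ignore_index=True)

    truth.alpha = alpha
    truth.eps = eps
    truth.route_order = route_ids
    truth.year_order = [int(y) for y in years]
    truth.full_point_covariates = point_cov
    truth.full_route_covariates = route_cov

    if truth.missing_before is not None:
        pt = point_cov[point_cov["year"] >= truth.missing_before].reset_index(drop=True)
        rt = route_cov[route_cov["year"] >= truth.missing_before].reset_index(drop=True)
    else:
        pt, rt = point_cov.copy(), route_cov.copy()
    cov = CovariateTable(point=pt, route=rt)
    return counts, cov, truth


def expected_counts(truth: TruthRecord, covariates) -> pd.DataFrame:
    """Marginal expected count per (route, point, year) under ``truth``.

    For the zero-inflated family the marginal mean is ``(1 - omega) * lam``;
    otherwise it is ``lam``.  Requires the realized random effects stored by
    :func:`generate_survey`.
    """
    if truth.eps is None or truth.alpha is None:
        raise ValueError("truth has no realized random effects; run generate_survey first")
    point = covariates.point
    route = covariates.route
    frame = point.merge(route, on=["route_id", "year"], how="left")
    if frame["grass2500"].isna().any():
        bad = frame.loc[frame["grass2500"].isna(), ["route_id", "year"]].drop_duplicates()
        raise ValueError(f"missing route-level covariate rows: {bad.to_dict('records')}")

    route_ids = truth.route_order
    years = truth.year_order
    k_idx = frame["route_id"].map({r: i for i, r in enumerate(route_ids)}).to_numpy()
    t_idx = frame["year"].map({int(y): i for i, y in enumerate(years)}).to_numpy()
    x_focal = frame["route_id"].str.startswith("F").to_numpy(dtype=float)

    log_lam = (
        truth.beta1 * x_focal
        + truth.beta2 * frame["grass250"].to_numpy()
        + truth.beta3 * frame["grass2500"].to_numpy()
        + truth.eps[k_idx, t_idx]
    )
    lam = np.exp(log_lam)
    mean = (1.0 - truth.omega) * lam if truth.family == "zip" else lam
    out = frame[["route_id", "point_id", "year"]].copy()
    out["expected_count"] = mean
    return out
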