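"""Metropolis-within-Gibbs sampler for the hierarchical count model.

The sampler cycles, per iteration:

1. latent structural-zero indicators ``z`` — exact full-conditional draw
   (zip family only);
2. ``omega`` — conjugate Beta Gibbs step (zip only);
3. the effect vector ``beta`` — joint random-walk Metropolis against the
   observation likelihood and its normal prior;
4. likelihood-invariant translation moves for ``beta1`` and ``beta3``:
   because x_focal and grass2500 are constant within a route-year cell, a
   shift of the effect can be absorbed exactly by the route-year random
   effects, so the proposal ``(beta_j + d, eps - d * x_cell)`` leaves every
   observation's lambda unchanged and is accepted against the random-effect
   layer and the effect prior alone.  These moves traverse the weakly
   identified ridges (effects vs. random effects) that plain random-walk
   updates cross very slowly;
5. all route-year effects ``eps[k,t]`` — simultaneous per-cell random-walk
   Metropolis (cells are conditionally independent);
6. route means ``alpha`` and hypermean ``mu`` — exact normal Gibbs;
7. scales ``sigma``, ``tau`` — exact Gibbs draws from truncated
   inverse-gamma full conditionals under the Uniform(0, upper) priors;
8. dispersion ``r`` — reflected random-walk Metropolis (negbin only).

Step sizes adapt toward a target acceptance rate during burn-in only, so
detailed balance holds for every saved draw.  Chains are bit-reproducible
given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .model import ModelSpec

__all__ = [
    "SamplerConfig", "PosteriorDraws", "DiagnosticsReport",
    "run_sampler", "gelman_rubin", "compute_diagnostics",
    "update_latent_z", "update_omega", "update_normal_layer",
]


@dataclass
class SamplerConfig:
    """Chain protocol and proposal tuning.

    Defaults follow the study protocol: 3 chains, 4,000 burn-in iterations,
    thinning rate 2, and at least 12,000 saved samples in total across
    chains (i.e. 4,000 per chain).  ``prior_only`` disables the observation
    likelihood so the sampler targets the joint prior (used by
    prior-consistency tests).
    """

    n_chains: int = 3
    burn_in: int = 4000
    thin: int = 2
    saved_total: int = 12000
    seed: int = 0
    step_beta: float = 0.05
    step_eps: float = 0.15
    step_r: float = 0.5
    step_shift: float = 0.2
    adapt: bool = True
    adapt_interval: int = 100
    target_accept: float = 0.35
    prior_only: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("need n_chains >= 1, burn_in >= 0, thin >= 1")
        if self.saved_total < self.n_chains:
            raise ValueError("saved_total must be >= n_chains")

    @property
    def draws_per_chain(self) -> int:
        return -(-self.saved_total // self.n_chains)  # ceil

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorDraws:
    """Saved post-burn-in, thinned draws; arrays are (chains, draws, ...)."""

    params: dict[str, np.ndarray]
    route_ids: list[str]
    years: list[int]
    family: str

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (chains*draws, ...)."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.params.items() if v.ndim == 2]

    def to_dataframe(self) -> pd.DataFrame:
        """Flat draws table: chain, iteration, one column per scalar."""
        nc, nd = self.n_chains, self.n_draws
        cols: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(nc), nd),
            "iteration": np.tile(np.arange(nd), nc),
        }
        for name, a in self.params.items():
            if a.ndim == 2:
                cols[name] = a.reshape(-1)
            elif a.ndim == 3:
                for j in range(a.shape[2]):
                    cols[f"{name}[{j}]"] = a[:, :, j].reshape(-1)
            else:
                for j in range(a.shape[2]):
                    for t in range(a.shape[3]):
                        cols[f"{name}[{j},{t}]"] = a[:, :, j, t].reshape(-1)
        return pd.DataFrame(cols)


@dataclass
class DiagnosticsReport:
    rhat: dict[str, float]
    acceptance: dict[str, float]
    degenerate: list[str] = field(default_factory=list)
    threshold: float = 1.1

    @property
    def flagged(self) -> list[str]:
        return [k for k, v in self.rhat.items() if not (v < self.threshold)]

    @property
    def converged(self) -> bool:
        return len(self.flagged) == 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"parameter": k, "rhat": v, "converged": bool(v < self.threshold),
             "degenerate": k in self.degenerate}
            for k, v in self.rhat.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gibbs and Metropolis building blocks (array-level, exposed for tests)
# ---------------------------------------------------------------------------

def update_latent_z(y: np.ndarray, lam: np.ndarray, omega: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Exact full-conditional draw of the structural-zero indicators.

    For y > 0 the indicator is 0 with probability 1; for y = 0,
    ``Pr(z = 1) = omega / (omega + (1 - omega) * exp(-lambda))``.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    z = np.zeros(y.shape, dtype=np.int8)
    zero = y == 0
    if omega > 0 and zero.any():
        p1 = omega / (omega + (1.0 - omega) * np.exp(-lam[zero]))
        z[zero] = (rng.random(int(zero.sum())) < p1).astype(np.int8)
    return z


def update_omega(z: np.ndarray, rng: np.random.Generator) -> float:
    """Conjugate Gibbs draw: omega | z ~ Beta(1 + sum z, 1 + sum(1 - z)).

    With no observations the draw falls back to the Beta(1, 1) = U(0, 1)
    prior.
    """
    z = np.asarray(z)
    n1 = int(z.sum()) if z.size else 0
    return float(rng.beta(1 + n1, 1 + z.size - n1))


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposal back into [lo, hi] (symmetric reflection)."""
    width = hi - lo
    x = (x - lo) % (2.0 * width)
    if x > width:
        x = 2.0 * width - x
    return x + lo


class _NormalLayerState:
    """Mutable (eps, alpha, mu, sigma, tau) block used by the chain loop."""

    def __init__(self, eps, alpha, mu, sigma, tau):
        self.eps, self.alpha, self.mu = eps, alpha, mu
        self.sigma, self.tau = sigma, tau


def _sample_scale(ss: float, n: int, upper: float, rng: np.random.Generator) -> float:
    """Exact draw of a normal-layer scale with a Uniform(0, upper) prior.

    Given n residuals with sum of squares ss, the conditional of the
    variance v = scale^2 is InvGamma((n-1)/2, ss/2) truncated to
    (0, upper^2], sampled by CDF inversion.  Degenerate inputs (ss = 0 or
    n < 2, both probability-zero events in a running chain) fall back to a
    prior draw.
    """
    shape = (n - 1) / 2.0
    if ss <= 0.0 or shape <= 0.0:
        return float(rng.uniform(0.0, upper))
    cdf_max = float(stats.invgamma.cdf(upper ** 2, shape, scale=ss / 2.0))
    if cdf_max <= 0.0:  # all conditional mass above the prior bound
        return upper
    v = float(stats.invgamma.ppf(rng.uniform(0.0, cdf_max), shape, scale=ss / 2.0))
    return float(np.sqrt(min(v, upper ** 2)))


def update_normal_layer(layer: _NormalLayerState, spec: ModelSpec,
                        rng: np.random.Generator,
                        cell_loglik_delta=None,
                        step_eps: float = 0.15,
                        prior_mean: float = 0.0, prior_var: float = 1000.0):
    """One sweep over the nested normal layer.

    ``eps`` cells move by simultaneous random-walk Metropolis: the
    acceptance ratio combines the per-cell observation log-likelihood delta
    (``cell_loglik_delta(prop_eps) -> (K*T,)`` array; None means prior-only)
    with the N(alpha[k], sigma^2) layer.  ``alpha``, ``mu``, ``sigma`` and
    ``tau`` are exact Gibbs draws from their full conditionals (the scales
    via truncated inverse-gamma under the Uniform(0, upper) priors).
    Returns the eps acceptance rate for adaptation.
    """
    eps, alpha = layer.eps, layer.alpha
    K, T = eps.shape
    sig2, tau2 = layer.sigma ** 2, layer.tau ** 2

    # --- eps: vectorized per-cell random walk -----------------------------
    prop = eps + rng.normal(0.0, step_eps, size=eps.shape)
    prior_delta = ((eps - alpha[:, None]) ** 2 - (prop - alpha[:, None]) ** 2) / (2.0 * sig2)
    log_acc = prior_delta
    if cell_loglik_delta is not None:
        log_acc = log_acc + cell_loglik_delta(prop).reshape(K, T)
    accept = np.log(rng.random(size=eps.shape)) < log_acc
    eps[accept] = prop[accept]
    eps_acc_rate = float(accept.mean())

    # --- alpha: conjugate normal Gibbs ------------------------------------
    ebar = eps.mean(axis=1)
    prec = T / sig2 + 1.0 / tau2
    mean = (T * ebar / sig2 + layer.mu / tau2) / prec
    layer.alpha = alpha = mean + rng.normal(0.0, 1.0, size=K) / math.sqrt(prec)

    # --- mu: conjugate normal Gibbs (normal prior) ------------------------
    prec_mu = K / tau2 + 1.0 / prior_var
    mean_mu = (alpha.sum() / tau2 + prior_mean / prior_var) / prec_mu
    layer.mu = float(mean_mu + rng.normal() / math.sqrt(prec_mu))

    # --- sigma, tau: exact truncated inverse-gamma Gibbs ------------------
    ss_eps = float(((eps - alpha[:, None]) ** 2).sum())
    layer.sigma = _sample_scale(ss_eps, eps.size, spec.sigma_upper, rng)
    ss_alpha = float(((alpha - layer.mu) ** 2).sum())
    layer.tau = _sample_scale(ss_alpha, K, spec.tau_upper, rng)

    return {"eps": eps_acc_rate}


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------

class _Data:
    """Design-table arrays pre-extracted for the inner loop."""

    def __init__(self, table):
        self.y = table["y"].to_numpy(dtype=np.int64)
        self.X = np.column_stack([
            table["x_focal"].to_numpy(dtype=float),
            table["grass250"].to_numpy(dtype=float),
            table["grass2500"].to_numpy(dtype=float),
        ])
        self.ryi = table["route_year_idx"].to_numpy(dtype=np.int64)
        route_ids = table.attrs.get("route_ids") or sorted(table["route_id"].unique())
        years = table.attrs.get("years") or sorted(int(y) for y in table["year"].unique())
        self.route_ids, self.years = list(route_ids), [int(y) for y in years]
        self.K, self.T = len(self.route_ids), len(self.years)
        self.n_cells = self.K * self.T
        if self.ryi.max(initial=-1) >= self.n_cells:
            raise ValueError("route_year_idx inconsistent with route/year sets")
        self.gl_y1 = gammaln(self.y + 1.0)
        # per-cell covariates (constant within a route-year cell by design)
        self.cell_focal = np.zeros(self.n_cells)
        self.cell_g2500 = np.zeros(self.n_cells)
        np.maximum.at(self.cell_focal, self.ryi, self.X[:, 0])
        np.maximum.at(self.cell_g2500, self.ryi, self.X[:, 2])
        self.cell_counts = np.bincount(self.ryi, minlength=self.n_cells)
        with np.errstate(invalid="ignore"):
            self.cell_g250_mean = np.where(
                self.cell_counts > 0,
                np.bincount(self.ryi, weights=self.X[:, 1], minlength=self.n_cells)
                / np.maximum(self.cell_counts, 1), 0.0)


def _poisson_ll(data: _Data, lam: np.ndarray) -> np.ndarray:
    return data.y * np.log(lam) - lam - data.gl_y1


def _negbin_ll(data: _Data, lam: np.ndarray, r: float) -> np.ndarray:
    return (gammaln(data.y + r) - gammaln(r) - data.gl_y1
            + r * np.log(r / (r + lam)) + data.y * np.log(lam / (r + lam)))


class _Chain:
    """One MCMC chain; owns its RNG, state, caches and step sizes."""

    def __init__(self, data: _Data, spec: ModelSpec, cfg: SamplerConfig,
                 rng: np.random.Generator):
        self.data, self.spec, self.cfg, self.rng = data, spec, cfg, rng
        K, T = data.K, data.T
        # overdispersed start
        self.beta = rng.normal(0.0, 1.0, size=3)
        self.sigma = float(rng.uniform(0.5, 5.0))
        self.tau = float(rng.uniform(0.5, 5.0))
        self.mu = float(rng.normal(0.0, 1.0))
        alpha = rng.normal(self.mu, self.tau, size=K)
        eps = rng.normal(alpha[:, None], self.sigma, size=(K, T))
        self.layer = _NormalLayerState(eps, alpha, self.mu, self.sigma, self.tau)
        self.omega = float(rng.uniform(0.1, 0.9)) if spec.family == "zip" else 0.0
        self.r = float(rng.uniform(0.5, min(5.0, spec.r_upper))) if spec.family == "negbin" else 1.0
        self.z = np.zeros(data.y.size, dtype=np.int8)
        if spec.family == "zip":
            self.z = ((data.y == 0) & (rng.random(data.y.size) < self.omega)).astype(np.int8)
        self.steps = {"beta1": cfg.step_beta, "beta2": cfg.step_beta,
                      "beta3": cfg.step_beta, "eps": cfg.step_eps,
                      "r": cfg.step_r, "shift1": cfg.step_shift,
                      "shift2": cfg.step_shift, "shift3": cfg.step_shift}
        self.accepts = {k: [] for k in self.steps}
        self._refresh_cache()

    # -- likelihood caches -------------------------------------------------
    def _eta(self) -> np.ndarray:
        return self.data.X @ self.beta + self.layer.eps.reshape(-1)[self.data.ryi]

    def _obs_ll(self, lam: np.ndarray) -> np.ndarray:
        """Per-observation log-likelihood given lambda (zip: conditional on z)."""
        if self.cfg.prior_only:
            return np.zeros(lam.size)
        if self.spec.family == "negbin":
            return _negbin_ll(self.data, lam, self.r)
        ll = _poisson_ll(self.data, lam)
        if self.spec.family == "zip":
            ll = np.where(self.z == 1, 0.0, ll)  # z=1 forces y=0 deterministically
        return ll

    def _refresh_cache(self) -> None:
        self.eta = self._eta()
        self.lam = np.exp(self.eta)
        self.ll = self._obs_ll(self.lam)

    # -- per-iteration updates --------------------------------------------
    def _update_z_omega(self) -> None:
        if self.spec.family != "zip":
            return
        if self.cfg.prior_only:
            self.z = (self.rng.random(self.data.y.size) < self.omega).astype(np.int8)
        else:
            self.z = update_latent_z(self.data.y, self.lam, self.omega, self.rng)
        self.omega = update_omega(self.z, self.rng)
        self.ll = self._obs_ll(self.lam)

    def _beta_prior_delta(self, prop: np.ndarray) -> float:
        v = self.spec.effect_prior_variance
        m = self.spec.effect_prior_mean
        return float(((self.beta - m) ** 2 - (prop - m) ** 2).sum() / (2.0 * v))

    def _update_beta(self) -> None:
        """Per-coordinate random-walk Metropolis on the effect vector."""
        for j, key in enumerate(("beta1", "beta2", "beta3")):
            d = self.rng.normal(0.0, self.steps[key])
            prop = self.beta.copy()
            prop[j] += d
            eta_p = self.eta + d * self.data.X[:, j]
            lam_p = np.exp(eta_p)
            ll_p = self._obs_ll(lam_p)
            log_acc = float(ll_p.sum() - self.ll.sum()) + self._beta_prior_delta(prop)
            ok = math.log(self.rng.random()) < log_acc
            if ok:
                self.beta = prop
                self.eta, self.lam, self.ll = eta_p, lam_p, ll_p
            self.accepts[key].append(float(ok))

    def _update_shift(self) -> None:
        """Likelihood-invariant hierarchical shear moves for beta1 and beta3.

        x_focal and grass2500 are constant within a route-year cell, so the
        translation (beta_j + d, eps - d*x_cell, alpha - d*x_route,
        mu - d*x_bar) leaves every observation's lambda unchanged.  Shifting
        all three random-effect levels together means only within-level
        contrasts of the covariate enter the acceptance ratio, which lets
        the chain traverse the weakly identified effect/random-effect ridge
        in large steps.
        """
        moved = False
        for key, j, cell_x in (("shift1", 0, self.data.cell_focal),
                               ("shift3", 2, self.data.cell_g2500)):
            d = self.rng.normal(0.0, self.steps[key])
            eps, alpha, mu = self.layer.eps, self.layer.alpha, self.layer.mu
            xc = cell_x.reshape(self.data.K, self.data.T)
            x_route = xc.mean(axis=1)
            x_bar = float(x_route.mean())
            prop_eps = eps - d * xc
            prop_alpha = alpha - d * x_route
            prop_mu = mu - d * x_bar
            prop_bj = self.beta[j] + d
            sig2 = self.layer.sigma ** 2
            tau2 = self.layer.tau ** 2
            la = float((((eps - alpha[:, None]) ** 2
                         - (prop_eps - prop_alpha[:, None]) ** 2) / (2.0 * sig2)).sum())
            la += float((((alpha - mu) ** 2 - (prop_alpha - prop_mu) ** 2) / (2.0 * tau2)).sum())
            v = self.spec.effect_prior_variance
            m = self.spec.effect_prior_mean
            la += ((self.beta[j] - m) ** 2 - (prop_bj - m) ** 2) / (2.0 * v)
            la += ((mu - m) ** 2 - (prop_mu - m) ** 2) / (2.0 * v)
            ok = math.log(self.rng.random()) < la
            if ok:
                self.beta = self.beta.copy()
                self.beta[j] = prop_bj
                self.layer.eps = prop_eps
                self.layer.alpha = prop_alpha
                self.layer.mu = prop_mu
                moved = True
            self.accepts[key].append(float(ok))
        if moved:
            self._refresh_cache()  # lambda unchanged in exact arithmetic; refresh guards fp drift
        self._update_shift2()

    def _update_shift2(self) -> None:
        """Centered shear for beta2 (point-level grassland effect).

        grass250 varies within a route-year cell, so the shear cannot be
        fully likelihood-invariant; absorbing the cell, route and grand
        means of grass250 into eps, alpha and mu leaves a likelihood delta
        driven only by within-cell contrasts — the information that
        identifies beta2 — so the move follows the beta2/random-effect
        ridge in large steps.
        """
        d = self.rng.normal(0.0, self.steps["shift2"])
        data = self.data
        cell_mean = data.cell_g250_mean.reshape(data.K, data.T)
        route_mean = cell_mean.mean(axis=1)
        grand = float(route_mean.mean())
        eps, alpha, mu = self.layer.eps, self.layer.alpha, self.layer.mu
        prop_eps = eps - d * cell_mean
        prop_alpha = alpha - d * route_mean
        prop_mu = mu - d * grand
        prop = self.beta.copy()
        prop[1] += d
        # residual within-cell contrast enters the likelihood
        eta_p = self.eta + d * (data.X[:, 1] - data.cell_g250_mean[data.ryi])
        lam_p = np.exp(eta_p)
        ll_p = self._obs_ll(lam_p)
        la = float(ll_p.sum() - self.ll.sum())
        sig2 = self.layer.sigma ** 2
        tau2 = self.layer.tau ** 2
        la += float((((eps - alpha[:, None]) ** 2
                      - (prop_eps - prop_alpha[:, None]) ** 2) / (2.0 * sig2)).sum())
        la += float((((alpha - mu) ** 2 - (prop_alpha - prop_mu) ** 2) / (2.0 * tau2)).sum())
        v = self.spec.effect_prior_variance
        m = self.spec.effect_prior_mean
        la += ((self.beta[1] - m) ** 2 - (prop[1] - m) ** 2) / (2.0 * v)
        la += ((mu - m) ** 2 - (prop_mu - m) ** 2) / (2.0 * v)
        ok = math.log(self.rng.random()) < la
        if ok:
            self.beta = prop
            self.layer.eps = prop_eps
            self.layer.alpha = prop_alpha
            self.layer.mu = prop_mu
            self.eta, self.lam, self.ll = eta_p, lam_p, ll_p
        self.accepts["shift2"].append(float(ok))

    def _cell_loglik_delta(self, prop_eps: np.ndarray) -> np.ndarray:
        if self.cfg.prior_only:
            return np.zeros(self.data.n_cells)
        delta_eta = (prop_eps - self.layer.eps).reshape(-1)[self.data.ryi]
        lam_p = np.exp(self.eta + delta_eta)
        diff = self._obs_ll(lam_p) - self.ll
        return np.bincount(self.data.ryi, weights=diff, minlength=self.data.n_cells)

    def _update_normal_layer(self) -> None:
        res = update_normal_layer(
            self.layer, self.spec, self.rng,
            cell_loglik_delta=None if self.cfg.prior_only else self._cell_loglik_delta,
            step_eps=self.steps["eps"],
            prior_mean=self.spec.effect_prior_mean,
            prior_var=self.spec.effect_prior_variance,
        )
        for k, v in res.items():
            self.accepts[k].append(v)
        self._refresh_cache()

    def _update_r(self) -> None:
        if self.spec.family != "negbin":
            return
        prop = _reflect(self.r + self.rng.normal(0.0, self.steps["r"]), 0.0, self.spec.r_upper)
        ok = False
        if prop > 0.0 and not self.cfg.prior_only:
            ll_p = _negbin_ll(self.data, self.lam, prop)
            if math.log(self.rng.random()) < float(ll_p.sum() - self.ll.sum()):
                self.r = prop
                self.ll = ll_p
                ok = True
        elif prop > 0.0:
            # flat prior, no likelihood: always accept
            self.r, ok = prop, True
        self.accepts["r"].append(float(ok))

    def iterate(self) -> None:
        self._update_z_omega()
        self._update_beta()
        self._update_shift()
        self._update_normal_layer()
        self._update_r()

    def adapt_steps(self, target: float) -> None:
        for k in self.steps:
            acc = self.accepts[k]
            if not acc:
                continue
            rate = float(np.mean(acc[-self.cfg.adapt_interval:]))
            self.steps[k] = float(np.clip(self.steps[k] * math.exp(rate - target),
                                          1e-4, 50.0))

    def acceptance_rates(self, tail: int) -> dict[str, float]:
        out = {}
        for k, acc in self.accepts.items():
            if acc:
                out[k] = float(np.mean(acc[-tail:] if tail else acc))
        return out


def run_sampler(table, spec: ModelSpec, config: SamplerConfig):
    """Fit the model; returns (PosteriorDraws, DiagnosticsReport).

    Runs ``config.n_chains`` independent chains from overdispersed starting
    points, discards ``burn_in`` iterations, thins by ``thin`` and saves
    ``ceil(saved_total / n_chains)`` draws per chain.  Bit-reproducible for
    a fixed ``config.seed``.  Non-convergence is reported through the
    diagnostics (R-hat flags), never silently ignored.
    """
    data = _Data(table)
    cfg = config
    n_save = cfg.draws_per_chain
    n_iter = cfg.burn_in + n_save * cfg.thin

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    store: dict[str, np.ndarray] = {
        "beta1": np.empty((cfg.n_chains, n_save)),
        "beta2": np.empty((cfg.n_chains, n_save)),
        "beta3": np.empty((cfg.n_chains, n_save)),
        "mu": np.empty((cfg.n_chains, n_save)),
        "sigma": np.empty((cfg.n_chains, n_save)),
        "tau": np.empty((cfg.n_chains, n_save)),
        "alpha": np.empty((cfg.n_chains, n_save, data.K)),
        "eps": np.empty((cfg.n_chains, n_save, data.K, data.T)),
    }
    if spec.family == "zip":
        store["omega"] = np.empty((cfg.n_chains, n_save))
    if spec.family == "negbin":
        store["r"] = np.empty((cfg.n_chains, n_save))

    acc_all: list[dict[str, float]] = []
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        chain = _Chain(data, spec, cfg, rng)
        saved = 0
        for it in range(n_iter):
            chain.iterate()
            in_burn = it < cfg.burn_in
            if in_burn and cfg.adapt and (it + 1) % cfg.adapt_interval == 0:
                chain.adapt_steps(cfg.target_accept)
            if not in_burn and (it - cfg.burn_in + 1) % cfg.thin == 0 and saved < n_save:
                store["beta1"][c, saved] = chain.beta[0]
                store["beta2"][c, saved] = chain.beta[1]
                store["beta3"][c, saved] = chain.beta[2]
                store["mu"][c, saved] = chain.layer.mu
                store["sigma"][c, saved] = chain.layer.sigma
                store["tau"][c, saved] = chain.layer.tau
                store["alpha"][c, saved] = chain.layer.alpha
                store["eps"][c, saved] = chain.layer.eps
                if spec.family == "zip":
                    store["omega"][c, saved] = chain.omega
                if spec.family == "negbin":
                    store["r"][c, saved] = chain.r
                saved += 1
        acc_all.append(chain.acceptance_rates(tail=n_save * cfg.thin))

    draws = PosteriorDraws(params=store, route_ids=data.route_ids,
                           years=data.years, family=spec.family)
    acceptance = {k: float(np.mean([a[k] for a in acc_all if k in a]))
                  for k in acc_all[0]}
    report = compute_diagnostics(draws, acceptance=acceptance)
    return draws, report


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray, return_flag: bool = False):
    """Classical Gelman-Rubin potential scale reduction factor.

    ``chains`` is an (m, n) array of m chains with n draws each.  With
    within-chain variance W, between-chain variance B (n times the variance
    of the chain means), the pooled variance estimate is
    ``(n - 1)/n * W + B/n`` and R-hat is ``sqrt(pooled / W)``.  Fully
    degenerate input (all values identical, W = B = 0) returns 1.0 with the
    degeneracy flag set.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    m, n = x.shape
    W = float(x.var(axis=1, ddof=1).mean())
    B = float(n * x.mean(axis=1).var(ddof=1))
    if W == 0.0:
        rhat, flag = (1.0, True) if B == 0.0 else (np.inf, True)
    else:
        pooled = (n - 1) / n * W + B / n
        rhat, flag = float(np.sqrt(pooled / W)), False
    return (rhat, flag) if return_flag else rhat


def compute_diagnostics(draws: PosteriorDraws, acceptance: dict[str, float] | None = None,
                        threshold: float = 1.1, include_random_effects: bool = True,
                        ) -> DiagnosticsReport:
    """Per-parameter R-hat over all saved scalars (and random effects)."""
    rhat: dict[str, float] = {}
    degenerate: list[str] = []

    def record(name: str, mat: np.ndarray) -> None:
        val, flag = gelman_rubin(mat, return_flag=True)
        rhat[name] = val
        if flag:
            degenerate.append(name)

    for name, a in draws.params.items():
        if a.ndim == 2:
            record(name, a)
        elif include_random_effects and a.ndim == 3:
            for j in range(a.shape[2]):
                record(f"{name}[{j}]", a[:, :, j])
        elif include_random_effects:
            for j in range(a.shape[2]):
                for t in range(a.shape[3]):
                    record(f"{name}[{j},{t}]", a[:, :, j, t])
    return DiagnosticsReport(rhat=rhat, acceptance=acceptance or {},
                             degenerate=degenerate, threshold=threshold)
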