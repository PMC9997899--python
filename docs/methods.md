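# Methods

This note documents the statistical model, the sampler, the synthetic-data
generator and the numerical choices behind `routetrend`, in enough detail
that a user can judge what a green test establishes and what it does not.

## Observation model and process model

The response is the count of one species at one roadside point in one
year. Three likelihood families are supported:

* **Poisson** — `y ~ Poisson(λ)`, for species detected at most stops.
* **Zero-inflated Poisson (default)** — `y ~ Poisson(λ·(1−z))` with
  `z ~ Bernoulli(ω)`. The latent indicator is implemented literally:
  `z = 1` forces a degenerate zero regardless of λ, so ω is the
  structural-zero probability (excess non-detections beyond Poisson
  sampling zeros). The family-selection rule picks this family when the
  observed zero fraction strictly exceeds 25 %.
* **Negative binomial** — mean λ, variance `λ + λ²/r`, for overdispersed
  species. An optional automatic override selects it when the sample
  variance/mean ratio exceeds a cutoff (default 2.0).

The process model is log-linear:

```
log λ[k,a,t] = β1·x_focal[k] + β2·grass250[k,a,t] + β3·grass2500[k,t] + ε[k,t]
ε[k,t] ~ N(α[k], σ²),  α[k] ~ N(μ, τ²)
```

There is no separate global intercept: μ, the hypermean of the route
effects, plays that role. Covariates enter as proportions in [0, 1]
(unstandardized); a `covariate_scale` flag records this choice and admits
percent or z-scored alternatives.

Priors: `β1–3, μ ~ N(0, 1000)` — read as **variance** 1000 (sd ≈ 31.6),
i.e. effectively flat at the scale of log-abundance. Engines that
parameterize normals by precision would read the same notation as variance
1/1000; the variance reading is recorded explicitly in `ModelSpec` because
only it yields a diffuse prior consistent with the protocol's intent.
`σ, τ ~ U(0, 10)`, `ω ~ U(0, 1)`, and the negative-binomial dispersion
`r ~ U(0, 50)` on the dispersion scale (configurable; the exact dispersion
prior used historically with this protocol is not documented anywhere we
can rely on).

A λ floor of 1e-12 guards logs against covariate extremes; it is
configurable and irrelevant for any realistic state.

**Identifiability.** `x_focal` and `grass2500` are constant within a
route-year, so β1 and β3 are confounded with the random effects: any shift
of β1 can be absorbed by the focal routes' α's, and any shift of β3 by the
route-year ε's. They are identified only through the hierarchical
shrinkage (α toward μ, ε toward α), and their posteriors are accordingly
wide. This is a property of the model as specified, not of the
implementation; the sampler is designed to mix across these ridges (below),
and the tests expect wide-but-calibrated intervals rather than tight ones.

## Sampler

Metropolis-within-Gibbs, hand-rolled and fully vectorized over
observations. Exact conjugate Gibbs steps are used wherever the full
conditional is standard:

* `z` — Bernoulli with `Pr(z=1 | y=0) = ω / (ω + (1−ω)e^{−λ})`; `z = 0`
  for `y > 0`.
* `ω` — `Beta(1 + Σz, 1 + Σ(1−z))`.
* `α`, `μ` — normal conditionals.
* `σ`, `τ` — the conditional of the variance under a `U(0, upper)` prior
  on the scale is an inverse-gamma truncated to `(0, upper²]`, sampled
  exactly by CDF inversion. (A reflected random walk was tried first and
  systematically under-visited the small-σ funnel, visibly distorting the
  prior-consistency check; the exact draw removed the defect.)

Random-walk Metropolis handles the rest: per-coordinate updates for β,
one simultaneous vectorized update of all ε cells (conditionally
independent given everything else), and a reflected walk on `(0, r_max)`
for the negative-binomial dispersion. For the zip family, λ-dependent
updates use the likelihood conditional on `z` (observations with `z = 1`
contribute nothing), which is cheaper than the marginal and mixes jointly
with the exact `z` draw.

**Shear moves.** Plain componentwise updates cross the β1/β3 ridges very
slowly. The sampler therefore adds hierarchical-centering translation
moves: propose `β_j + d` and simultaneously subtract `d` times the
covariate's cell value from ε, its route mean from α and its grand mean
from μ. Because the covariate is cell-constant, every observation's λ is
unchanged — the acceptance ratio involves only within-level contrasts of
the covariate in the normal layers plus the β and μ priors, so the move is
cheap and accepts large steps. β2 (point-level grassland) gets the
analogous centered shear, which is not fully likelihood-invariant — the
within-cell contrast of grass250 survives — but that residual is precisely
the information that identifies β2, so the move follows its ridge too.
These are ordinary Metropolis moves on deterministic volume-preserving
translations; detailed balance holds exactly.

**Adaptation and protocol.** Step sizes adapt every 100 iterations during
burn-in toward a 0.35 acceptance rate and are frozen afterwards, so all
saved draws come from a fixed, valid transition kernel. Defaults follow
the study protocol: 3 chains, 4,000 burn-in iterations, thinning 2, and
12,000 saved draws in total (4,000 per chain); `saved_total` is counted
across chains, matching the protocol's phrasing. Chains start
overdispersed (β ~ N(0,1), σ, τ ~ U(0.5, 5), ω ~ U(0.1, 0.9)) with
per-chain RNG streams spawned from the master seed; runs are
bit-reproducible.

Convergence uses the classical Gelman–Rubin PSRF
(`R̂ = sqrt(((n−1)/n·W + B/n)/W)`, no rank-normalization or chain
splitting, matching the diagnostic as originally defined); `R̂ < 1.1` on
every saved parameter (including each α and ε) is required unless the
caller opts out. Fully degenerate chains report `R̂ = 1` with a
degeneracy flag.

A `prior_only` switch disables the observation likelihood so the sampler
targets the joint prior; the test suite uses it to verify that every
marginal (β, μ, σ, τ, ω) reproduces its prior — a strong end-to-end check
of the transition kernel.

## Covariate extrapolation

Land-cover proportions are typically unavailable for the earliest survey
years. Missing years are filled by ordinary least squares of cover on
calendar year — fit independently per location (point for grass250, route
for grass2500) — with predictions clamped to [0, 1] and observed values
passed through untouched. Whether the original protocol pooled locations
or clamped is not documented; per-location fits with clamping are this
package's choice, recorded in a `source` column
(observed / extrapolated / carried). Locations with fewer than two
observed years carry the nearest observed value and emit a warning rather
than failing the run.

## Trend statistic

Route-level relative abundance λ[k,t] is the arithmetic mean over the
route's points of exp(linear predictor), computed within each posterior
draw. The reduction over points is not dictated by the trend definition
itself; the mean is the natural relative-abundance index, and because the
trend uses ratios, the choice (mean vs. sum) is immaterial whenever the
point count per route is constant.

The annual trend is `R[k,t] = λ[k,t+1]/λ[k,t] − 1`, aggregated as the
geometric mean of the **growth ratios** `g = λ[t+1]/λ[t]` minus one —
a literal geometric mean of R values would be undefined for negative R,
so the ratio form is used. Group trends (focal, paired, overall) take the
geometric mean of g over all years and member routes. Everything is
computed per draw and summarized across draws (median, central 95 %
interval, direction probability), so trend uncertainty inherits the full
posterior correlation structure.

Response curves fix the non-focus covariates at their observed means and
the random-effect level at each draw's μ; they summarize
`λ = exp(β_j·x + baseline)` over a cover grid in [0, 1].

## Synthetic-data generator

The generator emulates the target study design: 9 focal/paired route
pairs, 50 points per route, annual surveys 2001–2017 (15,300 rows), one
species at a time, one visit per route-year, with counts drawn from
exactly the hierarchical model above. Default true parameters are
β = (0.2, 1.0, 2.0), μ = 0, σ = τ = 0.3, ω = 0.3 — effect and variance
scales that produce zero fractions (~30–35 %) and mean counts (~2–3) in
the range reported for zero-inflated grassland species.

Grassland covariates follow per-location linear-in-year trajectories:
intercept ~ U(0.2, 0.8), slope ~ U(−0.01, 0.01) per year, Gaussian noise
(sd 0.02), clamped to [0, 1]. No empirical distribution for cover
trajectories is available, so these are conventions chosen to mimic mild
temporal trends around roughly half-grassland landscapes; all are
configurable. Years before a cutoff (2006 by default when enabled) can be
withheld from the returned covariate table to exercise extrapolation.

A `year_multiplier` parameter injects a deterministic trend through the
route-year effects (`ε[k,t]` means decline by `log(multiplier)` per year);
with σ = 0 the injected trend is exact, which the trend-recovery test uses
with multiplier 0.97 (a 3 %/yr decline). For that scenario the covariates
are held stationary (zero slope and noise) so that the true overall trend
is exactly −0.03; with drifting covariates the true trend differs from the
injected ε-trend by the covariate contribution, which is a property of the
world, not an error of the method. Trend recovery also needs adequate
per-cell information (points × mean count): hierarchical shrinkage of ε
toward route means attenuates recovered trends when cells are weakly
informed, so the recovery scenario uses an abundant species
(μ = 1.5, Poisson, 50 points/route). This attenuation is a real property
of the fitted model worth knowing about when interpreting trends for rare
species.

What the generator does **not** emulate: spatial autocorrelation beyond
the route random effect, observer effects, imperfect detection (absent
from the protocol being modeled), cross-species correlation, or revisit
structure. Green recovery tests therefore establish correctness of the
inference machinery under the model's own assumptions — not robustness to
the many ways real surveys violate them.

## Numerical choices and degenerate inputs

* Out-of-support states in `log_posterior` return −∞ rather than raising,
  so samplers and optimizers can probe freely.
* `zip_log_pmf` is computed via `logaddexp` in the zero branch for
  stability; `ω = 0` reproduces the Poisson log-pmf exactly (bit-equal).
* The negative-binomial pmf uses the mean–dispersion parameterization via
  `scipy.stats.nbinom(r, r/(r+λ))`; as r → ∞ it approaches the Poisson
  with error O(y²/r), which bounds the y-range over which the large-r
  agreement tests can demand 1e-4 accuracy.
* Ties/degeneracies in the PSRF (W = 0) return 1.0 with a flag rather
  than NaN.
* The pipeline writes byte-stable outputs: all randomness flows from the
  master seed, and the manifest excludes timestamps.

## Known limitations

* No imperfect-detection correction: λ is a relative-abundance index, and
  trends assume detectability is stable over years.
* β1/β3 inference leans entirely on the random-effect hierarchy (above);
  with few routes their posteriors are wide and prior-sensitive.
* The covariate extrapolation is a straight line per location; it cannot
  capture abrupt land-cover change in the unobserved years.
* Single-species models only; community-level inference is out of scope.
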