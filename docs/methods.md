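# Methods

## Model

A season of count data consists of counts `y_ij` at sites `i = 1..S` on
occasions `j = 1..T` (by default week numbers `1..T`, shared across sites).
The expected count factorises as `λ_ij = N_i a_ij`: a relative site total
`N_i` spread over the season by a pattern `a_ij`.  Detection is assumed
constant, so the `N_i` are relative, not absolute, abundances.  Missing
visits contribute nothing to any likelihood sum.

### Seasonal-pattern families

**Normal mixture.**  `a_ij = Σ_b w_ib · N(t_j; μ_ib, σ_ib)` with `B ≥ 1`
broods.  The ordinates are raw densities — the curve integrates to one over
continuous time rather than summing to one over the occasions.  A
`normalise_mixture` flag rescales rows to sum to one when comparability
with the spline convention is wanted; it is off by default to preserve the
distinction between the two conventions.

**Stopover.**  A mechanistic alternative: a proportion `β_{i,d−1}` of
individuals emerges at visit `d`, and an individual present at one visit
remains to the next with constant survival probability `φ`.  Availability
is `a_ij = Σ_{d≤j} β_{i,d−1} φ^{j−d}` (evaluated by the O(T) recursion
`a_j = φ a_{j−1} + β_j`), and mean adult life span is `1/(1−φ)` inter-visit
intervals.  Emergence proportions are Normal-mixture masses between
consecutive visit times.  The season edges need a convention: by default
the first visit absorbs the lower Normal tail and the last visit the upper
tail, which makes `Σ_d β_{i,d−1} = 1` hold exactly without a division.  An
alternative (`beta_method="rescale"`) computes interval masses on
`[t_1 − Δ, t_T]` and divides by their total; the two agree whenever the
emergence distribution is well inside the season.  Survival is constant
over time and age; time- or covariate-dependent survival is out of scope.

**B-spline.**  `a_j = softmax(X c)_j` with `X` a clamped cubic B-spline
basis (`spline_df` functions, equally spaced interior knots) shared across
sites.  One coefficient is pinned to zero for identifiability; the softmax
guarantees positivity and sum-to-one.

### Count distributions

Poisson; negative binomial with mean `λ` and variance `λ(1 + λ/r)` (Poisson
as `r → ∞`); zero-inflated Poisson with `P(0) = ψ + (1−ψ)e^{−λ}`.  The NB
log-pmf is computed through `betaln` and `log1p` so the large-`r` limit is
numerically clean — with `r = 1e8` the NB log-likelihood of a Poisson fit
matches the Poisson value to ~1e-6, where the naive
`gammaln(y+r) − gammaln(r)` form loses four digits to cancellation.

## Link-scale parameterisation

The optimiser works on an unconstrained vector θ.  Constraints hold by
construction: `μ_1 = exp(η)` with log-increments for later broods (ordered
means), log links for `σ` and `r`, a multinomial-logistic transform with
the last brood as reference for the weights (simplex), and logistic links
for `φ` and `ψ`.  Each phenology parameter can carry a covariate linear
predictor; formulas are polynomial ("northing + northing^2", intercept
implicit) and may be shared across broods or given per brood.  Covariates
are centred and scaled to unit (population) standard deviation internally —
slope coefficients are per standard deviation of the covariate — and the
scaling is stored so predictions can be requested at original-scale values.
`r` and `ψ` are intercept-only.

## Estimation

For Poisson counts the conditional maximiser of each `N_i` given the curve
is the scaled site total `N̂_i = Σ_j y_ij / Σ_j a_ij` (observed occasions
only), so the concentrated likelihood is maximised over θ alone with
L-BFGS-B and finite-difference gradients.  Degenerate θ (no curve mass on
occasions with counts, non-finite values) score −∞, which the optimiser
wrapper converts to a large finite penalty.  An all-zero site gets
`N̂_i = 0` and contributes nothing to the Poisson likelihood.

NB and ZIP fits have no closed-form concentration.  The curve parameters
are first fitted under the Poisson profile and the `N̂_i` initialised by
concentration; the scheme then alternates (i) maximising over the full θ
(including `r` or `ψ`) with the totals fixed and (ii) updating each `N̂_i`
by a bounded one-dimensional search on `log N` over
`[log 1e−6, log(10 Σy/Σa)]`, until the log-likelihood gain drops below
`tol` (1e-6) or 100 outer rounds.  The log-likelihood never decreases
across rounds, and on test problems the scheme reaches the same optimum as
a joint quasi-Newton run over `(θ, log N)`.

Starting values, unless supplied, put brood means at count-weighted
quantiles `(b − 0.5)/B` of the occasion axis, `σ = T/(4B)`, equal weights,
`φ = 0.5`, `r = 1`, `ψ = 0.1`.  Mixture likelihoods can be multimodal
(brood-labelling and merged-brood ridges); an optional seeded multi-start
(`n_starts`) perturbs the start and keeps the best optimum, ties broken by
the smaller ‖θ‖.  The variance matrix of θ̂ is the inverse
finite-difference Hessian of the objective at the optimum (profile
objective for Poisson; fixed-totals objective for NB/ZIP).  A
non-positive-definite Hessian is repaired to the nearest positive-definite
matrix by eigenvalue flooring and flagged in the diagnostics; a
non-converged fit is flagged and its variance matrix withheld.

AIC is `2n − 2ℓ` where `n` counts only the θ coefficients, never the
concentrated site totals — so the canonical model shapes carry
`n = 2` (Poisson, one brood), 4 (two broods, shared σ), 6 (three broods,
shared σ), 7 (ZIP or NB, three broods, shared σ), and 9 (NB, three broods,
per-brood σ).

## Bootstrap

Parametric: draws `θ* ~ MVN(θ̂, vcov)`.  Non-parametric: sites are resampled
with replacement (covariates travel with their site; occasions are never
resampled), each replicate refitted from θ̂ (a cold-start flag exists);
failed refits are dropped and counted, with more than 50 % failures an
error.  Intervals are percentile intervals at a configurable level (default
95 %) using order-statistic (`inverted_cdf`) quantiles, so intervals of
monotone transforms — `exp` of a log-mean, life span `1/(1−φ)` — are exactly
the transformed endpoints.  Natural-scale intervals push every draw through
the inverse links at requested covariate values.

## Synthetic surveys

The generator emulates one season of a weekly monitoring scheme: `S` sites,
`T` weekly occasions, constant or log-Normal site totals, curve-shaped
expected counts, Poisson/NB/ZIP noise, independent per-cell missingness,
and an optional uniform site covariate (northing in km) driving the
phenology through the same links the fitting code uses.  Per-site random
streams use stable spawn keys, so enlarging `S` never changes earlier
sites' draws.  Two stock scenarios:

* `make_bivoltine_gradient_scenario` — stopover, `B = 2`, baseline
  `μ = (10, 17)`, `σ = (1.6, 1.3)`, `w = (0.4, 0.6)`, `φ = 0.47`, site
  totals log-Normal with mean 200 and sd 100, 15 % missing visits, northing
  uniform on 0–1000 km with standardized-scale slopes 0.14 on the first
  emergence, −0.4 on the brood gap and (1.6, 0.3) on the first-brood
  weight: bivoltine in the south, effectively univoltine at the top of the
  gradient.
* `make_trivoltine_scenario` — mixture, `B = 3`, `μ = (7, 14, 21)`,
  clearly distinct spreads `σ = (1.2, 2.0, 3.0)`, `w = (0.25, 0.35, 0.40)`,
  NB noise with `r = 1`, constant totals 200: three overlapping broods with
  strong overdispersion, for brood-number/distribution selection studies.

What the generator does *not* emulate: spatio-temporally correlated noise,
observer or weather effects on detection, transect-length differences, and
between-year dynamics.  Passing recovery tests therefore show the estimator
is correct under its own assumptions, not that those assumptions hold for
any particular monitoring scheme.

## Verification studies and their sizes

The end-to-end suite (`tests/test_acceptance.py`) runs at `S = 50`,
`T = 26`, site totals 200 — one realistic season — with replicate counts
chosen to keep the whole suite at a few minutes on one CPU: 100 recovery
replicates for the one-brood Poisson scenario, 60 for the two-brood
stopover, 40 for the three-brood NB; 20 model-selection replicates over the
six standard shapes; 100 outer replicates with 200 inner refits for
non-parametric coverage; `R = 2000` for the parametric-bootstrap SE check.
Closed-form curve kernels are checked against brute-force evaluation to
1e-12 and the Poisson profile against per-site numeric joint maximisation
to 1e-8.

## Known limitations

* Dispersion estimates are biased upward by roughly a factor `T/(T−k)`
  (≈ +6 % at `T = 26`): profiling out `S` site totals absorbs part of the
  between-occasion variance, the usual incidental-parameter effect of
  profile ML.  The bias halves when `T` doubles; phenology parameters are
  unaffected.  Interval estimates for `r` should come from the bootstrap
  rather than the asymptotic variance alone.
* Percentile intervals are first-order accurate; with few sites their
  coverage runs one or two points below nominal.
* Survival `φ` is constant; detection is constant; single-season fits only
  (no trend estimation across years).
* The mixture/stopover likelihood surface can be multimodal when broods
  overlap heavily; the auto-start is robust in the tested scenarios, but
  heavily merged broods may need `n_starts > 1`.
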