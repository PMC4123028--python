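# Methods

## The models

Daily admission counts are modelled as Poisson with a log link.  Three
nested specifications are fitted, all restricted to warm-season days
(October–March) and all using the previous day's maximum dry-bulb
temperature (`tmax1`, °C) as a linear exposure:

1. **Citywide (model 1).** `log μ_j = α + log E + time_j + γ·tmax1_j`,
   where `E` is the total population (offset with coefficient fixed at 1)
   and `time_j = hols_j + dow_j + doy_j`.
2. **Area random slopes (model 2).** Counts per day × area with
   `log μ_jk = α + log E_k + time_j + γ_k·tmax1_j + π_k + smooth.area_k`.
   The slopes are exchangeable, `γ_k ~ N(μ_γ, σ_γ²)`; `π_k ~ N(0, σ_π²)`
   absorbs persistently high/low admission rates; `smooth.area_k` is a
   2-df natural cubic spline in each centroid direction (east–west and
   north–south), columns centred, capturing smooth large-scale spatial
   variation in rates.
3. **Cross-level modifier (model 3).** As model 2 with
   `γ_k = γ* + Σ_m λ_m x_mk + u_k`, `u_k ~ N(0, σ_γ²)`.  Covariates are
   mean-centred and SD-scaled internally and λ is reported per original
   covariate unit, so `γ*` is the slope at the citywide covariate mean,
   i.e. the average slope.  The residual term `u_k` is retained by default
   (dropping it, `residual_slope=False`, is available but understates
   uncertainty); a deterministic-slope variant is therefore a config
   choice, not the default.

Slopes are reported as percent change per 10 °C, `100·(exp(10γ) − 1)`,
summarized by the posterior median and central 95 % interval.  An area (or
modifier) is "significant" when the interval excludes zero.  No
multiplicity adjustment is applied across areas.

### Temporal adjustment

* Day of week: 6 indicators, Monday reference.
* Holidays: 4 categories (`standard`, `christmas`, `jan2`, `other`),
  reference `none`.  The categories exist because holiday effects are
  heterogeneous: most public holidays depress admissions ~15 %, Christmas
  Day ~25 %, while 2 January shows elevated admissions (deferred care after
  the holiday block).
* Day of year: per warm season, a natural cubic spline in the within-season
  day index (days since the season's first retained day, so the basis is
  continuous across 31 Dec → 1 Jan) with 5 interior knots at equally spaced
  quantiles, 4 for the truncated first and last seasons; boundary knots at
  each season's first/last day.  Seasons occupy disjoint column blocks.
  Because a no-intercept spline block cannot express between-season level
  shifts, season indicator columns (reference = first season) are added;
  together the blocks absorb seasonality *and* long-term trend.  The spline
  family and knot placement are config options; the basis is the
  truncated-power natural-spline construction, rescaled to [0, 1] within
  each season for conditioning.

### Exposure handling

Two stations are merged by averaging days where both report and taking the
single value where one is missing.  The exposure series is the merged
`tmax` shifted by the lag (default 1 day); rows whose lagged value is
missing are dropped from the likelihood rather than imputed (missingness in
station records of this kind is far below 1 %, so imputation is
immaterial).  Temperature is centred at its warm-season mean before
sampling — this improves the sampler geometry and is undone exactly on
output, leaving the slope unchanged.

## Priors and sampling

Location parameters get independent N(0, 1000) priors (variance 1000,
configurable).  Variance components get Gamma(1, 1) priors **on the
variance** (an Exponential(1) on σ²).  The alternative convention —
Gamma(1, 1) on the precision — is implemented as an option but is not the
default: per-°C slope deviations have SD of order 0.01–0.04, i.e.
precisions of order 10³, and a Gamma(1, 1) prior on the precision places
essentially no mass above ~10, which would pin σ_γ near 0.3/°C and disable
shrinkage entirely.  The on-variance prior supports arbitrarily small
variances and only discourages σ² larger than a few, which is vacuous at
these scales.

No probabilistic-programming backend is assumed.  The sampler is written
for this model family:

* **Location block** (all fixed effects, γ_k, π_k, mean-level parameters):
  static Hamiltonian Monte Carlo, 8 leapfrog steps by default, step size
  tuned by dual averaging to a 0.8 acceptance target during burn-in.  The
  mass matrix is the negative Hessian of the log posterior at its mode
  (found by damped Newton), refreshed twice during burn-in; the conditional
  posterior given the precisions is log-concave, where this kernel mixes
  rapidly.
* **Precisions τ_γ, τ_π**: Gibbs.  Under the on-precision prior the
  conditional is conjugate Gamma.  Under the default on-variance prior the
  conditional is inverse-gamma times `exp(−σ²)`; an inverse-gamma
  independence proposal makes the Metropolis correction `exp(−(σ²′ − σ²))`,
  which is ≈ 1 whenever the variance is small, so the update is effectively
  exact draws.
* Defaults follow the study design: burn-in and sample size 5,000 per chain
  for model 1, 2,000 for models 2–3; 4 chains (diagnostics need more than
  one) with the per-chain totals kept at those values.  Chains are seeded
  from a single seed sequence; repeated fits with the same data and
  settings are bit-identical.  Split-chain R-hat is computed per parameter
  and a `ConvergenceWarning` is raised when the slope parameter's R-hat
  exceeds 1.05.

One consequence of the sampler design worth recording: exact bitwise label
equivariance under area relabelling is unattainable for any joint kernel
with a shared RNG stream (the Cholesky factor of a permuted mass matrix is
not the permuted Cholesky factor), so equivariance holds in distribution
and is tested with Monte-Carlo tolerance.

## Reported quantities

* `percent_change`: per-draw `100·(exp(γΔt) − 1)`, Δt = 10 °C; posterior
  median (robust on the exponentiated scale; the mean is available) and
  2.5/97.5 percentiles.
* `extra_admissions`: mean daily rate × percent change / 100.
* `slope_table`: one row per area with percent change, interval and
  significance class; laid out positives descending, then nulls, then
  negatives ascending; significance counts are recomputed from the
  intervals.
* `modifier_table`: the effect of a covariate on the slope is reported as
  the percent change in the slope per stated reporting unit, computed per
  draw as `100·λ·Δx / γ*`.  This ratio is the natural reading of "percent
  change in the temperature–admissions slope"; its posterior can be
  heavy-tailed when γ* has mass near zero, which is visible as wide
  intervals in weakly identified fits.
* `morans_i`: `I = (n/S0)·Σ w_ij z_i z_j / Σ z_i²` over centred values;
  two-sided permutation p-value `(r+1)/(n_perm+1)` counting permutations at
  least as far from the null expectation −1/(n−1) as observed; 999
  permutations by default.  Weights are row-standardized k-nearest-
  neighbour graphs (k = 5) on centroids by default, or queen contiguity
  when polygons are supplied; the statistic is defined for n ≥ 2 (the
  permutation test is only meaningful for n ≥ 3) and undefined for
  constant values.

## The synthetic-data generator

The generator emulates the study conditions: 158 areas with log-normal
populations (median 6,000; citywide ≈ 1 M), correlated area covariates via
a Gaussian copula with marginals calibrated to the published area medians
(population density gamma with median ≈ 1,670/km²; percent high earners
beta with median ≈ 5.95 %), centroids on a unit square, subtropical
temperature seasonality (annual mean 20.8 °C, amplitude 5.5 °C peaking late
January; AR(1) day-to-day noise, φ = 0.6, marginal SD 4.3 °C calibrated so
5-year extremes land near the observed 2.5–39.9 °C), a fixed-date holiday
calendar with multiplicative effects 0.85 (standard), 0.75 (Christmas),
1.15 (2 January), 0.95 (quasi-holidays), a weekend dip in admissions (Sat
0.85, Sun 0.80), and a mid-winter-peaking sinusoidal day-of-year signal
(log amplitude 0.08) — a low-order sinusoid precisely so that recovery
tests are not circular with the fitting module's spline basis.  Area slope
heterogeneity defaults to σ_γ = 0.018/°C, spreading per-area percent
changes per 10 °C over roughly −25 % to +55 % around the mean, matching the
spread of published area tables; σ_π = 0.25 gives ±1.6-fold area rate
variation.  In model-3 simulations the modifier covariate is mean-centred
before λ applies, so γ* retains the meaning "average slope".

What it deliberately does **not** emulate: real geographic boundaries
(contiguity on synthetic data uses k-NN centroid graphs), spatially varying
exposure (one temperature series serves the whole city), overdispersion
beyond Poisson, pollution co-exposure, and heat-wave-specific dynamics.
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the assumed generative model, not robustness to
misspecification in real admissions data.

### Aggregation of heterogeneous slopes

Fitting model 1 to the citywide aggregate of a panel with heterogeneous
γ_k yields a slope larger than the mean slope: with a log link the
citywide rate is `Σ c_k exp(γ_k t)`, whose log-derivative is a
rate-weighted mean of γ_k in which hot days up-weight heat-sensitive
areas — approximately γ* + σ_γ²·t̄ for small heterogeneity.  At the default
σ_γ and Brisbane-like summer temperatures this inflates the citywide
estimate visibly (≈ 15 % vs 7.2 % at full scale).  Citywide recovery of
the headline effect is therefore checked against data generated from the
model-1 process itself (σ_γ = σ_π = 0), which is also what model 1 assumes.

## Problem sizes and numerical choices

* Headline recovery: 5 calendar years → ~910 warm-season days; default
  model-1 MCMC; runs in well under a minute on one core.
* Interval-calibration studies (model 3, λ = 0 null coverage and
  strong-λ sign power): 20 replicates each at 20 areas × 2 full warm
  seasons with shortened chains (2 × 500 draws after 500 burn-in,
  6 leapfrog steps) — sizes chosen so the whole calibration suite runs in
  a few minutes while leaving the binomial checks well powered.  The
  "strong" modifier effect is +150 % slope per 1,000 residents/km²,
  deliberately above the weakly identified regime at that size.
* Analysis drivers run models 2–3 at 30 areas × 2 seasons; the
  modifier driver simulates the published-strength density effect
  (+55.4 %/1,000 km⁻²) and reports it as weakly identified at that size —
  the full 158-area × 5-season design is what narrows it.
* Degenerate inputs raise errors rather than warnings: zero-variance
  exposure, constant or collinear modifier covariates, areas missing from
  the attribute table, non-integer or negative counts, constant values in
  Moran's I, seasons shorter than the knot count.
* Ties/edge rules: quantile knots must be distinct (duplicate knots raise);
  the first date of a weather series has no lag-1 exposure and its panel
  day is dropped; a warm season spanning the year boundary carries one
  season label ("2007-2008").

## Known limitations

* Poisson only; no overdispersion or zero-inflation extensions.
* The spatial smoother is directional splines, not a CAR/ICAR field; the
  spatial weights for Moran's I are a reporting choice, not part of the
  likelihood.
* The permutation p-value for Moran's I is two-sided by construction;
  one-sided conventions will differ near the null.
* The sampler is tuned for log-concave conditionals; severely separated
  posteriors (e.g. near-deterministic variance components at very small K)
  mix more slowly and may warrant longer chains than the defaults.
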