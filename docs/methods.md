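# Methods

## The model

Daily gobbling activity is modelled as a count-valued state-space
process. For each site k and year i, a latent log-abundance of gobbles
logN evolves through a daily growth rate r_t:

    r_expected(t) = rho·logN[t−1] + Site(k) + Σ_j β_j·x_j(t)
                    + Year(i) + log(Units(t))
    r_t ~ Normal(r_expected(t), σ²_process)
    logN[t] = logN[t−1] + r_t,      y_t ~ Poisson(exp(logN[t]))

The five weather covariates are mean temperature (°C), mean wind speed
(kph) and mean relative humidity (%) over the sunrise window (30 min
before to 150 min after sunrise), the day-over-day change in
window-mean barometric pressure (mb), and a binary rain indicator for
the same window. The continuous covariates are standardized (mean 0,
sample SD 1) over the pooled all-site, all-year fitting frame; the rain
indicator is left as 0/1 so β_precipitation reads as a rain-vs-no-rain
contrast, with exp(β_precipitation) the exact multiplicative effect of a
rainy morning on that day's expected gobbles. Pressure is differenced
*before* standardization, so the scaled covariate is the standardized
day-over-day change. Units, the number of ARUs recording that day,
enters as a log-offset with fixed unit coefficient (effort exposure).

Observation-model convention: the observed count y is a raw non-negative
integer and its Poisson mean is N_t = exp(logN_t). This is the standard
exponential-family state-space construction for counts; a Poisson rate
on the log scale would not define a valid probability model (it can be
negative), and it is the exp-scale convention that yields the
exp(β) rain contrast the effect curves report.

The leading term rho·logN[t−1] is a Gompertz-style density-dependence
coefficient. It is estimated by default (Normal(0, precision 0.001)
prior, like every other coefficient) and can be fixed by configuration;
rho = 0 reduces the process to a covariate-driven random walk. Site
enters as five free intercepts with no global intercept; year effects
are exchangeable Normal(0, σ²_year). Identifiability of rho against the
site intercepts is monitored through the convergence diagnostics; in
practice the offset variation across site-years separates them cleanly.

### Priors

- Coefficients (sites, weather β's, rho): Normal(mean 0, precision 0.001).
- Process precision 1/σ²_process and year-effect precision 1/σ²_year:
  Gamma(shape 0.001, rate 0.001).
- Initial state of each site-year (and of any segment re-started after a
  covariate gap): Normal centred at log(first non-zero observed count
  + 1) with SD 10 — vague, data-located.

## Sampler

Metropolis-within-Gibbs, exploiting every closed-form conditional:

1. **Latent states.** Given everything else, each logN[t] depends only on
   its two neighbours, its observation and the process terms. States are
   updated by random-walk Metropolis on an even/odd checkerboard, so each
   half of all states across all site-years updates in one vectorized
   step. Per-state step sizes adapt toward 44% acceptance by a
   Robbins-Monro rule during burn-in and are frozen afterwards, so the
   recorded draws target the exact posterior.
2. **Coefficient block.** Conditional on the latent states the process
   model is a linear-Gaussian regression of the realized growth rates on
   site dummies, the five covariates, year dummies and lagged logN, so
   the full coefficient vector (including rho) is drawn exactly from its
   conjugate multivariate-normal conditional. This exact joint draw is
   why the sampler mixes in hundreds rather than tens of thousands of
   iterations.
3. **Precisions.** Conjugate Gamma draws for the process and year-effect
   precisions.

Chains are initialized overdispersed: coefficients start at jitter drawn
from the prior scaled by 0.1 (chain-dependent magnitude), latent states
at log(max(count, 1)). Three chains, 2,500 burn-in, 10,000 iterations
thinned by 10 are the defaults; run lengths are configuration-exposed
and simulation studies use shorter, verified-converged runs (below).
One master seed spawns per-chain substreams; identical seeds give
bit-identical draws. Proposals that would push |logN| beyond 40 are
rejected outright to keep exp() finite; this bound is never approached
by real posteriors (it corresponds to e^40 gobbles per day).

Missing observation days contribute only process terms (no imputation);
a day with missing covariates breaks the transition chain and the next
day re-starts a segment with the vague initial-state prior.

## Convergence and summaries

The Gelman-Rubin statistic is the classic potential scale reduction
factor sqrt(((n−1)/n·W + B/n)/W) computed across chains, with a
split-chain option; values below 1.1 are taken as converged. Constant
chains are flagged degenerate (NaN) rather than reported as 1. Posterior
tables report mean, SD and the empirical 2.5%/97.5% quantiles using the
median-unbiased quantile rule (configurable). Trajectory displays emit
both the posterior band of the expected count exp(logN) and the wider
posterior-predictive band of counts, labelled distinctly; the predictive
band is the one whose ~95% coverage of observed days is checked.
Effect curves take the baseline expected-gobble count as an explicit
argument (default 20) rather than hard-coding one.

## Synthetic data

The generator emulates a southeastern-US spring season so the full
pipeline (15-min records → covariates → counts → fit) can be exercised
with known truth:

- **Temperature**: daily means climb linearly 10→24 °C over the season
  with AR(1) day-to-day noise (SD 3 °C, lag-1 0.7) plus a diurnal cosine
  (amplitude 5 °C, coolest near dawn) and 0.3 °C quarter-hour jitter.
- **Humidity / wind**: day-level AR(1) around 75% (SD 10) and 8 kph
  (SD 4), clipped to [0, 100] and ≥ 0.
- **Pressure**: a per-quarter-hour random walk (step SD 0.15 mb)
  reflected at 980–1040 mb so it cannot drift to impossible values.
- **Rain**: a two-state dry/wet Markov chain parameterized by its
  marginal wet probability (0.25) and day-to-day persistence (0.4), so
  rain arrives in multi-day spells; wet days carry strictly positive
  precipitation in every quarter-hour.
- **Sunrise**: a smooth seasonal ramp from ~06:50 (1 March) to ~05:25
  (late May) with a per-site offset; externally supplied sunrise tables
  are accepted everywhere instead.
- **Counts**: forward simulation of the exact process/observation
  equations at configurable truth, starting at the deterministic
  equilibrium when rho < 0. Latent trajectories are retained losslessly
  for recovery tests.

What the generator does *not* emulate: false positives of an automated
detector, detection loss during rain or wind (counts are generated from
the model, so weather affects the truth only through the β's), spatial
correlation between sites sharing a storm system, and ARU outages. A
passing recovery study therefore demonstrates correctness of the
covariate construction, likelihood and sampler — not robustness to the
observation artifacts of real acoustic surveys.

## Recovery study (the validation surface)

Twenty replicate datasets of 5 sites × 3 years × 90 days are simulated
at truth β = (−0.21, −0.16, +0.28, +0.09, −0.56) for temperature, wind,
pressure change, humidity and rain, site intercepts (0.20, 0.11, 0.10,
−0.01, −0.07), small year effects, σ_process = 0.15, rho = −0.5, and
constant per-site-year effort drawn uniformly from 10–20 units. Each
replicate is refit with 3 chains × (600 burn-in + 1,800 iterations,
thin 3) — sizes chosen because the conjugate coefficient block mixes
essentially immediately (R-hat < 1.01 in practice, far below the 1.1
criterion). Reported: per-coefficient 95% credible-interval coverage
(target ≥ 90%), aggregate posterior means, the recovered sign pattern,
and the worst R-hat across all fits.

Why rho = −0.5 in the truth: with rho = 0 the positive site intercepts
plus the log-effort offset (log 10 ≈ 2.3 per day) would drift the latent
walk by hundreds of log units over a season; a mean-reverting rho gives
stationary trajectories whose equilibrium abundance (~100–600 gobbles
per site-day at 10–20 units) matches realistic season totals. At these
study conditions the posterior SE of each weather coefficient is ~0.005
(≈1,350 informative transitions), so the near-null humidity effect is
recovered as the smallest-magnitude coefficient rather than as an
interval straddling zero — the latter only occurs at the much larger
process noise of field data.

## Numerical conventions and edge cases

- Windows are half-open [sunrise−30 min, sunrise+150 min), so every
  15-minute record belongs to exactly one day.
- A morning with fewer than 9 of the 12 aligned records (configurable)
  is flagged missing, never averaged or imputed; pressure differences
  never span a missing or absent day.
- Standardization uses the sample SD (n−1); constant covariates raise
  rather than silently producing zeros. Scaling constants are computed
  on the fitting frame and stored so new data transform identically.
- The collinearity screen uses |r| > 0.60 — perfectly anti-correlated
  covariates are exactly as redundant as perfectly correlated ones — and
  drops the member of a flagged pair with the larger mean absolute
  correlation against all covariates (ties: later declaration order
  drops), iterating until no pair exceeds the threshold. The full
  correlation matrix is always reported; pairs with fewer than 3
  complete observations are flagged unavailable.
- Season-summary display: percent columns round to whole percent;
  integer site-level mean ± SD display columns truncate toward zero
  (exact floats are always carried alongside). Sample SDs use n−1;
  percent differences are taken against the best site's mean.
- y = 0 is an ordinary Poisson observation; the latent state keeps it
  finite.

## Known limitations

- The sampler is exact but single-threaded; very long seasons (tens of
  thousands of site-days) would benefit from a compiled latent-state
  update.
- Detection error is not modelled: counts are treated as verified truth,
  and no false-negative correction is attempted.
- Weather is assumed measured at the site; using a station tens of km
  away attenuates coefficients toward zero in ways the recovery study
  does not quantify.
- One weather regime per fit: covariate effects are pooled across sites
  and years (no interactions), as in the model definition.
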