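# Methods

## The design

`itsim` implements a simulation-based interrupted time-series (ITS)
analysis for daily event counts around an annually recurring intervention
day — the motivating case being Alaska's Permanent Fund Dividend (PFD), a
statewide cash payment disbursed to nearly all residents on a single fall
day, and the question of whether traumatic-injury or mortality rates rise
in the days after disbursement. The logic is counterfactual extrapolation:
a model fit to the days *before* each year's distribution day predicts
what the days after it would have looked like absent the payment, and the
observed rates are compared with the predictive distribution.

## The pretreatment model

For each study year, the W days (default 30) strictly before the
distribution day t₀ contribute rows to a pooled negative-binomial
regression with a log link:

    log E[Y_t | X] = β₀ + β₁ t + Σ_{d=1..D} β_d r_{t−d} + ω(dow_t) + α(year_t) + log P_year

where Y_t is the day's count, r_{t−d} the observed daily rate per 10 000
residents d days earlier, ω six day-of-week contrasts (Sunday reference),
α year fixed effects (earliest year reference), t the within-window day
index (1..W, centered; the same construction every year, with year effects
absorbing cross-year level differences), and log P_year the annual
population offset that makes the model one of rates while fitting counts.
Counts are NB2: Var[Y] = μ + μ²/θ with dispersion θ.

Choices worth stating explicitly:

* **Lagged regressors are rates, not counts.** Rates are scale-stable
  across years with different populations. `AnalysisConfig.lag_covariate`
  exposes the count alternative.
* **Lag initialisation.** Lag columns reach back to observed days
  immediately before the window (`lag_init="extend"`), so no rows are lost;
  `"drop"` discards the first D rows per window instead.
* **Estimation.** Joint MLE of (β, θ) via `statsmodels`' NB2 likelihood
  (quasi-Newton, analytic gradients, Poisson warm start), with a
  profiled-dispersion GLM fallback on non-convergence. Estimated
  overdispersion below ~1e-7 is clamped to an effectively-Poisson θ = 1e7.
  The coefficient covariance used downstream is the β block of the inverse
  observed information; θ is treated as fixed at θ̂.
* **Lag-order selection.** Forward stepwise from the no-lag model, adding
  contiguous lags while AIC improves. The no-lag model is in the candidate
  set, so on serially independent data a lag is added only at AIC's known
  ~16% overfitting rate. Ljung-Box statistics of the selected model's
  Pearson residuals (default 7 lags, df discounted for fitted AR terms)
  are reported as the specification diagnostic.

## Counterfactual simulation and intervals

Uncertainty propagates through a parametric bootstrap: `n_sims` (default
1000) coefficient vectors β* are drawn from MVN(β̂, V̂) via a symmetric
eigenfactorization; for each draw and each year, expected means
μ*_j = exp(x_j′β* + log P) are built for days j = 0..H (default H = 7)
after the distribution day, and counts are sampled from NB2(μ*, θ̂) via the
gamma–Poisson mixture. Day 0's lagged-rate covariates come from observed
pretreatment days; later days use each draw's own simulated rates
(`lag_fill="recursive"`), because a counterfactual trajectory must not
condition on treated outcomes. The leaky alternative (`"observed"`) exists
for diagnostics only.

Per-day effects are differences d_{s,j} = observed_j − simulated_{s,j} in
rates per 10 000. The point estimate is the mean over draws; the 95%
credible interval is the empirical 2.5%/97.5% quantile pair (type-7 linear
interpolation — recorded in run metadata since the rule affects endpoints
at n_sims = 1000); a day is significant when the interval excludes zero.
No multiplicity adjustment is applied across days. Years are pooled
draw-wise — differences sharing a draw index are averaged across years
before quantiles — so the pooled interval retains the dependence induced
by the shared coefficient draw; pooling all year-draw pairs instead is a
config option. The implied statewide count difference is
mean_diff × P̄/10 000 with P̄ the mean study-period population.

Numerical guards: simulated means are capped at 1e9. A coefficient draw
far in the MVN tail can make the rate feedback supercritical, exploding
within the horizon; the cap keeps sampling finite. Such draws are ~1e-5 of
all draws and the quantile intervals are insensitive to them, but the
draw-mean effect on an affected replicate-day can be distorted — a known
limitation of dynamic log-linear count simulation.

Randomness: one root seed per run; coefficient draws and each year's
trajectory stream use `SeedSequence` children of it (distinct spawn keys),
so results are reproducible and independent of execution order.

## Sensitivity suite

* **Anticipatory shifts** (1..14 days): the whole pipeline re-run with the
  treatment day moved earlier; shift 0 reproduces the baseline bit-for-bit.
* **Window sweep** (15..80 days): windows too short to fit are marked
  failed without aborting the sweep.
* **Extended model**: pretreatment rows per year run from 30 days after
  the previous year's distribution day to the day before the current one
  (the first study year, lacking a predecessor, starts at the earliest
  date the lag columns allow); the within-window trend is replaced by a
  natural cubic spline in calendar time (patsy `cr`; the raw basis is a
  partition of unity, so one extra column is requested and the first
  dropped to stay full-rank beside the intercept; `spline_df` counts the
  retained columns) plus annual Fourier pairs sin/cos(2πkt/365.25).
  Defaults spline_df = 4, n_harmonics = 2; both open. `spline_df = 1` is
  special-cased as a plain linear calendar trend so the extended fit can
  be checked against the base model on identical rows; `spline_df = 2` is
  rejected. The spline extrapolates linearly beyond its boundary knots, so
  downstream simulation is unchanged.
* **Holiday power validation**: dates with known injury spikes (New
  Year's Day, July 4th) replace the distribution day as t₀, reusing the
  standard 30-day window, in every year of the span that accommodates
  window and horizon.
* The 30-day post-distribution horizon is a config change (H = 30), not
  separate code.

## The synthetic generator

The study's registry and vital-records data are restricted, so validation
runs on synthetic series whose generating process matches the fitted model
exactly under the null: NB2 counts with day-of-week effects, a slow linear
trend, year-level shifts, AR feedback through lagged daily rates inside
the log link, an annual population offset, and optional multiplicative
pulses. A 60-day burn-in initialised at the stationary mean rate is
discarded; a fixed-point diagnostic rejects AR configurations without a
finite stationary mean. An `ar_scale="log_rate"` toggle deliberately
misspecifies the feedback scale for robustness experiments, and optional
annual-sinusoid fields support seasonal-recovery checks of the extended
model.

Presets anchor to the study's printed scale: ~9.1 injuries/day (36 556
over 2009-2019, weekend excess, θ = 10) and ~10.7 deaths/day (43 170,
flat week, θ = 12), 11 study years, populations ramping 700k→735k, a
first-Thursday-of-October distribution day, +2%/year secular trend, year
shifts spanning ±0.04, and one lag-rate feedback term with coefficient 1.0
per unit rate. That coefficient implies a day-to-day count autocorrelation
of roughly 0.1–0.15 at mortality scale; materially smaller values are
statistically invisible at these sample sizes (the likelihood-ratio
noncentrality for the lag term over 330 pretreatment rows is ≈7.6 at
coefficient 1.0 but below 0.1 at coefficient 0.1), which would make any
selection or recovery study vacuous. The intercept is solved so the
stationary mean hits the daily-mean anchor despite the AR feedback and
averaged day-of-week/year multipliers; realised totals land within ~2%.

What the generator does *not* emulate: record-level structure and
demographics, spatial heterogeneity, genuine holiday/seasonal spikes
(unless planted), reporting artifacts, and secular breaks. Passing
calibration here shows the pipeline is correct *when its model family is
right*, not that the family fits any particular registry.

## Validation results computed by the test suite

* **Null calibration** (200 replicates, mortality scale, 1000
  trajectories): the pooled 95% interval contains the held-out observed
  rate for ~94% of (replicate, day) pairs over days 0-7 — about a point
  below nominal, the expected cost of plug-in V̂ and fixed θ̂.
  `scripts/acceptance.py` recomputes this from scratch.
* **Parameter recovery** (500 replicates): every coefficient's Monte-Carlo
  bias is below half its sampling SD and Wald coverage sits in [92%, 98%].
  The recovery harness uses 270-day windows — the longest the preset
  calendar permits — because the lag coefficient carries the classic
  short-panel (Nickell-type) attenuation of order (1+ρ)/T under year fixed
  effects: at T = 30 the attenuation is ≈28% of the coefficient (≈0.7 of
  its SD); at T = 270 it shrinks to ≈5% (≈0.4 SD). The same mechanism
  operates in any real analysis with short windows; it biases the *lag*
  coefficient, not the counterfactual calibration, which the null-coverage
  experiment checks directly at W = 30.
* **Lag-order selection** (200 replicates): the modal stepwise choice on
  AR(1)-generated data is D = 1.
* **Power** (60 replicates/multiplier, common random numbers): a planted
  ×2 treatment-day spike is detected in >80% of replicates; power is
  monotone in the multiplier.
* **Likelihood oracle**: the fit's log-likelihood matches an independent
  multi-start Nelder-Mead maximization of the hand-written NB2 likelihood
  to 1e-4 on a committed 20-row fixture, and the fit collapses onto the
  Poisson GLM when the generating dispersion vanishes.

Problem sizes (replicate counts, window lengths, draw counts) are the
package's chosen experiment scales; they keep the full validation loop
runnable in a few minutes on one CPU.

## Known limitations

* Wald intervals and the parametric bootstrap both lean on the inverse
  observed information; with ~20 parameters on 330 rows the intervals are
  mildly anticonservative (~1 point of coverage).
* The lag-coefficient attenuation above means fitted AR terms from short
  windows should be read as predictive devices, not structural estimates.
* Draw-mean effects can be distorted on the rare replicate containing a
  capped explosive draw; intervals are unaffected.
* The quantile rule matters at the margins: a different empirical-quantile
  convention shifts interval endpoints at n_sims = 1000 by O(1/n_sims).
* The Ljung-Box diagnostic is exact for raw i.i.d. residuals (its null
  rejection rate calibrates at 5% in the tests) but runs hot on *fitted*
  Pearson residuals at this design's size — ~20 parameters per 330 rows,
  with each year block's dummy demeaning 30 residuals, push null rejection
  toward ~15%. Read it descriptively, as a comparison across candidate lag
  orders, not as a strict 5% test.
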