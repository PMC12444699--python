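# Methods

This note documents the models, the synthetic-data generator, the
validation protocol, and the numerical and design choices behind
`asthmacast`.  It records what the package computes and why; every
empirical figure quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## The forecasting problem

The target is a daily count y_t of asthma hospital admissions.  The
emulated series (2016–2023, 2,922 days) averages ~1.91 admissions/day
with ~21% zero days and a heavy right tail: the top 5% of days reach 6 or
more admissions.  The operational questions are (i) how many admissions
to expect tomorrow, with a 95% interval, and (ii) whether tomorrow is a
*high-risk* day, defined as exceeding the 95th percentile of historical
daily totals.

## Synthetic admissions generator

Real hospital extracts are not shareable, so the generator module is a
first-class, tested component rather than a fixture.  It simulates

    log λ_t = β₀ + Fourier₅(day-of-year) + dow(t) + school(t)
              + pandemic(t) + u_t,
    u_t = ρ u_{t−1} + ε_t,          ε_t Gaussian,
    y_t | λ_t ~ NegBin(mean λ_t, size r).

* **Negative binomial, size r = 10.**  Overdispersion is forced by the
  data: a Poisson with mean 1.91 puts ~1.4% probability on counts ≥ 6,
  far short of the observed 5% tail.  Poisson is recovered as r → ∞.
* **Annual Fourier, order 5**, fitted by least squares to the log of the
  published monthly totals (after removing the school-term step).  The
  September peak, the June/July trough and the Tuesday/Wednesday weekday
  contrast are modestly sharpened relative to the printed totals so that
  the published *orderings* (September maximal; June and July lowest;
  Sunday–Tuesday each above Wednesday–Saturday) hold ordinally in a
  single eight-year realisation, not merely in expectation.
* **Day-of-week effects** are the log-ratios of the published
  day-of-week totals to their mean.
* **School term** is approximated as August 15 – May 31 (configurable);
  the seasonal peak is attributed to school onset but exact term dates
  are institution-specific.
* **Pandemic shift** log(0.48) over calendar 2020 encodes the published
  52% drop in admissions that year.
* **AR(1) log-intensity noise** (ρ = 0.55, stationary sd 0.15) creates
  day-to-day persistence so that one-step forecasting is non-trivial; the
  spec'd parameter list carries only ρ, and the scale `ar1_sigma` is this
  package's necessary addition.  Noise is on the log intensity, not the
  counts, so counts stay integer-valued and non-negative by construction.
* Leap days are generated like any other day.

Baseline β₀ = 0.52 and (r, σ_u) were calibrated once by simulation so the
generated 2016–2023 series matches the published marginals — mean daily
count within ±0.15 of 1.91, zero fraction within ±0.03 of 0.211,
P(count ≥ 6) within ±0.02 of 0.05 with threshold-6 behaviour (fraction ≥6
at most 5% while fraction ≥5 exceeds it), and a 40–60% 2020 drop — across
24 independent seeds, and were then frozen.

What the generator does *not* emulate: weather/pollution drivers, school
holidays within term, outbreak epidemics, spatial structure, or secular
drift beyond the single pandemic step.  Passing tests therefore show the
pipeline behaves correctly on a series with the right marginal and
calendar structure; they cannot certify accuracy on any particular real
hospital's data.

## Models

**ARIMA(p,d,q) with constant.**  The d-times differenced series (d ∈
{0,1}) is modelled as a stationary invertible ARMA around mean μ; the
constant c = μ(1 − Σφ) acts as drift under d = 1, which is what makes
long-range forecasts revert to the series' mean trend.  Estimation is
exact Gaussian MLE: the ARMA is put in Harvey companion state-space form,
the Kalman filter computes the prediction-error decomposition, and σ² is
concentrated out.  Stationarity/invertibility are enforced by optimizing
over partial-autocorrelation-transformed coefficients (tanh map plus
Durbin–Levinson), so the optimizer is unconstrained (L-BFGS-B with two
random restarts; fixed restart seed; warm starts reuse the previous
optimum).  The exact-MLE route (rather than conditional sum of squares)
was chosen because it is well-defined for MA terms on short windows and
matches the behaviour of the mainstream forecasting ecosystems; the test
suite verifies log-likelihood agreement with an independent reference
implementation to ~1e-4.  Standard errors come from the central-difference
Hessian in natural coordinates.  Model selection minimises BIC among
candidate orders, with a veto: candidates whose Ljung–Box residual
p-value (lags 10, fitdf = p+q) is ≤ 0.05 are excluded unless no candidate
passes, in which case the minimal-BIC spec is returned with a warning.
Ties break toward fewer parameters, then lexicographic (p, q).

**ETS, additive class.**  Error additive; trend none/additive/damped;
seasonality none/additive with period m.  The innovations recursions give
one-step errors e_t, and the Gaussian likelihood −(n/2)(log 2πσ̂² + 1)
with σ̂² = SSE/n is maximised over the smoothing parameters *and* the
initial states (initial seasonals constrained to sum to zero), inside the
usual admissibility box (0 < α < 1, β < α, γ < 1 − α, 0.8 < φ < 0.98).
AIC counts smoothing parameters, initial states and σ².  h-step interval
variance uses the additive-class closed form σ²(1 + Σ_{j<h} c_j²) with
c_j = α + βφ(1−φʲ)/(1−φ) + γ·1{j ≡ 0 mod m}.  The seasonal period
defaults to m = 7 (weekly): a 365-day additive seasonal ETS is
computationally degenerate (365 initial states) and is out of scope; the
yearly cycle is instead captured by the Prophet-style model's Fourier
terms.

**Prophet-style decomposition.**  y(t) = g(t) + s(t) + ε_t with h(t) = 0
(hospitals operate through holidays).  g(t) is continuous piecewise
linear: S = 25 changepoints equally spaced over the first 80% of history
(defaults; both configurable), each with rate change δⱼ carrying a
Laplace(0, τ) prior, τ = 0.05 by default.  The MAP estimate is least
squares with an L1 penalty λ = 1/τ on the δ's only; it is solved exactly
by projecting out the unpenalised columns (intercept, base slope, Fourier
terms with periods 7 and 365.25) and running a coordinate-descent Lasso on
the residualised changepoint basis.  Forecast uncertainty is Monte-Carlo:
future changepoints arrive at the historical rate S/T per day with slope
changes drawn from a Laplace whose scale is the mean absolute fitted δ,
plus Gaussian observation noise; interval limits are the 2.5%/97.5%
sample quantiles over 500 seeded draws.  This simulation scheme is this
package's reimplementation choice for interval construction — the source
protocol does not describe one — and is documented as such, not as a
claim about any other implementation's internals.  On training windows
shorter than two full years the yearly Fourier block is dropped
automatically (it is unidentifiable).

**Ensemble.**  For each date, the point forecast is the arithmetic mean
of the member points, and the 95% limits are the means of the member
limits — so the ensemble interval width is exactly the mean member width.

**Intervals and count data.**  All intervals are Gaussian (±1.96·sd) or
Monte-Carlo quantiles on a continuous scale; the lower limit may fall
below zero on count data.  Intervals are *not* truncated at zero when
computing coverage, so the coverage metric reflects the models as fitted;
truncation would only be cosmetic.

## Validation protocol

Rolling-origin, one-step-ahead, daily refits.  Model structure (ARIMA
orders, ETS form) is selected once on the initial training window; for
each validation day d, parameters are re-estimated (warm-started) on a
window ending at d−1 and a forecast for d is recorded.  No future
observation can enter a fit by construction, and a mutation test verifies
it: perturbing any observation never changes forecasts for that date or
earlier.

The source protocol is internally ambiguous about the update window: it
sweeps 1–7-year initial training windows yet describes daily updates "on
the most recent 365-day window".  The policy is therefore explicit:
`sliding` (default) re-estimates on a window of the initial training
length; `sliding-365` implements the literal 365-day rule; `expanding`
grows from the initial origin.  Re-*selection* of model structure is not
repeated daily — only re-estimation — both for tractability and because
a deployed system would pin one spec per class.  Non-convergent daily
refits fall back to the previous day's parameters with a logged warning
and a configurable abort threshold.

Era configurations mirror the study design: pre-pandemic (train
2016–2018, validate 2019), pandemic era (train 2020–2022, validate 2023),
and a two-year validation (train 2016–2021, validate 2022–2023).

## High-risk calibration

The observed threshold is the smallest integer t such that at most 5% of
history days had ≥ t admissions — defined on the integer counts directly
(no interpolated quantile) so that "6 or more admissions" is reproduced
exactly on the emulated series.  Predictions are continuous, so each
model's threshold is the linear-interpolation 95th-percentile quantile of
its predictions, with strictly-greater flagging.  Which predictions feed
the calibration is ambiguous in the source; the default here uses rolling
one-step-ahead predictions over the training history, so calibration
consumes no validation information (deployment realism); calibrating on
validation-period predictions is available as an option.

## Evaluation

* **MAPE** = median of absolute percentage errors, in percent.  On zero
  count days the percentage error is undefined — and about a fifth of
  days are zero — which is the single largest unstated analytic choice in
  this pipeline.  Default policy: exclude zero-actual days and report the
  exclusion count; a `denominator-max-1` policy is selectable.
* **Coverage** = percent of days whose 95% interval contains the actual,
  endpoints inclusive.
* **ROC/AUC**: scores are the continuous point forecasts, labels are
  observed count ≥ observed threshold.  AUC is the Mann–Whitney
  probability with half credit for ties (verified exactly against an
  exhaustive pair-enumeration oracle), with a DeLong 95% CI.
* **Operating point**: Youden's J = sens + spec − 1, ties broken toward
  higher sensitivity then lower threshold.  PPV/NPV/sens/spec are
  reported at the Youden cut and additionally at the 5%-calibrated
  threshold, since the source is not fully determinate about which cut
  its predictive values use.

## Diagnostics

KPSS (null: level-stationarity; trend variant by flag) with
Bartlett-kernel long-run variance, automatic truncation
⌊4(n/100)^0.25⌋, and table-interpolated p-values reported as bounds
(">0.1", "<0.01") outside the tabulated range.  Sample ACF (biased
normalisation) and PACF via Durbin–Levinson, with z_{0.975}/√n white-noise
bands.  Ljung–Box Q with χ²(lags − fitdf) reference; default lags 10 with
fitdf = number of estimated ARMA coefficients.  All statistics are
cross-checked against an independent reference implementation to 1e-6 in
the tests.

## Problem sizes and numerical choices

The test suite and acceptance script choose simulation sizes that make
each check statistically meaningful while keeping a full run in the
minutes range on one CPU: 10,000 days for marginal mean checks, n = 3,000
for parameter recovery (tolerances set at three times the estimated or
empirically measured sampling sd), 2,000 forecast days for interval
coverage (binomial sd ≈ 0.5 points, against a 93–97% acceptance band),
five generator seeds for every calibration property of the reference
configuration, and full-year (365-day) validation windows for the
ensemble-accuracy comparison, where median-APE differences between models
are small and shorter windows would be noise-dominated.  The likelihood
inner loops (Kalman filter, ETS recursions) are numba-compiled; daily
refits warm-start from the previous day's optimum.  The regime-change
demonstration in the backtest tests uses a fixed scenario: at the
one-step horizon, window-length effects on MAPE are inherently small
(consistent with the near-tied published cross-window results), so that
test documents the *possibility* that a short window wins after a regime
change rather than a universal ordering.

## Known limitations

* Counts are forecast on a continuous scale with Gaussian errors; no
  integer-valued likelihood (Poisson/NB state space) is provided.
* The ETS seasonal period is weekly only; yearly seasonality lives in the
  Prophet-style model.
* The ICD-10-CM code lists for the secondary (respiratory-presentation)
  admission pathway are configurable approximations; the institutional
  lists are not public.
* No bootstrap CIs for MAPE or coverage; the AUC CI is the only
  uncertainty statement on the evaluation side.
* The generator emulates marginal and calendar structure, not causal
  drivers; transfer of any accuracy figure to real hospital data is an
  empirical question.
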