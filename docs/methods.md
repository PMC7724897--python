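# Methods

This note documents the statistical model, the numerical choices, and the
simulation design behind `contits`, in the order the pipeline runs.

## Problem setting and model

An interrupted time series (ITS) is a uniformly spaced outcome series
y(1), …, y(N) — here, typically a monthly health-outcome rate — whose
generating process changes at an intervention. We decompose

    y(t) = jump + trend + period + stochastic component,

where the first three are deterministic and removable, and model the
stochastic remainder with a linear stage plus a nonlinear residual stage.
The point of the design is that no component of the pipeline receives the
intervention date or its lag: delayed, immediate or temporary intervention
effects all surface as features of the series itself (a trend segment, a
level shift, extra curvature) that the battery, the preprocessing and the
flexible nonlinear stage absorb. This removes the most fragile analyst
choice in segmented-regression ITS analysis.

## Diagnostic battery

* **Mann–Kendall (trend).** S = ΣΣ sgn(y_j − y_i) over ordered pairs;
  variance with the tie-group correction; ±1 continuity correction;
  two-sided normal decision. Constant input gives S = 0, "no trend".
* **Seasonal Mann–Kendall.** Per-season scores summed across the ω
  seasons, one continuity correction on the aggregate (the standard
  convention — a per-season correction measurably deflates the size);
  cross-season covariances are set to zero (independent-seasons
  assumption — no estimator for them is better-supported at these sample
  sizes). With ω = 1 the statistic reduces exactly to the non-seasonal
  test. At 12 seasons of 10 observations the aggregate score is discrete
  with spacing 2, so the exact size at the nominal 5% normal cut is
  ≈ 0.044 — slightly conservative by construction.
* **Mann–Whitney (jump).** Standardized rank sum of the leading n₁
  observations, average ranks for ties, variance without tie correction;
  two-sided normal p-value. The p-value is a normal approximation: at very
  small n it is anticonservative relative to the exact permutation law
  (for two groups of 3 with maximal separation, normal p ≈ 0.0496 versus
  exact 0.10). The split index is a parameter — the intervention date when
  known, the midpoint otherwise. Note that a trending series produces rank
  separation between any two halves, so the jump screen responds to trends
  too; verdicts are read jointly.
* **Fisher (period).** The harmonic z with maximal periodogram ordinate
  a_z² + b_z² is reported through the harmonic-regression F ratio
  N(N−2)(a²+b²)/(4·RSS). The *decision*, however, uses the exact null
  distribution of Fisher's g = max ordinate / ordinate sum, because
  comparing a maximum over ~N/2 harmonics against a single-harmonic
  F(2, N−2) quantile has type-I error near 0.8, not 0.05. The F(2, N−2)
  critical value is still attached for the conventional readout.
* **KPSS (stationarity).** Computed through `statsmodels` (Bartlett
  weights 1 − s/(l+1), default truncation l = ⌊4(n/100)^0.25⌋, p-values
  interpolated in the published critical-value table, hence censored to
  [0.01, 0.10]). Null is stationarity: stationary iff p > α.
* **Jarque–Bera (normality).** n(S²/6 + (K−3)²/24) against χ²(2). The
  asymptotic p-value is adequate at n ≈ 100 (measured size ≈ 0.05).
* **Ljung–Box (residual independence).** N(N+2) Σ r_h²/(N−h) against
  χ²(m), default m = round(ln N). A `model_df` argument subtracts fitted
  ARMA parameters from the degrees of freedom when desired; the pipeline's
  adequacy check uses the plain form.

All six tests are calibrated: their empirical type-I error under an
iid-normal null at α = 0.05 (2000 replicates, n = 100; 10 cycles of ω = 12
for the seasonal test) lies within the 99% binomial interval around 0.05
(see `tests/test_acceptance.py` and `scripts/acceptance.py`, which measure
this rather than assume it).

## Preprocessing

Detrending fits an OLS line against t = 1..N (so the reported intercept is
the value at t = 1, the conventional printed form of a trend line) and
subtracts it. Differencing applies Δy(t) = y(t) − y(t−1) up to twice,
storing initial values and training tails. Normalization is gated on
Jarque–Bera: if the series already passes at α = 0.05 nothing happens;
otherwise a Box–Cox transform with profile-ML λ is applied, with a recorded
positivity shift of −min + half the training range + 1. The margin keeps
plausible held-out continuation values inside the transform's domain;
values still below it are clipped with a logged warning rather than
failing. Every step lands in a `DecompositionRecord` whose inverse chain
reproduces the input to 1e−9 (measured over 1000 random
detrend ∘ difference ∘ Box–Cox chains).

The `stationarize` driver mirrors the screening flowchart: test, remove
trend (by line or difference per the chosen scenario), re-test KPSS, cap at
two differencing rounds, then normalize; in `auto` mode both scenarios are
tried and the one passing more battery tests wins (ties go to detrending).
If stationarity is still rejected at the cap the pipeline proceeds with a
structured warning — a deliberate, flagged permissiveness.

## Linear stage: subset ARMA/ARIMA under a continuous GA

A specification is a *set* of active AR and MA lags (seasonal lags fold in
additively at multiples of ω), a differencing order d ∈ {0, 1, 2} and a
constant flag. Estimation is exact Gaussian maximum likelihood in state
space (statsmodels SARIMAX with a concentrated scale); excluded lags are
structurally zero. Model quality is

    AICC = N ln(MSE) + 2 Comp + 2 Comp (Comp + 1)/(N − Comp − 1),

with N the post-differencing training length, MSE the mean squared
one-step residual, and Comp the count of active (p, q, P, Q) terms plus
the constant.

The subset space (2^(p_max+q_max) − 1 non-trivial models) is searched by a
real-coded genetic algorithm: chromosomes in [0,1]^(p_max+q_max+1)
threshold at 0.5 into inclusion flags; tournament selection (k = 3),
whole-arithmetic crossover (rate 0.8), Gaussian mutation (rate 0.1,
sd 0.35, clipped), elitism 2, and two random immigrants per generation as
a premature-convergence guard. Defaults: population 40, 60 generations,
all seeded and logged. Fits are memoized by decoded spec, so on small
decode spaces the GA approaches exhaustive coverage at little cost; an
`exhaustive_search` twin exists for oracle comparisons. The candidate
order bound defaults to the highest correlogram lag outside the
±1.96/√N band, cappable (cap 10 by default).

Failure handling: a non-converged fit is retried with Nelder–Mead; a
persistently failing spec scores −∞ fitness; an all-zero chromosome is the
valid constant-only model.

## Nonlinear stage: generalized-structure GMDH

Neurons are polynomial regressions over 2 or 3 inputs (MNI) at degree 2 or
3 (PD), with coefficient counts 6/10/10/20 for (2,2)/(3,2)/(2,3)/(3,3),
fitted by least squares (minimum-norm solution with a conditioning warning
if rank-deficient). Layer growth scores every eligible input subset —
previous-layer survivors only (IM = 0) or all earlier nodes including the
original inputs (IM = 1) — by AICC on a held-out selection split (default
last 25% of training rows), with complexity Comp = NL + NTN of the
subnetwork ending at the candidate. The best MNN candidates survive
(MNN defaults to the input count); growth stops when the best candidate
stops improving or `max_layers` is hit. The winning neuron's ancestor
subgraph is then refitted on all training rows. Selection MSEs are floored
at var(y)·1e−20 so that "improvements" below numerical noise can never
justify an extra layer. When the candidate pool exceeds a budget (2000) it
is randomly subsampled under the run seed — the stochastic-structure
flavor of the algorithm — and is exhaustive below the budget.

For time series the network regresses the series on its own lags (default
{1, 2, 3}, consistent with correlogram-bounded short memory); recursive
forecasting feeds predictions back through the lag window.

## Hybrid and evaluation protocol

`fit_hybrid` pairs scenarios: the ARMA path detrends then normalizes
(d = 0); the ARIMA path normalizes and differences inside the stochastic
stage (d = 1). The linear stage's training residuals — the exact stored
vector, not a recomputation — become the GS-GMDH's training series.
Near-constant residuals degrade the hybrid to its linear stage with a
notice.

Two prediction modes exist and are never mixed:

* `forecast_hybrid` — pure multi-step: linear forecast (future shocks at
  zero) plus the residual network run recursively on its own predictions,
  summed and inverse-preprocessed.
* `predict_onestep` — rolling one-step: the fitted linear parameters are
  applied (no refit) to the transformed full series, each step's residual
  is predicted from *observed* previous residuals, and the sum is inverted
  pointwise.

Model comparisons (hybrid vs singles, lag-agnosticism) use the rolling
one-step protocol. The reason is structural: the exploitable residual
nonlinearity is a function of the previous innovation, which is
unforecastable more than one step ahead, so multi-step forecasts of all
models collapse toward the deterministic part and the comparison would
measure only trend extrapolation.

## Synthetic data: what it emulates and what it does not

`generate_its` composes intercept + slope·t, a sinusoidal seasonal term of
period ω, a simulated stationary ARMA path (root-checked, 10×max-lag
burn-in), an optional nonlinear term, and one of nine intervention
patterns: level / slope / both, each immediate, lagged, or temporary
(temporary effects end at a hard window edge by default; a linear ramp is
selectable). The exact component breakdown is returned and sums to the
series to 1e−12.

The nonlinear options are nonlinear moving-average terms in the lagged
*innovation* e of the noise process: quadratic λσ(e²/σ² − 1) or sinusoidal
λσ sin(1.5 e/σ). This is the package's defined study condition for
"nonlinearity": it is invisible to any linear projection (e² is
uncorrelated with the past linearly) yet recoverable from the linear
stage's residual lags — precisely the structure a residual-based hybrid
claims to capture. A nonlinearity in the raw trending outcome would be
dominated by the deterministic part and, for quadratic feedback, unstable.

The admissions-like preset (59 monthly values, slope 0.4792/month around
level 201.72, weak annual cycle, ARMA(1,1) noise with sd 6, a level drop
of 8 at month 37) targets the qualitative screening profile of such data:
trend detectable, marginally normal, non-stationary, weak periodicity.
Two caveats are inherent, not bugs: a trend of this size makes *any*
midpoint rank test flag a "jump" and lends the seasonal trend screen
power, so those two verdicts cannot be simultaneously "absent" in any
series of this shape; and the preset matches qualitative verdict rates
(≥80% over seeds for trend and normality), never exact statistics of the
real data, which the package does not ship.

## Simulation experiment design (problem sizes and conditions)

* **Calibration:** 2000 replicates, n = 100 (120 for the seasonal test),
  α = 0.05 — large enough that the 99% binomial band is ±0.0126.
* **Subset-ARMA recovery:** 20 paths of n = 500 from ARMA(2,1) with
  φ = (1.0, −0.7), θ = (0.4). The AR pair gives complex roots of modulus
  ≈ 1.2 (a pronounced pseudo-cycle), chosen because recovery can only be
  read against a generating structure the information criterion itself
  identifies: for weakly identified pairs (e.g. φ = (0.5, −0.3)) the
  exhaustive AICC optimum omits the second AR lag in a large fraction of
  paths, which is a property of AICC, not of any search algorithm. The GA
  is compared against exhaustive enumeration over its full decode space
  at p_max = q_max = 3 (constant free).
* **Composite fixtures** (hybrid comparison, lag-agnosticism): n = 260
  (200 train / 60 test), trend 0.15/step on level 100, weak annual cycle,
  ARMA(1,1) noise (φ = 0.5, θ = 0.3, σ = 2), quadratic innovation
  nonlinearity λ = 0.5 (≈ one third of one-step residual variance), and an
  intervention at t = 120 with level +6 and slope +0.05. The 60-point
  holdout keeps correlation-type indices stable; the intervention sits
  inside the training window so that the lag sweep {0, 3, 6} changes what
  the models must absorb, not what they are scored on. Single-model
  baselines: the hybrid's own linear stage (residual stage zeroed) and a
  GS-GMDH on the raw series lags.

These sizes are the package's chosen desk-scale study conditions; the
experiments run in minutes on one core.

## Known limitations

* The MW/SMK screens respond to trends (above); battery verdicts need
  joint reading.
* Seasonal subset lags are additive, not multiplicative, in the lag
  polynomials.
* The KPSS p-value is table-censored to [0.01, 0.10].
* One-step evaluation, while the right protocol for residual
  nonlinearity, gives little advantage to the hybrid at long pure-forecast
  horizons.
* GS-GMDH polynomials extrapolate poorly outside the training range of
  their inputs; on strongly trending raw series the preprocessing (not the
  network) must carry the trend.
* Counts are modeled on the rate scale; no Poisson/overdispersion
  machinery is included.
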