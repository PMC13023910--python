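# Methods

## The sensing model

A microbial electrolysis cell (MEC) sensor converts biofilm metabolic
activity into a current.  We model one exposure as a noise-free curve
plus i.i.d. Gaussian measurement noise:

    I(t)  = I0                                              t < t_inj
    I(t') = I0 · [1 + A · (t'/τ_up) · e^(1 − t'/τ_up) · 1(stress)]
               · [1 − f · (1 − e^(−t'/τ_dec))]
            + 1(recovery) · r · I0 · (1 − e^(−max(0, t' − t_r)/τ_rec))

with t' the time since injection.  The three factors are the three
biological regimes the sensor exhibits: a transient *stress* rise (the
biofilm transiently upregulates metabolism under toxic stimulus), a
dose-dependent *inhibition* decline toward a plateau, and a partial
*recovery* at sub-threshold doses as the community adapts.  The stress
pulse `(t'/τ)e^(1−t'/τ)` is a unit-peak gamma-like shape; any smooth
unimodal pulse would serve — this one is fixed for reproducibility.

### Dose and mixture interaction

Concentrations combine by concentration addition in toxic units
`TU_j = ppm_j / c_max,j` (panel maxima: formaldehyde 200 ppm,
tetracycline 5 ppm, silver nitrate 100 ppm, copper sulfate 100 ppm).
The effective dose of a composition is

    dose = λ · 10 · Σ_j TU_j        [EC units]

where λ is a per-setup interaction factor (λ > 1 synergy, λ < 1
antagonism, λ = 1 additive).  The inhibited fraction is linear in dose,
`f = min(β·dose, f_cap)` with β = 0.02/EC and f_cap = 0.95.  A linear
(not Hill-shaped) dose–response was chosen deliberately so that the
fixed-time response is linear in EC, matching the linear calibration
behaviour this class of sensor shows over the working range.

By construction a single toxicant at its panel maximum is dose 10, and
the EC gradient {1,3,5,7,10} scales every component of a setup together,
so `Σ TU = ec/10` for every setup (toxic-unit conservation).

### Per-toxicant kinetic signatures

With a single shared timescale, every trace would be a function of the
scalar dose alone and per-component concentrations would be structurally
unidentifiable — no regressor could separate the four toxicants.  Real
toxicants differ in mode of action, and the generator encodes that as
per-toxicant parameters, combined across a mixture by toxic-unit-weighted
averaging (timescales, recovery) or summation (stress amplitude):

| parameter (units) | formaldehyde | tetracycline | AgNO₃ | CuSO₄ |
|---|---|---|---|---|
| decline τ_dec (s)      | 110   | 250   | 25    | 60    |
| stress amp / EC (–)    | 0.015 | 0.002 | 0.005 | 0.010 |
| stress peak τ_up (s)   | 30    | 45    | 15    | 66    |
| recovery capacity (–)  | 0.10  | 0.06  | 0.00  | 0.02  |

The pattern follows standard toxicodynamics: dissolved silver acts fast
and allows no adaptation; the antibiotic acts slowly on protein
synthesis; the degradable organic provokes the strongest stress response
and the strongest adaptation.  Each toxicant is extreme in at least one
channel, so the four signature vectors span a non-degenerate simplex and
mixture weights are recoverable in principle.  Recovery is graded,
`r = capacity · (1 − dose/threshold)` below the threshold of 5 EC units,
and capped at 80% of the inhibition plateau — adaptation restores part of
the impaired electron transfer, never more than was lost (this cap also
makes the noise-free ΔI/I₀ monotone in EC within a setup).

### Noise and variability

Defaults: baseline I₀ ~ N(1 mA, (0.01 mA)²) per trace, pointwise noise
sd 0.3 µA (clipped at 5 sd; a benchtop potentiostat averaging over a 12 s
sampling interval resolves sub-µA), sampling every 12 s, 60 s baseline +
300 s exposure (5 + 26 samples).  These choices set the signal-to-noise
of the synthetic study to the regime in which this sensor class operates:
fixed-time responses of 0.02–0.4 resolved to ~1%.

Interaction factors: singles λ = 1; mixtures draw log-uniform λ ∈
[0.25, 1.8] from the design seed, with two conditions pinned to the
observed extremes — λ = 1.6 (formaldehyde–tetracycline 2:1) and λ = 0.18
(quaternary 1:1:1:1).

### Named configurations

* `SimulationParams.additive_reference()` — noise-free, stress and
  recovery off, one shared τ_dec.  Used for interaction-index and
  calibration checks: when mixture and single exposures share kinetics,
  the saturation factor (1 − e^(−T/τ)) cancels in the II ratio and the
  recovered II equals λ exactly.  With toxicant-specific kinetics the
  concentration-addition reference itself shifts (a real phenomenon:
  singles and mixtures then saturate differently), so II would estimate λ
  only up to a kinetic factor of order ±10%.
* `SimulationParams.stress_coupled()` — shared timescales with per-trace
  lognormal latency jitter (sd 0.4) and larger, well-separated
  per-toxicant stress amplitudes.  This isolates the stress-amplitude
  channel as the carrier of toxicant identity; the current increment
  I_max − I₀ is then the one unconfounded reader of that channel and
  ranks in the Gini top-5 for every toxicant.  Under the full five-channel
  defaults, impurity-decrease credit splits near-arbitrarily among the
  correlated stress readers (I_max − I₀, k_max-0, D_max, t−D_max), so the
  rank of any single reader is not a stable property there; across noise
  realizations the worst-of-four rank in the coupled configuration
  fluctuates by roughly ±1 around 4.

## Feature engineering

All 22 descriptors are computed on the post-injection window, with
extrema ties resolved to the earliest sample.  I₀ is the mean of the
trailing 60 s pre-injection window (sample sd → σ₀); with no
pre-injection samples it falls back to the first sample.  Numerical
conventions: trapezoidal integral; derivatives are central finite
differences (one-sided at the window ends) of a centered moving average
(window 5, truncated at the edges); `Δt = t(I_max) − t(I_min)` is kept
signed and the secant slope is defined as 0 for a constant trace so
degenerate inputs featurize rather than fail.  The event flags are noise-
calibrated: `up` fires when the raw maximum within 60 s of injection
exceeds I₀ + 3σ₀; `back` fires when any smoothed sample after the minimum
exceeds I_min + 3σ₀ (and the minimum is not the final sample).  Features
are never normalized except where the definition divides by I₀.

## Interaction statistics

The Interaction Index divides the mixture's replicate-mean ΔI/I₀ by the
sum of single-toxicant responses *at each component's actual ppm in the
mixture*, obtained by linear interpolation of the single-exposure
response table (the standard concentration-addition reading).  The table
is anchored at (0 ppm, 0 response) — true by definition — so mixture
components below the lowest tested single concentration interpolate
toward zero instead of clamping; above the range the lookup clamps.
Negative mixture responses (noise) are floored at 0; a non-positive
denominator raises rather than returning an undefined ratio.

Fixed-time responses map 30/60/300 s to the nearest grid sample; on the
12 s grid, 30 s is equidistant between 24 s and 36 s and resolves to the
later sample (36 s).

## Regression protocol

One single-output model per toxicant (per-toxicant scores require it);
ten-fold cross-validation with shuffled fold assignment seeded at 42;
metrics (MAE, RMSE, R²) on the pooled out-of-fold predictions, one number
per model × toxicant.  Features are z-scored inside each training fold
for SVM, KNN and PLS; trees consume raw features.  Hyperparameters are
pinned rather than left to library defaults so results cannot drift:
SVR(C = 1, ε = 0.1, γ = 1/(d·var)), KNN(k = 200, Euclidean; k clamps to
the training-fold size with a warning when it exceeds it), PLS(2
components), RF(100 trees, seeded).  R² may be negative — predictions
worse than the observation mean — and is reported as such.

## Overfitting diagnostics

* Learning curves: seeded subsamples per training size, RMSE on training
  and held-out folds (5-fold), mean ± sd.
* Train/test split: grouped by (setup, EC) condition so replicates never
  straddle the split; a setup with single replicates falls back to a
  random split with a warning.  This is a *condition-level*
  generalization test and is deliberately harsher than replicate-level
  scores.
* OOB vs test: the out-of-bag R² (reconstructed per tree from the exact
  bootstrap masks; samples in every bootstrap are excluded with their
  count logged) is compared against a *random* held-out split — both
  sides are then replicate-level scores and agree within a few
  hundredths.  Comparing OOB to the grouped split would conflate two
  different generalization levels.
* Gini importances are normalized mean impurity decrease (non-negative,
  sum 1), reported with ranks.

## Problem sizes

The default study is the full design: 43 setups × 5 EC levels × 6
replicates = 1290 traces of 31 samples each.  Interaction-index checks
use 2 replicates, calibration checks 1 (both noise-free, where replicates
add nothing); learning curves use sizes 50–1000.

## What the generator does and does not emulate

It emulates: dose-dependent inhibition with saturation, stress
transients, low-dose adaptation, mixture synergy/antagonism, replicate
variability, and the sampling/duration of the real instrument.  It does
not emulate: baseline drift or autocorrelated noise, biofilm aging
between batches, Hill-shaped dose–response outside the linear working
range, inter-reactor heterogeneity beyond baseline scatter, or chemical
speciation (e.g. precipitation in mixtures).  Passing tests therefore
demonstrate that the *pipeline* — features, statistics, models,
diagnostics — behaves correctly on data with the stated structure; they
do not certify performance numbers on any real sensor, where the
condition-to-feature mapping is richer and noisier.  In particular the
synthetic design is a discrete grid of 215 conditions, so the forest
partly acts as a condition lookup; its condition-level (grouped-split)
test R² is substantially lower than its replicate-level R², and both are
reported separately.

## Known limitations

* The kinetics (timescales, stress amplitudes, recovery capacities) are
  plausible but not fitted to measured curves; only qualitative shape
  fidelity is claimed.
* The interaction factor λ acts multiplicatively on summed toxic units —
  the simplest mechanism that makes II identifiable; real interactions
  can be dose-ratio-dependent.
* II estimation assumes mixture and single exposures share response
  kinetics (see `additive_reference` above).
* KNN with k = 200 on ~1160-row training folds is heavily smoothed by
  construction; its poor scores reflect that protocol choice, pinned for
  comparability.
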