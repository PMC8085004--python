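# Methods

This note documents the models, conventions and design choices behind
`adaptrate`: what exactly is computed, which parameters matter, what the
synthetic data do and do not emulate, and where the genuinely open
design decisions were made.

## 1. The adaptation-rate estimators

All four estimators are slopes of a regression with intercept, applied
to a contiguous sequence of `n ≥ 3` trials toward a fixed target `x_i`.
With `x_u` the noise-free endpoint (motor intent), `x_m = x_u + η_q` the
measured endpoint (`η_q ~ N(0, Q)` control noise), `x_s = x_m + η_r` the
sensed endpoint (`η_r ~ N(0, R)` feedback noise) and `x_p` the perceived
endpoint:

| estimator    | response              | predictor      | needs                  |
|--------------|-----------------------|----------------|------------------------|
| gold         | `x_u[k+1] − x_u[k]`   | `x_p[k] − x_i` | both latents (simulation only) |
| silver       | `x_u[k+1] − x_u[k]`   | `x_m[k] − x_i` | per-trial known noise (`x_u = x_m − η_q`) |
| conventional | `x_m[k+1] − x_m[k]`   | `x_m[k] − x_i` | endpoints only         |
| analytic     | `(cov(x_m[k+1], x_m[k]) − var(x_m[k]) + Q) / var(x_m[k])` | | endpoints + `Q` |

The analytic form follows from writing the silver slope as
`cov/var` and cancelling the noise cross-terms: `cov(η_q[k], x_m[k]) = Q`
and `cov(η_q[k+1], x_m[k]) = 0`, while the target drops out of all
centered quantities (`var(x_m − x_i) = var(x_m)`).

**Numerical conventions** (the quantitative results depend on them):

* `cov` and `var` are the unbiased (`ddof = 1`) sample statistics over
  the `n − 1` lagged pairs, i.e. denominator `n − 2`. The same
  denominator must be used for both, because `Q` enters on an absolute
  scale — mixing a `1/n` convention into the numerator would bias it by
  `O(Q/n)`.
* The denominator variance is computed over the predictor trials
  `x_m[1..n−1]` only (the trials that actually serve as regressors).
* With `Q = 0` the analytic estimator is *algebraically identical* to
  the conventional slope; this identity is enforced by tests to 1e−9.
* Estimates are signed (negative = corrective). Absolute values are a
  reporting convention only (`report_abs`, `fit(absolute=True)`).
* Series with gaps are refused; callers segment first. Minimum length 3
  (two lagged pairs, so a slope with intercept is defined). Degenerate
  (zero-variance) predictors raise rather than returning NaN.

Population reference values used throughout the tests, derived from the
linear error-correcting process `x_u[k+1] = x_u[k] + A(x_m[k] − x_i)`,
`x_m = x_u + η`, `η ~ N(0, Q)`: stationary error variance
`V = A²Q / (1 − (1+A)²)`; `E[analytic] = A` exactly; `E[conventional] =
A − Q/(V+Q)` (= −1.15 for A = −0.3, Q = 1); for pure iid endpoint noise
conventional → −1 and analytic → 0.

**Uncertainties.** Gold/silver/conventional are OLS slopes and report
the classical OLS slope standard error. The analytic estimator is a
ratio of lagged moments with no exact small-sample SE; `fit(n_boot=...)`
provides a circular block bootstrap over the lagged pairs (block length
`≈ n^(1/3)`, preserving serial dependence).

## 2. The hierarchical Kalman-filter learner

The simulator generates ground-truth data from a Bayesian model of an
experienced performer. Per trial:

1. **Predict:** parameter uncertainty inflates, `P_pred = P_p + ξ`.
2. **Plan:** `u = x_i / B̂` (inverse internal model; `|B̂| < 1e−6`
   raises rather than producing unbounded commands).
3. **Move/sense:** `x_u = B·u`; `x_m = x_u + η_q`; `x_s = x_m + η_r`
   (fixed draw order `η_q`, then the optional added-noise stream, then
   `η_r`; one seeded generator per run, so runs are bit-reproducible).
4. **Perceive (layer 1):** Kalman fusion of the premotor prediction
   `x_i` (prior variance `Q + u²·P_pred` — the endpoint prediction is
   blurred by control noise and by parameter uncertainty propagated
   through the command) with `x_s` (variance `R`):
   `x_p = x_i + K₁(x_s − x_i)`, `K₁ = prior/(prior + R)`.
5. **Learn (layer 2):** the percept is treated as a measurement of the
   noise-free endpoint `B̂·u` with observation variance
   `obs = Q + posterior₁` (control noise plus perceptual posterior
   variance): `B̂ ← B̂ + K₂(x_p − B̂u)`, `K₂ = P_pred·u/(u²P_pred + obs)`,
   `P_p ← (1 − K₂u)P_pred`.

Defaults: `B = 1`, `B̂⁽¹⁾ = 1`, `P_p⁽¹⁾ = 5`, `x_i = 100`, `Q = R = 1`,
`ξ = 0.1`.

Two choices here were genuinely open, and both are configurable:

* **Layer-2 observation variance.** Including `Q` (default,
  `obs_var_mode="control+percept"`) makes the learner discount large
  errors when its own output is noisy; this is what produces the
  characteristic behavior that true adaptation *decreases* with
  growing control noise. With the perceptual posterior alone
  (`"percept"`), `Q` barely reaches the parameter update and the gold
  AR stays pinned near −1 across the entire `Q` range — retained as a
  variant because the decomposition is a modelling convention.
* **ξ as variance increment vs sampled perturbation.** `ξ` is
  implemented as additive process variance in the layer-2 predict step
  (an uncertainty increment), not as a sampled disturbance of `B`.
  Sampling would make the *world* nonstationary; the increment makes
  only the learner's *confidence* decay, which is the intended role of
  an internal-model noise parameter.

A degenerate corner is defined by continuity: when the update is fully
certain and fully consistent (`u²P_pred + obs = 0` and zero innovation)
nothing is learned and the state passes through unchanged; a zero-
variance update with a *nonzero* innovation is a contradiction and
raises.

## 3. Simulation studies and the scales used

**Parameter sweep** (`run_sweep`): one of `Q`, `R`, `ξ` varied over a
log₁₀-uniform grid (endpoints included) from 1e−2 to 1e2, the others at
the defaults above; per grid value, independent runs with seeds
`base + run_index`, estimators applied to the last 1000 of 1500 trials;
mean/SD of the signed estimates, mean |AR|, and the MSE of each
estimator against the *per-run* gold value (error of matched runs, not
of means). Reference scale is 100 grid values × 1000 runs; the shipped
tests and the acceptance script use 20 values × 100 runs, which
reproduces the qualitative structure (gold |AR| falls monotonically in
`Q`; conventional rises; analytic tracks gold, and for `Q > R` its MSE
is below the conventional MSE at every grid value).

**Window study** (`run_window_study`): fixed parameters, runs of 2000
trials, estimators applied to nested windows of 20…1000 trials (step
10) starting at trial 1000; run-to-run SD per window size. Reference
scale 10,000 runs; tests and acceptance use 500. At 500 runs the SD
curves still carry Monte-Carlo jitter of the same order as the ~1%
per-step decrease, so adjacent window sizes show occasional SD
upticks (4–9% of adjacent pairs depending on seed) even though the
end-to-end reduction (SD at 1000 vs at 20: factor ≈ 6–7) is unambiguous.

## 4. The empirical pipeline and the synthetic experiment

The pipeline mirrors a cursor-to-target task with endpoint-only
feedback: per block, (i) backwards and short movements (< 25% of the
way to the target) are treated as accidental clicks and removed without
breaking contiguity; (ii) off-screen movements have unmeasurable error,
so the analyzable record is split there; (iii) the longest contiguous
segment is kept (ties → earliest); (iv) the initial learning transient
is trimmed; (v) the estimators run on the steady-state segment, the
silver AR using `x_u = endpoint − added_noise` and the analytic AR
using `Q = Q_added` — deliberately ignoring the participant's baseline
control noise, which is unmeasurable per trial; (vi) per-estimator
one-way repeated-measures ANOVAs across the NO/LOW/HIGH added-noise
conditions, with Mauchly's sphericity test, Greenhouse–Geisser
correction of the degrees of freedom when sphericity is rejected at
α = 0.05, and Bonferroni-corrected paired comparisons. Subjects with
any failing block (fewer than 20 analyzable steady-state trials) are
excluded listwise. The ANOVA machinery is delegated to pingouin and is
cross-checked in the tests against statsmodels' `AnovaRM` to 1e−6.

**Steady-state detection** is a convention, not part of the estimators,
so it is swappable: the default detector returns the earliest trial
from which the 20-trial sliding mean absolute error stays within 20%
of the mean absolute error over the final half of the segment; a fixed
burn-in override is available. Blocks end up with ≈ 90 of 100 trials
analyzed under the default generator settings.

**The synthetic experiment generator** emulates the task it will be
analyzed as: 22.4 cm target; three 100-valid-trial blocks per subject
under added control noise of SD 0 / 2.24 / 4.48 cm (0%, 10%, 20% of
movement distance; `Q_added = SD²` — the SD is primary and the variance
derived); condition order drawn per subject from the six permutations;
invalid movements injected at per-trial rates 1% (backwards), 1%
(short), 0.3% (off-screen), the last rate set so that blocks retain the
~90-trial steady-state segments typical of the task. Learner
parameters, chosen once as plausible for this task and kept: baseline
control noise `Q = 1 cm²` (SD ≈ 4.5% of movement distance), sensory
noise `R = 0.1 cm²` (precise visual endpoint feedback), `ξ = 0.01`,
initial gain estimate 0.9 (a mild miscalibration, so each block has a
transient for the detector to trim), `P_p⁽¹⁾ = 5`. The added noise is
drawn as its own recorded stream and the learner's effective
control-noise variance is `Q + SD²` — the simulated participant knows
its overall noisiness, which is precisely what makes true adaptation
fall from NO to HIGH.

What the generator does *not* emulate: baseline-noise heterogeneity
across subjects, proprioceptive feedback (all sensory noise is lumped
into `R`), order/fatigue effects within a session, and any drift of the
true gain `B`. Passing pipeline tests therefore demonstrate that the
estimators and statistics behave correctly for a rational, stationary
learner — not that every human dataset will show equally clean trends.

## 5. Known limitations

* The analytic estimator needs `Q`; misspecifying it shifts the
  estimate by `ΔQ / var(x_m)`.
* At small window sizes (tens of trials) the analytic estimator is as
  variable as the conventional one; its advantage is in bias, not
  variance. Analyze as many steady-state trials as available.
* The silver/analytic agreement on short blocks carries `O(1/√n)`
  Monte-Carlo noise in group means; with 26 subjects × ~90 trials,
  group-mean gaps of a few hundredths are expected jitter.
* The learner model is one defensible reconstruction of a hierarchical
  Bayesian motor learner; the estimators themselves are model-free, and
  the layer choices that matter are exposed as options.
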