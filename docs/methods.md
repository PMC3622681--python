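# Methods

`ofcbmi` implements a two-stage real-time brain-machine interface (BMI)
for an instructed-delay center-out cursor task, together with a
closed-loop simulator rich enough to exercise every part of the decoder
with synthetic spikes only.  This note records the models, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## Task model

The task is the standard instructed-delay center-out reach: a 500 ms
center hold, a 1000 ms instruction epoch during which one of four
peripheral targets is cued, a go cue, and a 3 s timeout.  Touching any
non-cued target disk first aborts the trial, so chance-level
acquisition accuracy is at most 25% for any decoder.  Spikes are
binned at 5 ms throughout; the cursor is pinned at the center until
the go cue.

Workspace geometry is dimensionless with `target_distance = 0.1`
(about a 10 cm reach) and `target_radius = 0.025`.  No screen geometry
is published for this class of experiment, so these are package
choices: the radius is a quarter of the reach so that the four disks
subtend a realistic angular window without overlapping.  Disk entry is
tested at bin endpoints against closed disks; at 5 ms bins intra-bin
interpolation would change entry times by at most one bin.

## Movement prior: LQG optimal feedback control

Reaches are modelled with a per-dimension muscle-like plant

    dp/dt = v,    dv/dt = (f − b·v)/m,    df/dt = (u − f)/τ,

with `b = 10 N·s/m`, `τ = 40 ms`, `m = 1 kg` — standard biomechanics
values for planar reaching.  The six-dimensional state
`[p, v, f] ⊗ {x, y}` is discretized by exact zero-order hold at
`dt = 5 ms` (exact for an LTI plant at any step, unlike Euler).
Process noise enters on the force channels only.

A reach of duration `T` to target `d*` minimises

    ‖p_T − d*‖² + w_v‖v_T‖² + w_f‖f_T‖² + Σ_t u_tᵀ R u_t ,

a terminal accuracy + stopping + effort cost.  The optimal policy is
linear state feedback `u_t = −L_t (x_t − x*)` with `x* = [d*, 0, 0]`
and gains from the finite-horizon backward Riccati recursion,
precomputed per duration (they depend on the horizon, not on the
target, so one gain table serves all targets).

**Weight defaults.** The classical prescription is to weight the cost
terms so they contribute about equally on average.  For this plant
that prescription alone is degenerate: the four-term balance can
always be improved by making the controller stiffer (R → 0), and the
iterative rebalancer (`calibrate_weights`, provided and tested)
converges into that stiff corner from generic starting points.  The
package's defaults instead fix the effort scale first at a
physiological level — `R = 1e-6·I` keeps commanded forces near 3 N for
a 10 cm, 0.6 s reach — and balance the three *terminal* terms under
the default process noise (`w_v = 0.024`, `w_f = 3.7e-5`, measured
spread < 1.5×); the effort term then sits within a factor ≈5 of the
terminal terms.  Noiseless rollouts with these weights are straight
(lateral deviation < 2% of the reach), have bell-shaped speed
profiles, and stop within ≈5% of the target.

**Process noise.** `σ_f = 1.45 N/√bin` was calibrated once so that
noisy closed-loop rollouts acquire the target disk in ≈90% of
unassisted reaches, which makes simulated manual sessions resemble
trained-subject behavior (the suite asserts ≥85%).

## Encoding models

*Delay epoch.* Each neuron is a homogeneous Poisson process whose rate
depends only on the cued target.  The maximum-likelihood rate is
count/exposure over the decode window — the last 800 ms before the go
cue; the first 200 ms after cue onset are discarded to allow the
visual information to reach premotor cortex.  Rates are floored at
0.1 spikes/s because the decoder takes `log(λΔ)`.

*Movement epoch.* Rates are log-linear in position and velocity
(`λ = exp(α + βᵀ[p_x, p_y, v_x, v_y])`), a modified cosine-tuning
model, fitted per neuron as a Poisson GLM with a log-exposure offset
via statsmodels' IRLS.  Covariates are standardized internally for
conditioning; coefficients, standard errors, and Wald p-values are
reported in native units.  Tuning classification
(position-only / velocity-only / both / untuned) uses Bonferroni
correction across all neuron × coefficient tests at family level
0.05.  Neurons whose fit fails (separation, non-convergence) are
flagged and classified untuned rather than aborting the session fit.

Everywhere `λΔ` is used as a per-bin Bernoulli event probability it is
clamped at 0.95 to stay a valid probability.

## Stage 1: maximum-likelihood target decoding

With neurons conditionally independent given the target, the ensemble
log-likelihood of a delay window under target `m` is the Bernoulli
point-process sum `Σ_c Σ_t [ΔN log(λ_c(m)Δ) + (1−ΔN) log(1−λ_c(m)Δ)]`
(exact for binary bins; equivalent to the Poisson form at λΔ ≪ 1).
The decoder takes the argmax; exact ties are broken uniformly at
random with a caller-supplied generator to avoid positional bias.
Cross-validation is leave-one-out throughout, with the constant-rate
refits done incrementally from count totals.  The neuron-dropping
analysis ranks neurons by single-cell leave-one-out accuracy and
reports the smallest top-k ensemble reaching 90% of the full-ensemble
accuracy.

## Stage 2: feedback-controlled point process filtering

The trajectory decoder is a recursive Bayesian filter with Gaussian
beliefs.  Prediction pushes the posterior mean through the
feedback-controlled model, `mean ← x* + (A − B L_t)(mean − x*)`.  The
update is information-form with intensities linearised at the
predicted mean:

    Σ⁻¹ ← Σ_pred⁻¹ + Σ_c λ_c Δ · b_c b_cᵀ
    mean ← mean_pred + Σ Σ_c b_c (ΔN_c − λ_c Δ),

where `b_c` embeds the tuning vector into state space (zeros on
force).  The innovation `ΔN − λΔ` is spike-indicator minus predicted
spike probability.  Posterior covariances are symmetrized and
eigenvalue-clipped at −1e-10; with Gaussian observations substituted
for the Bernoulli likelihood the recursions reduce exactly to a Kalman
filter (verified against the textbook form).

**Covariance propagation.** The prediction covariance propagates
open-loop through `A`, not through `(A − B L_t)`.  Rationale: in
decoding, the control input is a deterministic function of the
*displayed* cursor state — the previous posterior mean, which the
filter knows exactly — so feedback should not contract the filter's
uncertainty.  Propagating through the closed loop makes the filter
overconfident: measured on the default conditions, duration
identification drops (55% vs 68% modal-true) and the second stage
loses its ability to override a wrong decoded target.  The closed-loop
variant, in which feedback is of the latent state itself, remains
available via `closed_loop_cov=True` for sensitivity analysis.

**Duration mixture (FC-P-PPF).** The gain schedule depends on the
movement duration, which the decoder cannot know, so one FC-PPF runs
per candidate duration on the coarse grid {0.4, 0.6, 0.8, 1.0, 1.2} s
(within the 3 s timeout and centered near the ≈0.6 s natural
acquisition time).  Each bin, each active filter's log-weight is
incremented by its one-bin predictive log-likelihood, computed by a
Gaussian (Laplace) approximation from quantities the update step
already produced:

    log p(ΔN|x̂_post) + log N(x̂_post; x̂_pred, Σ_pred) + ½ log det(2π Σ_post).

A dense-quadrature oracle on a 1-d toy bounds the approximation error
below 1e-2 in log-likelihood.  Weights are renormalised each bin over
the active set {i : T_i ≥ t} in log space with log-sum-exp; a filter
whose duration has elapsed drops out, and past the longest grid point
the last filter continues with its terminal gain frozen to avoid an
output discontinuity.  An all-weights underflow triggers a logged
uniform reset.  The combined estimate is the weight-averaged posterior
mean.  The RW-PPF ablation is the same recursion with `B = 0` — no
goal information, smoothness only.

## Ridge baseline

Position is regressed on the history of trailing-window (100 ms,
stepped at 5 ms) standardized firing rates,
`f = (RᵀR + δI)⁻¹ Rᵀq`, decoded causally.  History length
{200, 400, 600, 800} ms and δ (log-spaced, scaled by the mean diagonal
of RᵀR) are selected by leave-one-trial-out CV; standardization
moments and the position mean are frozen per training fold.  The
chance control shuffles each neuron's rates across time and trials,
preserving its rate distribution exactly.

## The simulator

`make_population` draws the ground truth the encoding models are
supposed to recover.  Defaults emulate the recording statistics the
decoder targets: 20 neurons; log-normal baselines around 5 spikes/s;
48% of cells target-tuned with cosine tuning in target angle; 47%
kinematically tuned, split 57/15/28 between position-only,
velocity-only, and both.  Two depths were calibrated once against
published ensemble-level statistics rather than invented: the delay
tuning depth (`target_kappa = 0.5`) reproduces ≈81% leave-one-out
ensemble target accuracy at 89-trial sessions, and the velocity
log-gain (12 per unit speed, i.e. an order-of-magnitude rate swing at
peak speed) places the random-walk decoder's closed-loop accuracy in
the reported intermediate range and gives the peri-movement activity
genuine corrective power.  The position log-gain (10 per workspace
unit) keeps λΔ below the clamp everywhere in the workspace.

Manual-control trials draw a uniformly random target and an intended
duration uniform over the grid range, roll the noisy LQG plant, and
thin spikes per 5 ms bin (delay rates during the instruction epoch,
kinematic rates along the realized movement).

Closed-loop trials put a simulated subject in the loop.  Each bin the
subject (i) slaves its internal position to the displayed — decoded —
cursor (perfect visual feedback), (ii) keeps its own intended velocity
and force, (iii) computes its LQG corrective command toward the *cued*
target with its own intended-duration gains, (iv) advances its
internal state through the noisy plant, and (v) emits spikes from the
kinematic model at that internal state.  This is the minimal
realization in which the subject's spikes carry corrective intent
while position feedback is of the cursor actually shown.  How real
neurons re-encode intent under closed-loop control is not something
this package can settle; the assumption is a modeling choice and is
the main caveat on the closed-loop results.

Sessions default to 89 trials with per-trial counter-split random
streams, so sessions are reproducible and trial k is unaffected by
changes elsewhere.

## What the synthetic benchmark shows — and does not

Because spikes are generated from the same model families the decoder
fits, the benchmark establishes *internal correctness* (oracle
equivalences, parameter recovery within 3 SE, exact chance levels) and
*mechanistic behavior* (the two stages correcting each other, duration
inference working, graceful degradation to the prior when tuning is
absent).  It does not establish real-data performance: real neurons
have history effects, non-Poisson variability, nonstationarity, and
unknown closed-loop re-encoding, none of which are simulated.  The
published real-data effect sizes are therefore not treated as pass/fail
numbers anywhere in the suite.

One directional result is condition-sensitive and worth flagging: the
roughness ordering between the two-stage decoder and the RW-PPF.  With
weakly informative peri-movement activity the RW-PPF wanders and is
rougher (the published situation); with strongly velocity-tuned
ensembles it becomes sluggish — smooth but inaccurate — and the
roughness ratio can flip even while the accuracy and RMS orderings are
preserved.  The accuracy comparisons are stable across the population
draws we simulate; the roughness comparison is reported but should be
read with this caveat.

## Problem sizes

The suite and the acceptance script use desk-scale problem sizes
chosen as the package's own benchmark conditions: 89-trial training
sessions (the typical session size), 240-trial sessions for parameter
recovery and chance-level constructions, 200 paired closed-loop trials
for decoder comparisons, 10,000 draws for the chance classifier, and
100 seeded runs for the duration-mixture modal check.
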