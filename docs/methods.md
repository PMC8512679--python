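# Methods

This note documents the models implemented in `gaitkinetics`, the
assumptions behind them, the tunable parameters that matter, what the
synthetic data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Problem and pipeline

Net sagittal joint torques (hip and knee flexion/extension, ankle
plantar/dorsiflexion) are standard clinical gait outcomes. Computing
them requires the ground reaction force (GRF) and its centre of
pressure (COP), conventionally measured with force plates — equipment
that confines the analysis to a laboratory. The package implements and
evaluates a paradigm that replaces the force plates with statistical
estimates:

1. candidate features (joint angles, linear and angular velocities and
   accelerations, EMG envelopes) are reduced by regression
   neighbourhood component analysis (NCA);
2. per-channel feedforward networks estimate AP/ML/vertical GRF (in
   %BW) and AP/ML COP (in mm, heel-referenced);
3. joint torques are predicted from those estimates by (M) planar
   Newton–Euler inverse dynamics and (N) a hybrid EMG-informed
   neuromusculoskeletal model;
4. conditions crossing estimated/measured GRF and COP sources
   (EGEC, EGMC, MGEC × M/N) quantify how estimation error propagates
   into each joint's torque, with R²/RMSE metrics and a nonparametric
   statistical branch (Friedman + Dunn–Bonferroni, α = 0.05).

Everything runs intrasubject and leave-one-trial-out: each of a
subject's four trials is tested against models trained/calibrated on
the other three.

## Planar stance-leg dynamics

The body is four planar rigid segments — foot, shank, thigh, and a
HAT lump (head–arms–trunk, which here also absorbs the swing leg so
that segment masses sum exactly to body mass). Anthropometrics follow
Winter-style fractions of body mass and stature (`winter_hat` table).
Sign conventions: x anterior, y up, ground at y = 0; reported torques
are positive in extension/plantarflexion; joint-angle coordinates are
chosen conjugate to that torque convention (hip extension, knee
extension, ankle plantarflexion positive), so extensor muscles have
positive moment arms and joint power is `τ·θ̇` throughout.

Two mutually inverse entry points exist. `forward_ground_reaction`
computes the AP/vertical GRF from the whole-body Newton equation and
the AP COP from the whole-body moment balance about the ground plane.
`inverse_dynamics` runs the distal-to-proximal recursion
foot → shank → thigh. For any kinematic description the two agree to
round-off; the generator additionally verifies the bottom-up hip
torque against the HAT segment's top-down requirement (< 1e-8 Nm).
This exactness is the package's central oracle: a regression anywhere
in the kinematic chain, the recursion, or the generator breaks it
immediately.

Structural consequences worth knowing when reading results:

* a COP error δ shifts *every* joint torque by exactly `GRF_V·δ`
  (transport of the application point), so under MGEC all three
  joints show identical RMSE — in a 3-D model the couplings differ;
* a GRF error works through the height of each joint above the
  ground, i.e. a short lever at the ankle and the full leg length at
  the hip. This is the mechanism behind the headline sensitivity
  ordering (hip most sensitive, ankle most resistant), and it is a
  property of the recursion, not of any particular cohort.

## Synthetic gait generator

The generator stands in for a motion-capture/force-plate/EMG dataset
(five subjects × four self-paced walking trials, one right-leg stance
phase each). It emulates the *statistical structure* the analysis
assumes, not human gait in full:

* **Kinematics.** Shank and thigh angles ramp between template
  endpoints with small seeded harmonics (including a knee-flexion
  bump); trial duration is drawn from U(0.62, 0.78) s at 100 Hz. The
  whole-body COM follows a linear-inverted-pendulum (LIP) solution:
  the COP target runs on a line from ~10% to ~70% of foot length and
  the COM obeys `ẍ = ω²(x − u(t))` with `ω² = g/z`, entering stance
  behind the heel (braking) and leaving beyond the toe (propulsion).
  The HAT lean is solved pointwise to realise this COM path; its
  derivatives are frame-by-frame numerical, which is harmless because
  forward and inverse dynamics consume the same arrays.
* **Ground reactions.** AP/vertical GRF and AP COP come from the
  forward dynamics and are therefore exactly consistent with the
  stored ground-truth torques. ML GRF and ML COP are smooth seeded
  templates: the planar model cannot constrain them and they are
  declared non-dynamic (they also never enter torque computation).
* **Muscles.** A reduced set of 11 MTUs spans the three DoFs with the
  recorded/unrecorded structure of an 8-channel surface-EMG protocol:
  one channel may drive several MTUs (the two gastrocnemius heads
  share a channel) and two MTUs (iliopsoas, short biceps head) have no
  channel at all, exercising the synthesized-excitation path of the
  hybrid model. Ground-truth calibration parameters are drawn inside
  the calibration box, away from its edges.
* **Excitations and EMG.** Ground-truth excitations solve a
  frame-wise minimum-effort problem (min Σe² subject to the MTU
  torques matching the truth torques), with channel-sharing MTUs tied
  to one excitation and unrecorded MTUs held at zero drive (their
  passive force remains). This makes the recorded-channel EMG-driven
  model *complete* on noiseless data — the calibration recovery oracle
  is exact, with zero residual at the true parameters. Raw EMG is an
  amplitude-modulated band-limited Gaussian carrier at 1000 Hz
  (band 30–475 Hz, unit mean absolute value), so the standard
  envelope chain recovers the excitation up to smoothing error.
* **Noise.** Gaussian measurement noise on angles (0.003 rad), marker
  positions (2 mm), GRF (3 N), COP (2 mm) and the raw EMG carrier
  (2% of unit amplitude) — typical optical-capture/force-plate
  magnitudes. With all amplitudes zero the measured channels equal the
  truth channels exactly, which the oracle tests rely on.

What the generator does **not** emulate: heel rise and push-off foot
rotation (the stance foot is flat and stationary), double support,
frontal/transverse-plane mechanics, the characteristic double-bump
vertical GRF, realistic inter-subject kinematic style variation, EMG
crosstalk and motion artifacts. A green end-to-end test therefore
establishes that the *pipeline machinery* behaves as specified under
the stated world — not that the numerical torque accuracies would
match a human cohort.

Known realism limitation: minimum-effort recruitment leaves some
channels (knee extensors especially) barely active, and subject-global
peak normalisation then inflates those envelopes by more than the
strength coefficient's [0.5, 2] range can absorb. Calibration on noisy
cohorts consequently fits the strongly recruited channels and
saturates the weak ones — the same identifiability problem real
EMG-driven calibrations have with weakly recruited muscles.

## Signal processing

Markers/angles and force-plate channels: zero-lag (forward–backward)
second-order Butterworth low-pass at 8 Hz, reflective edge padding of
3× the filter order. "Order" names the one-pass design; zero-lag
application squares the magnitude response (≈ −6 dB at the cutoff).
EMG: 30 Hz high-pass, full-wave rectification, 6 Hz low-pass (both
4th-order zero-lag), then normalisation per channel to the peak over
all of a subject's trials. Derivatives are frame-by-frame (central
differences, one-sided at the ends). Stance phases are resampled to
100 samples by linear interpolation with exact endpoint preservation
(heel strike = 0%, toe-off = 100%). The pipeline applies the 8 Hz
filter *before* differentiating: double-differentiated raw marker
noise otherwise dominates every acceleration channel.

## NCA feature selection

With weighted L1 distance `d_w(x_i,x_j) = Σ_r w_r² |x_ir − x_jr|`,
neighbour probabilities `p_ij ∝ exp(−d_w/σ)`, expected leave-one-out
loss `l_i = Σ_j p_ij |y_i − y_j|`, the objective is
`F(w) = mean(l_i) + λ Σ_r w_r²`. The gradient is analytic and the fit
uses L-BFGS from all-ones weights (weights enter squared, so the
problem is unconstrained; the softmax is computed with row-wise
max-shifting for stability). Features with `w_r²` above 1% of the
maximum are selected (the squared weight is the quantity appearing in
the distance and the penalty, which resolves the w-vs-w² ambiguity of
the selection rule).

Defaults: σ = 1 and λ = 1/n after internal standardisation of the
features **and the response**. Standardising y is the package's own
choice: σ and λ are dimensionless, and the pipeline feeds targets in
%BW and in mm — without unit-free responses the effective
regularisation would differ per target by orders of magnitude (and the
decoy-exclusion behaviour degrades measurably).

## GRF/COP estimation networks

One network per target channel: single tanh hidden layer, linear
output, full-batch Levenberg–Marquardt with adaptive damping, and a
minimum-gradient stopping rule (default 1e-7 on the standardised-space
SSE gradient). LM has no classical learning rate; the tunable
"learning rate" maps to the *initial damping factor*, which plays the
same step-scaling role. Hyperparameters (2–20 neurons, rate 5e-4–1
log-scaled, 500–1000 epochs) are searched by seeded Bayesian
optimisation — Gaussian-process surrogate (Matérn 5/2), expected
improvement over 256 seeded candidates, random-search fallback if the
surrogate fit fails — minimising the worst-fold MSE of a seeded
five-fold cross-validation. Folds partition pooled *time samples*, not
trials: three training trials cannot form five trial-level folds. Near
equal-sized folds come from one seeded permutation.

## Hybrid EMG-informed model

Rigid-tendon Hill MTUs with zero pennation: fibre length
`l_m = l_mt − s·L_slack`, normalised by `o·L_opt`; force
`F = c·F_max·(a·f_l·f_v + f_p)` with a Gaussian active force–length
curve (width 0.45), a saturating force–velocity curve (zero at
maximal shortening 10 L_opt/s, eccentric plateau 1.5) and an
exponential passive curve that is zero below optimal length. The curve
constants are fixed; only the five per-MTU parameters in the
calibration box (slack and optimal-fibre scales, strength coefficient,
two activation-filter coefficients, shape factor) are tuned — the
slack/optimal bounds are read as multiplicative scales, matching their
dimensionless printed ranges. Excitation→activation: a unit-DC-gain
second-order recursive filter (poles −c1, −c2, steady-state
initialisation) followed by the exponential shape-factor
nonlinearisation with the A→0 limit handled exactly.

Calibration minimises the summed squared torque-tracking error over
three trials with a bounded trust-region least-squares solver; the
residual evaluation is fully vectorised over (trial, MTU) and the
block sparsity of the Jacobian (an MTU's parameters only touch the
joints it spans) is exploited for grouped finite differences.

The hybrid solve minimises, frame by frame over all MTU excitations
in [0,1], `E_trackMOM + β·E_sumEXC + γ·E_trackEMG` (α fixed at 1),
with activation history propagated using the adjusted excitations of
previous frames. The L1 EMG term is handled exactly with slack
variables inside SLSQP; each frame additionally scores an
exact-pinning candidate (optimal in the γ-dominated limit, where
SLSQP becomes stiff) and, in the tracking-dominated or failed case, a
bounded Gauss–Newton polish of the torque residual. Targets beyond
muscle capacity leave a saturated residual rather than an exception.
β/γ default to (1, 2); `tune_beta_gamma` implements the grid rule —
minimise the min–max-normalised sum of E_trackMOM and E_trackEMG —
which is one reading of the underdetermined "both reach the minimum"
criterion.

Per-condition, model N tracks the inverse-dynamics torques computed
from *that condition's* GRF/COP inputs; the reference ("measured")
torques always come from the fully measured pipeline.

## Evaluation and statistics

R² is `1 − SS_res/SS_tot` about the measured mean (not a squared
correlation; it may be negative — the knee, whose torque variance is
small in this world, shows this readily). RMSE is reported in Nm/kg
after body-mass normalisation and 100-sample phase resampling. The
Friedman test uses within-block mid-ranks with tie correction;
Dunn–Bonferroni post-hocs build z statistics from mean ranks and
multiply two-sided normal p values by the number of comparisons
(capped at 1). Within-subject blocks are trials; the between-subject
variant blocks subjects on trial means. The parametric ANOVA branch is
deliberately absent. Statistics on synthetic subjects are labelled
illustrative in the report output.

## Reduced-budget profile and runtime

`PipelineConfig.reduced()` keeps the protocol identical but coarsens
optimisation budgets for desk-scale sweeps: NCA iteration cap 40,
tuning budget 10 (the floor), LM minimum gradient 1e-2, sample stride
2 for selection/tuning, calibration capped at 15 residual evaluations,
and estimated targets restricted to the three channels the planar
inverse dynamics consumes (AP/V GRF, AP COP — the ML channels never
enter torque computation). With this profile a full 5-subject × 4-trial
cohort under EGEC with both models runs in roughly a minute.

## Degenerate inputs and ties

Zero-variance features and responses get unit scales instead of
division by zero; an all-zero EMG channel is an error naming the
channel; constant targets are fitted by the network bias exactly;
complete ties make the Friedman statistic 0 with p = 1; a COP outside
the plausible foot band warns but is not clamped (late-stance COP
beyond the toe is physiological).
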