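# gaitkinetics

Sagittal lower-limb joint-torque prediction during walking **without
force plates**: ground reaction forces (GRF) and centres of pressure
(COP) are estimated statistically from motion and EMG features, then
fed into biomechanical models, and the resulting torque errors are
quantified joint by joint.

The package is aimed at movement-science and rehabilitation-engineering
researchers who want to study how GRF/COP estimation error propagates
through inverse dynamics and EMG-informed neuromusculoskeletal
modelling — at desk scale, with exact oracles, and with no external
dataset: a seeded synthetic stance-phase generator stands in for a
motion-capture/force-plate/EMG cohort.

## What it implements

**Feature selection.** Regression neighbourhood component analysis:
with weighted distance `d_w(x_i,x_j) = Σ_r w_r²|x_ir − x_jr|` and
neighbour probabilities `p_ij ∝ exp(−d_w/σ)`, the weights minimise the
expected leave-one-out loss plus an L2 penalty,

    F(w) = 1/n Σ_i Σ_{j≠i} p_ij |y_i − y_j| + λ Σ_r w_r² ,

with an analytic gradient; features with `w_r²` above 1% of the
maximum are kept (`NcaFeatureSelector`, scikit-learn compatible).

**GRF/COP regression.** One single-hidden-layer tanh network per
channel (AP/ML/V GRF in %BW; AP/ML COP in mm relative to the heel),
trained by full-batch Levenberg–Marquardt with minimum-gradient
stopping; hyperparameters (2–20 neurons, learning rate 5e-4–1,
500–1000 epochs) are tuned by seeded Bayesian optimisation of the
worst-fold objective of a five-fold cross-validation,

    F_obj = max_k ( Σ_n (y_est,k − y_true,k)² / N_k ).

**Torque models.** (M) planar distal-to-proximal Newton–Euler inverse
dynamics of the stance leg (foot–shank–thigh plus a trunk lump), and
(N) a hybrid EMG-informed model: calibrated rigid-tendon Hill-type
musculotendon units driven by EMG envelopes, with a per-frame static
optimisation over all excitations `e ∈ [0,1]`,

    F = E_trackMOM + β·E_sumEXC + γ·E_trackEMG ,

which tracks the inverse-dynamics torques, penalises total effort, and
keeps recorded excitations close to their envelopes while synthesising
the unrecorded ones.

**Evaluation.** Conditions crossing estimated/measured GRF and COP
(EGEC, EGMC, MGEC) with both models; R² and RMSE (Nm/kg) on
body-mass-normalised torques resampled to 100 stance samples; Friedman
and Dunn–Bonferroni nonparametric statistics.

## Worked example

```python
import numpy as np
from gaitkinetics import (NoiseConfig, generate_subject, generate_subject_trials,
                          PipelineConfig, preprocess_trial, estimate_ground_reaction,
                          run_condition, ConditionLabel, fit_metrics)
from gaitkinetics.pipeline import calibrate_subject, target_series

subject = generate_subject(seed=11)
trials = [preprocess_trial(t) for t in
          generate_subject_trials(subject, 4, NoiseConfig(), base_trial_seed=50)]
cfg = PipelineConfig.reduced()

# leave-one-trial-out: estimate trial 0's ground reactions from its
# motion/EMG features using models trained on trials 1-3
estimates, info = estimate_ground_reaction(trials[0], trials[1:], cfg, seed=0)
for target, series in estimates.items():
    r2, rmse = fit_metrics(target_series(trials[0], target), series)
    print(target, round(r2, 3), round(rmse, 2))

# torque prediction under the estimated-GRF/estimated-COP condition
params, _ = calibrate_subject(subject, trials, 0, cfg, seed=0)
for cond in (ConditionLabel("estimated", "estimated", "M"),
             ConditionLabel("estimated", "estimated", "N")):
    results = run_condition(subject, trials[0], 0, cond, estimates, params, cfg)
    print(cond.name, [(r.joint, round(r.rmse, 3)) for r in results])
```

prints (seeds as above):

```
subject: 59.5 kg, 1.70 m, 11 MTUs (2 without EMG)
grf_ap: R2 = 0.881, RMSE = 1.35 %BW (14 features selected)
grf_v: R2 = 0.478, RMSE = 1.49 %BW (17 features selected)
cop_ap: R2 = 0.977, RMSE = 5.85 mm (17 features selected)
EGEC-M  hip: RMSE 0.121 Nm/kg (R2 0.47), knee: RMSE 0.076 Nm/kg (R2 0.50), ankle: RMSE 0.055 Nm/kg (R2 0.98)
EGEC-N  hip: RMSE 0.121 Nm/kg (R2 0.47), knee: RMSE 0.076 Nm/kg (R2 0.50), ankle: RMSE 0.156 Nm/kg (R2 0.83)
```

Reading this: the AP COP is recovered to ~6 mm and the AP force to
~1.4 %BW from motion/EMG features alone; propagated through inverse
dynamics, the residual estimation error costs ~0.12 Nm/kg at the hip
but only ~0.06 Nm/kg at the ankle — the hip is the joint most
sensitive to ground-reaction estimation error, because the foot is
solved first and force errors act on ever longer levers up the
recursion chain. The hybrid model (N) tracks the same inverse-dynamics
targets while staying close to the measured EMG.

A command-line layer wraps the same pipeline
(`gaitkinetics simulate|estimate|torques|evaluate|report`, driven by a
YAML config); trials serialise to HDF5 and flat CSV.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it generates a seeded synthetic cohort, runs the full
leave-one-trial-out pipeline (NCA selection → network tuning and
estimation → muscle calibration → all six condition × model cells),
prints the condition summary tables, and writes the JSON results map:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the
synthetic world and its limitations, and every numerical choice
(tolerances, initialisation, tie-breaking, degenerate inputs).
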