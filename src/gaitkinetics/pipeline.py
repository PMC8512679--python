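"""End-to-end orchestration: estimation protocol, conditions, cohort study.

For every subject the protocol is intrasubject and leave-one-trial-out:
each trial is tested in turn with the other three as training data.
Per test case and per target channel (AP/ML/V GRF in %BW, AP/ML COP in
mm), features are selected by NCA on the pooled training samples, the
network hyperparameters are tuned by Bayesian optimisation of the
worst-fold five-fold CV objective, a final network is trained on all
training samples, and the test trial is predicted from its motion and
EMG channels only -- the test trial's force-plate channels are never
read by the estimator.

Torque prediction then crosses the estimated/measured GRF and COP
sources (conditions EGEC, EGMC, MGEC) with model M (planar inverse
dynamics) and model N (hybrid EMG-informed model tracking that
condition's inverse-dynamics torques).  Muscle parameters are
calibrated on the three training trials with fully measured data and
reused across all conditions of that test case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import signal as sig
from .ann import tune_hyperparameters, train_ann
from .dynamics import inverse_dynamics
from .evaluation import CONDITIONS, ConditionLabel, ConditionResult
from .muscle import (
    HybridWeights,
    calibrate,
    expand_channel_excitations,
    hybrid_solve,
    tune_beta_gamma,
)
from .nca import NcaFeatureSelector
from .synthetic import (
    EMG_CHANNELS,
    JOINTS,
    StanceTrial,
    SubjectModel,
    kinematics_from_arrays,
)

__all__ = [
    "TARGETS",
    "PipelineConfig",
    "preprocess_trial",
    "feature_matrix",
    "target_series",
    "estimate_ground_reaction",
    "calibrate_subject",
    "run_condition",
    "run_subject_study",
    "run_cohort_study",
]

#: Estimated channels: GRF in %BW, COP in mm (heel-referenced).
TARGETS = ("grf_ap", "grf_ml", "grf_v", "cop_ap", "cop_ml")

_GRF_ROW = {"grf_ap": 0, "grf_ml": 1, "grf_v": 2}
_COP_ROW = {"cop_ap": 0, "cop_ml": 1}


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the full study pipeline.

    ``reduced()`` returns a configuration with coarse optimisation
    budgets (smaller tuning budget, looser LM stopping gradient,
    sample stride 2, capped calibration evaluations) for desk-scale
    cohort sweeps; the protocol itself is unchanged.
    """

    nca_sigma: float = 1.0
    nca_lambda: float | str = "auto"
    nca_fraction: float = 0.01
    nca_max_iter: int = 150
    tune_budget: int = 30
    cv_folds: int = 5
    ann_min_grad: float = 1e-7
    sample_stride: int = 1          # training-sample subsampling for NCA/tuning
    hybrid_weights: HybridWeights = field(default_factory=lambda: HybridWeights(beta=1.0, gamma=2.0))
    tune_hybrid: bool = False
    hybrid_grid: tuple = ((0.1, 1.0), (1.0, 2.0), (1.0, 10.0))
    calibration_max_nfev: int | None = None
    targets: tuple = TARGETS

    @staticmethod
    def reduced() -> "PipelineConfig":
        return PipelineConfig(
            nca_max_iter=40, tune_budget=10, ann_min_grad=1e-2,
            sample_stride=2, calibration_max_nfev=15,
            targets=("grf_ap", "grf_v", "cop_ap"),
        )


# ---------------------------------------------------------------------------
# preprocessing, features and targets
# ---------------------------------------------------------------------------

def preprocess_trial(trial: StanceTrial) -> StanceTrial:
    """Standard measurement preprocessing before any model sees a trial.

    Joint angles, joint-centre/heel trajectories and force-plate
    channels (GRF and COP) pass through the 8 Hz zero-lag second-order
    Butterworth low-pass; velocities and accelerations are re-derived
    by frame-by-frame differentiation of the filtered positions.
    Without this step the double-differentiated channels are dominated
    by measurement noise.  EMG envelopes are left untouched (their own
    chain ran already).
    """
    fs = trial.fs

    def lp(x):
        return sig.butterworth_zero_lag(x, fs, sig.MARKER_FILTER)

    theta = {j: lp(v) for j, v in trial.theta.items()}
    omega = {j: sig.differentiate(theta[j], fs) for j in theta}
    alpha = {j: sig.differentiate(omega[j], fs) for j in theta}
    jc = {}
    for j, d in trial.joint_centres.items():
        pos = np.stack([lp(d["pos"][:, i]) for i in range(2)], axis=-1)
        vel = np.stack([sig.differentiate(pos[:, i], fs) for i in range(2)], axis=-1)
        acc = np.stack([sig.differentiate(vel[:, i], fs) for i in range(2)], axis=-1)
        jc[j] = {"pos": pos, "vel": vel, "acc": acc}
    heel = np.stack([lp(trial.heel_pos[:, i]) for i in range(2)], axis=-1)
    grf = np.stack([lp(row) for row in trial.grf])
    grf[2] = np.clip(grf[2], 0.0, None)
    cop = np.stack([lp(row) for row in trial.cop])
    return StanceTrial(
        fs=fs, t=trial.t, theta=theta, omega=omega, alpha_ang=alpha,
        joint_centres=jc, heel_pos=heel, emg_raw=trial.emg_raw,
        emg_env=trial.emg_env, grf=grf, cop=cop, mass=trial.mass,
        bw=trial.bw, seed=trial.seed, truth=trial.truth,
    )


def feature_matrix(trial: StanceTrial) -> tuple[np.ndarray, list[str]]:
    """Candidate features per time sample: angles, linear and angular
    velocity/acceleration, joint-centre and heel kinematics, EMG envelopes.

    Force-plate channels are deliberately absent.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for j in JOINTS:
        for block, label in ((trial.theta, "angle"), (trial.omega, "angvel"),
                             (trial.alpha_ang, "angacc")):
            cols.append(block[j])
            names.append(f"{j}_{label}")
    for j in JOINTS:
        for key in ("pos", "vel", "acc"):
            arr = trial.joint_centres[j][key]
            for ax, axname in enumerate(("x", "y")):
                cols.append(arr[:, ax])
                names.append(f"{j}_{key}_{axname}")
    for ax, axname in enumerate(("x", "y")):
        cols.append(trial.heel_pos[:, ax])
        names.append(f"heel_pos_{axname}")
    for ci, ch in enumerate(EMG_CHANNELS):
        cols.append(trial.emg_env[ci])
        names.append(f"emg_{ch}")
    return np.column_stack(cols), names


def target_series(trial: StanceTrial, target: str) -> np.ndarray:
    """Measured target channel on the reporting scale (%BW or mm)."""
    if target in _GRF_ROW:
        return trial.grf[_GRF_ROW[target]] / trial.bw * 100.0
    if target in _COP_ROW:
        return trial.cop[_COP_ROW[target]]
    raise ValueError(f"unknown target channel {target!r}; expected one of {TARGETS}")


# ---------------------------------------------------------------------------
# GRF/COP estimation
# ---------------------------------------------------------------------------

def estimate_ground_reaction(
    test_trial: StanceTrial,
    train_trials: list[StanceTrial],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, dict]]:
    """Estimate the target channels of one held-out trial.

    Returns (per-target estimated series, per-target metadata with the
    selected features, tuned hyperparameters and CV objective).  The
    test trial contributes only its motion/EMG features; its GRF/COP
    channels are never accessed.
    """
    cfg = cfg or PipelineConfig()
    if any(t is test_trial for t in train_trials):
        raise ValueError("test trial must be excluded from the training trials")
    X_parts, names = [], None
    for t in train_trials:
        X_t, names = feature_matrix(t)
        X_parts.append(X_t)
    X_train_full = np.vstack(X_parts)
    X_test, _ = feature_matrix(test_trial)
    stride = max(1, cfg.sample_stride)

    estimates: dict[str, np.ndarray] = {}
    info: dict[str, dict] = {}
    for ti, target in enumerate(cfg.targets):
        t_seed = (seed * 1009 + ti * 101) % (2**31 - 1)
        y_train_full = np.concatenate([target_series(t, target) for t in train_trials])
        X_sub = X_train_full[::stride]
        y_sub = y_train_full[::stride]

        selector = NcaFeatureSelector(
            sigma=cfg.nca_sigma, lambda_reg=cfg.nca_lambda,
            fraction=cfg.nca_fraction, max_iter=cfg.nca_max_iter,
        ).fit(X_sub, y_sub)
        support = selector.get_support()

        hp, f_obj, log = tune_hyperparameters(
            X_sub[:, support], y_sub, budget=cfg.tune_budget, seed=t_seed,
            n_folds=cfg.cv_folds, min_grad=cfg.ann_min_grad,
        )
        model = train_ann(X_train_full[:, support], y_train_full, hp,
                          seed=t_seed, min_grad=cfg.ann_min_grad)
        estimates[target] = model.predict(X_test[:, support])
        info[target] = {
            "selected_features": [n for n, s in zip(names, support) if s],
            "hyperparameters": {"n_hidden": hp.n_hidden,
                                "learning_rate": hp.learning_rate,
                                "epochs": hp.epochs},
            "cv_objective": f_obj,
            "stop_reason": model.stop_reason_,
            "n_evaluations": len(log),
            "seed": t_seed,
        }
    return estimates, info


# ---------------------------------------------------------------------------
# torque computation per condition
# ---------------------------------------------------------------------------

def _trial_kinematics(trial: StanceTrial):
    return kinematics_from_arrays(
        trial.theta, trial.alpha_ang,
        ankle_pos=trial.joint_centres["ankle"]["pos"],
        fs=trial.fs, omega=trial.omega,
        ankle_vel=trial.joint_centres["ankle"]["vel"],
        ankle_acc=trial.joint_centres["ankle"]["acc"],
    )


def measured_torques(subject: SubjectModel, trial: StanceTrial) -> dict[str, np.ndarray]:
    """Reference joint torques: inverse dynamics from the measured channels (Nm)."""
    kin = _trial_kinematics(trial)
    tq = inverse_dynamics(kin, trial.grf[0], trial.grf[2], trial.cop[0] / 1000.0,
                          subject.segment_params)
    return {"hip": tq.tau_hip, "knee": tq.tau_knee, "ankle": tq.tau_ankle}


def calibrate_subject(
    subject: SubjectModel,
    trials: list[StanceTrial],
    exclude_idx: int,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
):
    """Calibrate MTU parameters on the trials other than ``exclude_idx``.

    Uses measured torques (inverse dynamics of measured GRF/COP) as
    tracking targets and the measured EMG envelopes as excitations.
    """
    cfg = cfg or PipelineConfig()
    cal_trials, cal_torques = [], []
    for i, trial in enumerate(trials):
        if i == exclude_idx:
            continue
        envelopes = {ch: trial.emg_env[ci] for ci, ch in enumerate(EMG_CHANNELS)}
        exc = expand_channel_excitations(envelopes, subject.emg_channel_map,
                                         subject.mtu_labels)
        cal_trials.append({"thetas": trial.theta, "omegas": trial.omega,
                           "excitations": exc})
        cal_torques.append(measured_torques(subject, trial))
    params, cal_info = calibrate(
        subject.mtu_set, cal_trials, cal_torques, seed=seed,
        max_nfev=cfg.calibration_max_nfev,
    )
    return params, cal_info


def _condition_inputs(trial: StanceTrial, condition: ConditionLabel,
                      estimates: dict[str, np.ndarray] | None):
    """(grf_ap N, grf_v N, cop_ap m) for the requested condition sources."""
    if condition.grf_source == "measured":
        grf_ap, grf_v = trial.grf[0], trial.grf[2]
    else:
        grf_ap = estimates["grf_ap"] * trial.bw / 100.0
        grf_v = np.clip(estimates["grf_v"] * trial.bw / 100.0, 0.0, None)
    if condition.cop_source == "measured":
        cop_ap = trial.cop[0] / 1000.0
    else:
        cop_ap = estimates["cop_ap"] / 1000.0
    return grf_ap, grf_v, cop_ap


def run_condition(
    subject: SubjectModel,
    trial: StanceTrial,
    trial_index: int,
    condition: ConditionLabel,
    estimates: dict[str, np.ndarray] | None,
    mtu_params,
    cfg: PipelineConfig | None = None,
    weights: HybridWeights | None = None,
) -> list[ConditionResult]:
    """Torque prediction and metrics for one trial under one condition.

    Model M runs inverse dynamics on the condition's GRF/COP inputs;
    model N runs the hybrid solver tracking those inverse-dynamics
    torques.  The reference is always the fully measured pipeline.
    Torques are body-mass normalised and resampled to 100 stance
    samples before computing metrics.
    """
    cfg = cfg or PipelineConfig()
    needs_estimates = "estimated" in (condition.grf_source, condition.cop_source)
    if needs_estimates:
        if estimates is None:
            raise ValueError(f"condition {condition.name} requires estimates")
        needed = set()
        if condition.grf_source == "estimated":
            needed |= {"grf_ap", "grf_v"}
        if condition.cop_source == "estimated":
            needed |= {"cop_ap"}
        missing = needed - set(estimates)
        if missing:
            raise ValueError(
                f"condition {condition.name} missing estimate channel(s) {sorted(missing)}"
            )
    ref = measured_torques(subject, trial)
    grf_ap, grf_v, cop_ap = _condition_inputs(trial, condition, estimates)
    kin = _trial_kinematics(trial)
    tq = inverse_dynamics(kin, grf_ap, grf_v, cop_ap, subject.segment_params)
    cond_id = {"hip": tq.tau_hip, "knee": tq.tau_knee, "ankle": tq.tau_ankle}

    if condition.model == "M":
        pred = cond_id
    else:
        if mtu_params is None:
            raise ValueError("model N requires calibrated MTU parameters")
        envelopes = {ch: trial.emg_env[ci] for ci, ch in enumerate(EMG_CHANNELS)}
        exp_exc = {}
        for ch, labs in subject.emg_channel_map.items():
            for lab in labs:
                exp_exc[lab] = envelopes[ch]
        _, pred, _ = hybrid_solve(
            trial.theta, trial.omega, subject.mtu_set, mtu_params,
            cond_id, weights or cfg.hybrid_weights, exp_exc,
        )

    out = []
    for joint in JOINTS:
        out.append(ConditionResult(
            subject=subject.subject_id, trial=trial_index, joint=joint,
            condition=condition,
            torque_pred=sig.resample_stance(pred[joint] / subject.mass),
            torque_meas=sig.resample_stance(ref[joint] / subject.mass),
        ))
    return out


def run_subject_study(
    subject: SubjectModel,
    trials: list[StanceTrial],
    cfg: PipelineConfig | None = None,
    conditions: tuple[ConditionLabel, ...] = CONDITIONS,
    seed: int = 0,
) -> list[ConditionResult]:
    """Leave-one-trial-out study of one subject over the given conditions."""
    cfg = cfg or PipelineConfig()
    trials = [preprocess_trial(t) for t in trials]
    results: list[ConditionResult] = []
    needs_n = any(c.model == "N" for c in conditions)
    needs_est = any("estimated" in (c.grf_source, c.cop_source) for c in conditions)
    for test_idx, test_trial in enumerate(trials):
        train = [t for i, t in enumerate(trials) if i != test_idx]
        estimates = None
        if needs_est:
            estimates, _ = estimate_ground_reaction(
                test_trial, train, cfg, seed=seed * 31 + test_idx)
        params, weights = None, cfg.hybrid_weights
        if needs_n:
            params, _ = calibrate_subject(subject, trials, test_idx, cfg,
                                          seed=seed * 31 + test_idx)
            if cfg.tune_hybrid:
                cal_idx = [i for i in range(len(trials)) if i != test_idx]

                def solve_candidate(w):
                    br_total = None
                    for i in cal_idx:
                        tr = trials[i]
                        envelopes = {ch: tr.emg_env[ci]
                                     for ci, ch in enumerate(EMG_CHANNELS)}
                        exp_exc = {lab: envelopes[ch]
                                   for ch, labs in subject.emg_channel_map.items()
                                   for lab in labs}
                        tgt = measured_torques(subject, tr)
                        _, _, br = hybrid_solve(
                            tr.theta, tr.omega, subject.mtu_set, params,
                            tgt, w, exp_exc)
                        if br_total is None:
                            br_total = br
                        else:
                            br_total.e_track_mom += br.e_track_mom
                            br_total.e_track_emg += br.e_track_emg
                            br_total.e_sum_exc += br.e_sum_exc
                    return br_total

                weights, _ = tune_beta_gamma(solve_candidate, list(cfg.hybrid_grid))
        for condition in conditions:
            results.extend(run_condition(
                subject, test_trial, test_idx, condition, estimates, params,
                cfg, weights))
    return results


def egec_hip_ankle_rmse(
    cohort_seed: int,
    cfg: PipelineConfig | None = None,
    n_subjects: int = 5,
    n_trials: int = 4,
) -> dict[tuple[str, str], float]:
    """Mean torque RMSE per joint x model under the EGEC condition.

    Runs the default synthetic cohort (default noise) through the
    estimated-GRF/estimated-COP condition with both models and returns
    ``{(joint, model): mean RMSE in Nm/kg}`` — the quantity behind the
    qualitative finding that the hip is the most sensitive and the
    ankle the most resistant joint to ground-reaction estimation error.
    """
    from .synthetic import NoiseConfig, generate_cohort

    cohort = generate_cohort(n_subjects, n_trials, seed=cohort_seed,
                             noise_cfg=NoiseConfig())
    conds = (ConditionLabel("estimated", "estimated", "M"),
             ConditionLabel("estimated", "estimated", "N"))
    results = run_cohort_study(cohort, cfg or PipelineConfig.reduced(), conds,
                               seed=cohort_seed)
    out: dict[tuple[str, str], float] = {}
    for model in ("M", "N"):
        for joint in JOINTS:
            vals = [r.rmse for r in results
                    if r.joint == joint and r.condition.model == model]
            out[(joint, model)] = float(np.mean(vals))
    return out


def run_cohort_study(
    cohort,
    cfg: PipelineConfig | None = None,
    conditions: tuple[ConditionLabel, ...] = CONDITIONS,
    seed: int = 0,
) -> list[ConditionResult]:
    """Run the subject study over a whole cohort of (subject, trials) pairs."""
    results: list[ConditionResult] = []
    for si, (subject, trials) in enumerate(cohort):
        results.extend(run_subject_study(subject, trials, cfg, conditions,
                                         seed=seed * 127 + si))
    return results
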