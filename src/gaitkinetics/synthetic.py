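"""Seeded synthetic subjects and dynamically consistent stance-phase trials.

The generator emulates the statistical structure the torque-prediction
pipeline assumes, at desk scale and with exact oracles:

* smooth sagittal joint kinematics from analytic templates (so angular
  velocities and accelerations are exact derivatives, not numerical);
* AP/vertical GRF and AP COP synthesised by the planar whole-body
  dynamics, so inverse dynamics on the noiseless channels reproduces
  the stored ground-truth torques to machine precision;
* ML GRF and ML COP as smooth seeded templates -- the planar model
  does not constrain them, and they are declared non-dynamic;
* per-MTU excitations obtained by frame-wise minimum-effort static
  optimisation that reproduces the ground-truth torques, with raw EMG
  synthesised as an amplitude-modulated band-limited carrier whose
  envelope-processing chain recovers the excitation;
* configurable measurement noise on every measured channel; with all
  noise amplitudes at zero the measured channels equal the truth
  channels exactly.

The stance foot is modelled flat and stationary (no heel rise), and
the HAT lump absorbs trunk, arms, head and the swing leg; these are
deliberate simplifications that buy an exact forward/inverse oracle.
The trial starts at heel strike and ends at toe-off by construction.

The minimum-effort solver assigns zero neural drive to the MTUs that
have no recorded EMG channel (their passive force still contributes),
so the recorded-channel EMG-driven model is complete on noiseless
data; the hybrid solver may still synthesise their excitations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize

from . import signal as sig
from .dynamics import (
    PlanarStanceKinematics,
    SegmentParams,
    forward_ground_reaction,
    hat_reference_hip_torque,
    inverse_dynamics,
    segment_parameters,
)
from .muscle import (
    MtuGeometry,
    MtuParams,
    mtu_state,
    _force_length,
    _force_velocity,
    _force_passive,
    _filter_coeffs,
    _VMAX_LOPT,
)

__all__ = [
    "SubjectModel",
    "StanceTrial",
    "NoiseConfig",
    "DEFAULT_ANTHROPOMETRY_RANGES",
    "generate_subject",
    "generate_stance_trial",
    "generate_subject_trials",
    "generate_cohort",
    "excitations_from_torques",
    "synthesize_raw_emg",
    "kinematics_from_arrays",
]

JOINTS = ("hip", "knee", "ankle")

#: EMG channels recorded in the emulated protocol (8 surface channels).
EMG_CHANNELS = (
    "soleus",
    "tibialis_anterior",
    "gastrocnemius_medialis",
    "rectus_femoris",
    "vastus_medialis",
    "semitendinosus",
    "gluteus_maximus",
    "gluteus_medius",
)

# Reduced sagittal MTU set: label -> (channel or None, F_max N,
# optimal fibre m, tendon slack m, {joint: nominal moment arm m,
# positive = extensor/plantarflexor}).  One recorded channel may drive
# several MTUs (the two gastrocnemius heads share a channel); the
# iliopsoas and the short head of biceps femoris have no channel and
# exercise the synthesized-excitation path.
_MTU_TABLE: dict[str, tuple[str | None, float, float, float, dict[str, float]]] = {
    "soleus": ("soleus", 2800.0, 0.08, 0.22, {"ankle": 0.050}),
    "tib_ant": ("tibialis_anterior", 850.0, 0.09, 0.18, {"ankle": -0.040}),
    "med_gas": ("gastrocnemius_medialis", 1500.0, 0.09, 0.36, {"ankle": 0.048, "knee": -0.030}),
    "lat_gas": ("gastrocnemius_medialis", 900.0, 0.09, 0.36, {"ankle": 0.045, "knee": -0.028}),
    "rect_fem": ("rectus_femoris", 1700.0, 0.11, 0.30, {"knee": 0.045, "hip": -0.050}),
    "vasti": ("vastus_medialis", 3150.0, 0.10, 0.16, {"knee": 0.048}),
    "semiten": ("semitendinosus", 1550.0, 0.13, 0.26, {"knee": -0.035, "hip": 0.054}),
    "glut_max": ("gluteus_maximus", 2250.0, 0.15, 0.12, {"hip": 0.054}),
    "glut_med": ("gluteus_medius", 850.0, 0.08, 0.08, {"hip": 0.030}),
    "iliopsoas": (None, 1550.0, 0.11, 0.12, {"hip": -0.045}),
    "bifemsh": (None, 630.0, 0.16, 0.10, {"knee": -0.035}),
}

DEFAULT_ANTHROPOMETRY_RANGES = {"mass": (55.0, 90.0), "height": (1.55, 1.85)}

# ground-truth parameter draw (inside the calibration box, away from edges)
_TRUTH_PARAM_RANGES = {
    "tendon_slack_scale": (0.97, 1.03),
    "optimal_fibre_scale": (0.985, 1.015),
    "strength_coeff": (0.8, 1.4),
    "c1": (-0.5, -0.05),
    "c2": (-0.5, -0.05),
    "shape_factor": (-3.0, -0.5),
}


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise amplitudes; all zero means measured == truth."""

    angle_sd: float = 0.003      # rad, on joint angles
    marker_sd: float = 0.002     # m, on joint-centre and heel positions
    grf_sd: float = 3.0          # N, on each GRF component
    cop_sd: float = 2.0          # mm, on each COP component
    emg_sd: float = 0.02         # fraction of the raw-EMG carrier amplitude

    def __post_init__(self) -> None:
        for name in ("angle_sd", "marker_sd", "grf_sd", "cop_sd", "emg_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise amplitude {name} must be >= 0")

    @property
    def silent(self) -> bool:
        return all(
            getattr(self, k) == 0
            for k in ("angle_sd", "marker_sd", "grf_sd", "cop_sd", "emg_sd")
        )

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(*(getattr(self, k) * factor for k in
                             ("angle_sd", "marker_sd", "grf_sd", "cop_sd", "emg_sd")))


@dataclass
class SubjectModel:
    """A synthetic subject: anthropometry, MTU set and ground-truth parameters."""

    subject_id: str
    mass: float      # kg
    height: float    # m
    seed: int
    segment_params: SegmentParams
    mtu_set: list[MtuGeometry]
    truth_params: dict[str, MtuParams]
    emg_channel_map: dict[str, list[str]]
    channels: tuple[str, ...] = EMG_CHANNELS

    @property
    def bw(self) -> float:
        """Body weight, N."""
        return self.mass * self.segment_params.g

    @property
    def mtu_labels(self) -> list[str]:
        return [g.label for g in self.mtu_set]

    def unrecorded_mtus(self) -> list[str]:
        return [g.label for g in self.mtu_set if g.recorded_channel is None]

    def serialise(self) -> str:
        """Deterministic JSON serialisation (identical for identical seeds)."""
        payload = {
            "subject_id": self.subject_id,
            "mass": self.mass,
            "height": self.height,
            "seed": self.seed,
            "mtu_set": [asdict(g) for g in self.mtu_set],
            "truth_params": {k: asdict(v) for k, v in self.truth_params.items()},
            "emg_channel_map": self.emg_channel_map,
            "channels": list(self.channels),
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class StanceTrial:
    """One stance phase: measured channels plus an optional truth block.

    Angles in rad, positions in m, GRF in N (rows AP, ML, V), COP in
    mm relative to the heel (rows AP, ML), EMG envelopes in [0, 1].
    """

    fs: float
    t: np.ndarray
    theta: dict[str, np.ndarray]
    omega: dict[str, np.ndarray]
    alpha_ang: dict[str, np.ndarray]
    joint_centres: dict[str, dict[str, np.ndarray]]  # joint -> {pos, vel, acc}, (n, 2)
    heel_pos: np.ndarray          # (n, 2)
    emg_raw: np.ndarray           # (8, n_emg) at fs_emg (raw EMG runs at its own rate)
    emg_env: np.ndarray           # (8, n), envelopes on the kinematic grid
    grf: np.ndarray               # (3, n): AP, ML, V
    cop: np.ndarray               # (2, n): AP, ML, mm heel-referenced
    mass: float
    bw: float
    fs_emg: float = 1000.0
    seed: int = 0
    truth: dict | None = None

    @property
    def n(self) -> int:
        return len(self.t)

    def channel_index(self, channel: str) -> int:
        return EMG_CHANNELS.index(channel)


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------

def generate_subject(
    seed: int,
    anthropometry_ranges: dict | None = None,
    subject_id: str | None = None,
) -> SubjectModel:
    """Draw a synthetic subject deterministically from ``seed``.

    Ground-truth MTU parameters are drawn inside the calibration box;
    geometry coefficients are drawn so that every moment arm stays in
    a 5-60 mm band over the motion range.
    """
    ranges = dict(DEFAULT_ANTHROPOMETRY_RANGES)
    if anthropometry_ranges:
        ranges.update(anthropometry_ranges)
    for key in ("mass", "height"):
        lo, hi = ranges[key]
        if not (0 < lo < hi):
            raise ValueError(f"degenerate anthropometry range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    mass = float(rng.uniform(*ranges["mass"]))
    height = float(rng.uniform(*ranges["height"]))
    seg = segment_parameters(mass, height)

    mtu_set: list[MtuGeometry] = []
    channel_map: dict[str, list[str]] = {ch: [] for ch in EMG_CHANNELS}
    for label, (channel, fmax, l_opt, l_slack, arms) in _MTU_TABLE.items():
        dof_coeffs: dict[str, tuple[float, float]] = {}
        for joint, r_nom in arms.items():
            r0 = float(np.clip(r_nom * rng.uniform(0.9, 1.1), -0.056, 0.056))
            if abs(r0) < 0.009:
                r0 = np.sign(r_nom) * 0.009
            k2 = float(rng.uniform(-0.004, 0.004))
            dof_coeffs[joint] = (-r0, k2)
        mtu_set.append(
            MtuGeometry(
                label=label,
                l0=l_slack + l_opt,
                base_optimal_fibre=l_opt,
                base_tendon_slack=l_slack,
                max_isometric_force=fmax * float(rng.uniform(0.9, 1.1)),
                dof_coeffs=dof_coeffs,
                recorded_channel=channel,
            )
        )
        if channel is not None:
            channel_map[channel].append(label)

    truth_params = {}
    for g in mtu_set:
        vals = {k: float(rng.uniform(*_TRUTH_PARAM_RANGES[k])) for k in _TRUTH_PARAM_RANGES}
        truth_params[g.label] = MtuParams(**vals)

    return SubjectModel(
        subject_id=subject_id or f"S{seed:04d}",
        mass=mass,
        height=height,
        seed=seed,
        segment_params=seg,
        mtu_set=mtu_set,
        truth_params=truth_params,
        emg_channel_map=channel_map,
    )


# ---------------------------------------------------------------------------
# kinematic templates
# ---------------------------------------------------------------------------

class _AngleTemplate:
    """phi(s) = start + sweep * s + sum_k c_k sin(k pi s), analytic derivatives.

    The linear ramp keeps template angular accelerations small (only
    the low-amplitude harmonics accelerate), so the synthesised COP
    stays close to the quasi-static whole-body COM path and inside the
    foot.
    """

    def __init__(self, start: float, end: float, harmonics: dict[int, float]):
        self.start = start
        self.sweep = end - start
        self.harmonics = harmonics

    def __call__(self, s: np.ndarray, duration: float):
        phi = self.start + self.sweep * s
        d1 = np.full_like(s, self.sweep)
        d2 = np.zeros_like(s)
        for k, c in self.harmonics.items():
            w = k * np.pi
            phi = phi + c * np.sin(w * s)
            d1 = d1 + c * w * np.cos(w * s)
            d2 = d2 - c * w**2 * np.sin(w * s)
        return phi, d1 / duration, d2 / duration**2


def _hat_com_for_target(
    seg: SegmentParams, phi_s: np.ndarray, phi_t: np.ndarray, com_target_x: np.ndarray
):
    """HAT-COM x and hip x that place the whole-body COM at ``com_target_x``."""
    ankle_x = seg.ankle_offset[0]
    knee_x = ankle_x + seg.lengths["shank"] * np.sin(phi_s)
    hip_x = knee_x + seg.lengths["thigh"] * np.sin(phi_t)
    m = seg.masses
    leg_com = (
        m["foot"] * seg.foot_com_offset[0]
        + m["shank"] * (ankle_x + seg.com_from_distal["shank"] * seg.lengths["shank"] * np.sin(phi_s))
        + m["thigh"] * (knee_x + seg.com_from_distal["thigh"] * seg.lengths["thigh"] * np.sin(phi_t))
    )
    c_hat_x = (seg.total_mass * com_target_x - leg_com) / m["hat"]
    return c_hat_x, hip_x


def _stance_kinematics(
    subject: SubjectModel, rng: np.random.Generator, speed_scale: float
) -> PlanarStanceKinematics:
    """Seeded perturbation of the template stance-leg motion."""
    seg = subject.segment_params
    duration = float(rng.uniform(0.62, 0.78)) / speed_scale
    fs = 100.0
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    s = t / t[-1]

    def wiggle(scale: float) -> dict[int, float]:
        return {2: float(rng.uniform(-scale, scale)), 3: float(rng.uniform(-scale, scale))}

    sweep = speed_scale
    shank_ends = (-0.10 * sweep, 0.32 * sweep)
    thigh_ends = (-0.18 * sweep, 0.22 * sweep)
    shank = _AngleTemplate(*shank_ends, wiggle(0.006))
    thigh_h = wiggle(0.006)
    thigh_h[1] = thigh_h.get(1, 0.0) - (0.10 + float(rng.uniform(-0.02, 0.02)))  # knee-flexion bump
    thigh = _AngleTemplate(*thigh_ends, thigh_h)
    phi_s, dphi_s, ddphi_s = shank(s, duration)
    phi_t, dphi_t, ddphi_t = thigh(s, duration)

    # Whole-body COM follows a linear-inverted-pendulum (LIP) solution:
    # the COP target runs on a line through the foot and the COM obeys
    # x'' = omega^2 (x - u(t)) with omega^2 = g / z_com, entering stance
    # behind the heel (braking) and leaving beyond the toe (propulsion).
    # This reproduces the classic braking-then-propulsion AP ground
    # reaction profile while the computed COP stays inside the foot.
    foot_len = seg.lengths["foot"]
    # pendulum height = trunk-COM height (~0.80 stature), where the
    # horizontally accelerated mass effectively sits
    omega_lip = np.sqrt(seg.g / (0.80 * seg.hat_com_dist / 0.30))
    u0 = (0.10 + float(rng.uniform(-0.01, 0.01))) * foot_len
    u1 = (0.70 + float(rng.uniform(-0.02, 0.02))) * foot_len
    slope = (u1 - u0) / duration
    d0 = (-0.10 + float(rng.uniform(-0.015, 0.015))) * sweep
    d1 = (+0.10 + float(rng.uniform(-0.015, 0.015))) * sweep
    ewt = np.exp(omega_lip * duration)
    B = (d1 - d0 / ewt) / (ewt - 1.0 / ewt)
    C = d0 - B
    com_path = u0 + slope * t + B * np.exp(omega_lip * t) + C * np.exp(-omega_lip * t)

    # The HAT lean is solved pointwise so that the whole-body COM tracks
    # the LIP path; this keeps the heavy trunk from inheriting the
    # knee-bump hip wobble.  Its time derivatives are taken frame by
    # frame; forward and inverse dynamics consume the same arrays, so
    # the round-trip consistency oracle is unaffected.
    c_hat_x, hip_x = _hat_com_for_target(seg, phi_s, phi_t, com_path)
    q = (c_hat_x - hip_x) / seg.hat_com_dist
    if np.any(np.abs(q) > 0.6):
        raise RuntimeError("HAT lean out of range; template configuration invalid")
    phi_h = np.arcsin(q)
    dphi_h = np.gradient(phi_h, t, edge_order=2)
    ddphi_h = np.gradient(dphi_h, t, edge_order=2)

    ankle = np.tile(np.asarray(seg.ankle_offset), (n, 1))
    zeros = np.zeros((n, 2))
    return PlanarStanceKinematics(
        t=t, fs=fs,
        phi_shank=phi_s, phi_thigh=phi_t, phi_hat=phi_h,
        dphi_shank=dphi_s, dphi_thigh=dphi_t, dphi_hat=dphi_h,
        ddphi_shank=ddphi_s, ddphi_thigh=ddphi_t, ddphi_hat=ddphi_h,
        ankle_pos=ankle, ankle_vel=zeros.copy(), ankle_acc=zeros.copy(),
    )


def _joint_angles(kin: PlanarStanceKinematics) -> tuple[dict, dict, dict]:
    """Joint-angle coordinates conjugate to the torque convention.

    Positive = hip extension, knee extension, ankle plantarflexion, so
    that extension/plantarflexion torques (the positive direction in
    :mod:`gaitkinetics.dynamics`) do positive work on positive angle
    rates and extensor MTUs have positive moment arms.
    """
    theta = {
        "hip": kin.phi_thigh - kin.phi_hat,
        "knee": kin.phi_thigh - kin.phi_shank,
        "ankle": -(kin.phi_shank + kin.phi_foot),
    }
    omega = {
        "hip": kin.dphi_thigh - kin.dphi_hat,
        "knee": kin.dphi_thigh - kin.dphi_shank,
        "ankle": -(kin.dphi_shank + kin.dphi_foot),
    }
    alpha = {
        "hip": kin.ddphi_thigh - kin.ddphi_hat,
        "knee": kin.ddphi_thigh - kin.ddphi_shank,
        "ankle": -(kin.ddphi_shank + kin.ddphi_foot),
    }
    return theta, omega, alpha


def kinematics_from_arrays(
    theta: dict[str, np.ndarray],
    alpha_ang: dict[str, np.ndarray] | None,
    ankle_pos: np.ndarray,
    fs: float,
    omega: dict[str, np.ndarray] | None = None,
    ankle_vel: np.ndarray | None = None,
    ankle_acc: np.ndarray | None = None,
) -> PlanarStanceKinematics:
    """Rebuild segment-level kinematics from joint-angle channels.

    Inverse of :func:`_joint_angles` under the flat-foot convention
    (``phi_foot = 0``).  Missing derivative channels are obtained by
    frame-by-frame differentiation.
    """
    n = len(next(iter(theta.values())))
    t = np.arange(n) / fs
    if omega is None:
        omega = {j: sig.differentiate(theta[j], fs) for j in theta}
    if alpha_ang is None:
        alpha_ang = {j: sig.differentiate(omega[j], fs) for j in theta}
    phi_s = -theta["ankle"]
    phi_t = theta["knee"] + phi_s
    phi_h = phi_t - theta["hip"]
    dphi_s = -omega["ankle"]
    dphi_t = omega["knee"] + dphi_s
    dphi_h = dphi_t - omega["hip"]
    ddphi_s = -alpha_ang["ankle"]
    ddphi_t = alpha_ang["knee"] + ddphi_s
    ddphi_h = ddphi_t - alpha_ang["hip"]
    if ankle_vel is None:
        ankle_vel = np.stack([sig.differentiate(ankle_pos[:, i], fs) for i in range(2)], axis=-1)
    if ankle_acc is None:
        ankle_acc = np.stack([sig.differentiate(ankle_vel[:, i], fs) for i in range(2)], axis=-1)
    return PlanarStanceKinematics(
        t=t, fs=fs,
        phi_shank=phi_s, phi_thigh=phi_t, phi_hat=phi_h,
        dphi_shank=dphi_s, dphi_thigh=dphi_t, dphi_hat=dphi_h,
        ddphi_shank=ddphi_s, ddphi_thigh=ddphi_t, ddphi_hat=ddphi_h,
        ankle_pos=ankle_pos, ankle_vel=ankle_vel, ankle_acc=ankle_acc,
    )


# ---------------------------------------------------------------------------
# minimum-effort excitations and raw EMG
# ---------------------------------------------------------------------------

def excitations_from_torques(
    thetas: dict[str, np.ndarray],
    omegas: dict[str, np.ndarray],
    target_torques: dict[str, np.ndarray],
    subject: SubjectModel,
    include_passive: bool = True,
    include_unrecorded: bool = False,
    tol: float = 1e-5,
) -> dict[str, np.ndarray]:
    """Frame-wise minimum-effort excitations reproducing the target torques.

    Minimises the sum of squared MTU excitations subject to the
    MTU-model torques matching the targets, propagating activation
    dynamics across frames.  MTUs sharing a recorded channel share one
    excitation (their envelope is one signal); unrecorded MTUs are
    held at zero unless ``include_unrecorded``.  Raises with the frame
    index and torque residual if a frame is infeasible.
    """
    joints = list(target_torques)
    n = len(next(iter(target_torques.values())))
    labels = subject.mtu_labels
    m = len(labels)
    params = subject.truth_params

    # variable groups: one per recorded channel (+ optionally one per unrecorded MTU)
    groups: list[list[int]] = []
    for ch in subject.channels:
        members = [labels.index(lab) for lab in subject.emg_channel_map.get(ch, [])]
        if members:
            groups.append(members)
    if include_unrecorded:
        for lab in subject.unrecorded_mtus():
            groups.append([labels.index(lab)])
    k = len(groups)
    G = np.zeros((m, k))
    for gi, members in enumerate(groups):
        for i in members:
            G[i, gi] = 1.0
    group_size = G.sum(axis=0)

    gains = np.zeros((m, n))
    passive = np.zeros((m, n))
    arms = np.zeros((m, len(joints), n))
    filt = np.array([_filter_coeffs(params[lab]) for lab in labels])
    shape = np.array([params[lab].shape_factor for lab in labels])
    for i, g in enumerate(subject.mtu_set):
        p = params[g.label]
        l_mt, v_mt, r = mtu_state(thetas, omegas, g)
        l_fibre = l_mt - p.tendon_slack_scale * g.base_tendon_slack
        if np.any(l_fibre <= 0):
            raise ValueError(f"non-physical fibre length for MTU {g.label!r}")
        l_opt = p.optimal_fibre_scale * g.base_optimal_fibre
        scale = p.strength_coeff * g.max_isometric_force
        gains[i] = scale * _force_length(l_fibre / l_opt) * _force_velocity(v_mt / (_VMAX_LOPT * l_opt))
        if include_passive:
            passive[i] = scale * _force_passive(l_fibre / l_opt)
        for jx, j in enumerate(joints):
            if j in r:
                arms[i, jx] = r[j]

    tau_passive = np.einsum("mjn,mn->jn", arms, passive)
    tau_target = np.stack([np.asarray(target_torques[j], float) for j in joints])

    exc = np.zeros((m, n))
    u_hist = np.zeros((m, 2))
    e_prev = np.full(k, 0.1)

    for t in range(n):
        g_t = gains[:, t]
        r_t = arms[:, :, t]
        tgt = tau_target[:, t] - tau_passive[:, t]
        alpha_g, b1, b2 = filt[:, 0], filt[:, 1], filt[:, 2]
        if t == 0:
            drive = np.zeros(m)
            u_gain = np.ones(m)
        else:
            drive = -b1 * u_hist[:, 0] - b2 * u_hist[:, 1]
            u_gain = alpha_g

        def residual(eg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            e = G @ eg
            u = u_gain * e + drive
            uc = np.clip(u, 0.0, 1.0)
            a = np.where(np.abs(shape) < 1e-8, uc, np.expm1(shape * uc) / np.expm1(shape))
            res = r_t.T @ (g_t * a) - tgt
            nl = np.where(np.abs(shape) < 1e-8, 1.0,
                          shape * np.exp(shape * uc) / np.expm1(shape))
            da_de = np.where((u >= 0) & (u <= 1), nl * u_gain, 0.0)
            jac = (r_t.T * (g_t * da_de)) @ G
            return res, jac

        def objective(eg: np.ndarray):
            return float(group_size @ eg**2), 2.0 * group_size * eg

        cons = [{
            "type": "eq",
            "fun": lambda eg: residual(eg)[0],
            "jac": lambda eg: residual(eg)[1],
        }]
        sol = optimize.minimize(
            objective, np.clip(e_prev, 0, 1), jac=True, method="SLSQP",
            bounds=[(0.0, 1.0)] * k, constraints=cons,
            options={"maxiter": 150, "ftol": 1e-12},
        )
        e_t = np.clip(sol.x, 0.0, 1.0)
        res_t, _ = residual(e_t)
        if np.linalg.norm(res_t, ord=np.inf) > tol:
            # one retry from a neutral point before declaring infeasibility
            sol = optimize.minimize(
                objective, np.full(k, 0.3), jac=True, method="SLSQP",
                bounds=[(0.0, 1.0)] * k, constraints=cons,
                options={"maxiter": 300, "ftol": 1e-12},
            )
            e_t = np.clip(sol.x, 0.0, 1.0)
            res_t, _ = residual(e_t)
            if np.linalg.norm(res_t, ord=np.inf) > tol:
                raise RuntimeError(
                    f"torque targets infeasible within [0,1] excitations at frame {t}: "
                    f"residual {np.linalg.norm(res_t, ord=np.inf):.3e} Nm"
                )
        e_full = G @ e_t
        u_t = np.clip(u_gain * e_full + drive, 0.0, 1.0)
        if t == 0:
            u_hist[:, 0] = u_t
            u_hist[:, 1] = u_t
        else:
            u_hist[:, 1] = u_hist[:, 0]
            u_hist[:, 0] = u_t
        exc[:, t] = e_full
        e_prev = e_t

    return {lab: exc[i] for i, lab in enumerate(labels)}


def synthesize_raw_emg(
    envelope_truth: np.ndarray, fs: float, seed: int, band: tuple[float, float] | None = None
) -> np.ndarray:
    """Amplitude-modulated band-limited Gaussian carrier for one channel.

    The carrier is zero-mean broadband noise band-passed to
    ``band`` (default [30 Hz, 0.95 * Nyquist]) and scaled to unit
    mean absolute value, so the 30 Hz HP -> rectify -> 6 Hz LP chain
    recovers the envelope up to smoothing error.
    """
    env = np.asarray(envelope_truth, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be non-negative")
    if fs <= 60:
        raise ValueError(f"fs={fs} Hz too low for the 30 Hz high-pass (need fs > 60)")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(len(env))
    lo, hi = band if band is not None else (30.0, 0.95 * fs / 2)
    from scipy.signal import butter, filtfilt

    b, a = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    carrier = filtfilt(b, a, white)
    mean_abs = np.mean(np.abs(carrier))
    if mean_abs > 0:
        carrier = carrier / mean_abs
    return env * carrier


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def generate_stance_trial(
    subject: SubjectModel,
    trial_seed: int,
    noise_cfg: NoiseConfig | None = None,
    speed_scale: float = 1.0,
    consistency_tol: float = 1e-8,
) -> StanceTrial:
    """One dynamically consistent stance-phase trial with measurement noise.

    The noiseless block (``trial.truth``) carries the ground-truth
    torques, excitations and clean channels; inverse dynamics on the
    clean channels reproduces the truth torques to ``consistency_tol``
    (verified internally against the top-down HAT check).
    """
    noise = noise_cfg if noise_cfg is not None else NoiseConfig()
    rng = np.random.default_rng((int(trial_seed), int(subject.seed), 0x5717CE))
    seg = subject.segment_params
    kin = _stance_kinematics(subject, rng, speed_scale)
    n, fs, t = kin.n, kin.fs, kin.t

    grf_ap, grf_v, cop_ap = forward_ground_reaction(kin, seg)
    torques = inverse_dynamics(kin, grf_ap, grf_v, cop_ap, seg)
    hip_check = hat_reference_hip_torque(kin, seg)
    resid = float(np.max(np.abs(hip_check - torques.tau_hip)))
    if resid > consistency_tol:
        raise RuntimeError(
            f"internal dynamics inconsistency: hip-torque residual {resid:.3e} Nm "
            f"exceeds {consistency_tol:.1e}"
        )

    theta, omega, alpha_ang = _joint_angles(kin)
    target = {"hip": torques.tau_hip, "knee": torques.tau_knee, "ankle": torques.tau_ankle}
    excitations = excitations_from_torques(theta, omega, target, subject)

    # channel envelopes: each channel's MTUs share one excitation by construction
    env_truth = np.zeros((len(EMG_CHANNELS), n))
    for ci, ch in enumerate(EMG_CHANNELS):
        labs = subject.emg_channel_map.get(ch, [])
        if labs:
            env_truth[ci] = excitations[labs[0]]

    # raw EMG runs at its own (higher) rate so the carrier is wideband
    # and the envelope chain can actually separate carrier from envelope
    fs_emg = 1000.0
    step = int(round(fs_emg / fs))
    n_emg = (n - 1) * step + 1
    t_emg = np.arange(n_emg) / fs_emg
    emg_raw_clean = np.stack([
        synthesize_raw_emg(np.interp(t_emg, t, env_truth[ci]), fs_emg,
                           seed=int(rng.integers(2**31)))
        for ci in range(len(EMG_CHANNELS))
    ])

    # non-dynamic ML channels: smooth seeded templates
    s = t / t[-1]
    bw = subject.mass * seg.g
    grf_ml_clean = bw * (0.05 * np.sin(np.pi * s)
                         + 0.01 * np.sin(2 * np.pi * s + rng.uniform(0, 2 * np.pi)))
    cop_ml_clean = 8.0 * np.sin(np.pi * s) + 3.0 * np.sin(
        2 * np.pi * s + rng.uniform(0, 2 * np.pi))  # mm

    ch_pts = _joint_points(kin, seg)
    heel_clean = ch_pts.pop("heel")["pos"]

    grf_clean = np.stack([grf_ap, grf_ml_clean, grf_v])
    cop_clean = np.stack([cop_ap * 1000.0, cop_ml_clean])  # mm, heel-referenced

    truth = {
        "torques": torques,
        "excitations": excitations,
        "emg_env": env_truth,
        "grf": grf_clean,
        "cop": cop_clean,
        "theta": theta,
        "omega": omega,
        "alpha_ang": alpha_ang,
        "joint_centres": ch_pts,
        "heel_pos": heel_clean,
        "kinematics": kin,
    }

    if noise.silent:
        theta_m = {j: v.copy() for j, v in theta.items()}
        omega_m = {j: v.copy() for j, v in omega.items()}
        alpha_m = {j: v.copy() for j, v in alpha_ang.items()}
        jc_m = {j: {k: v.copy() for k, v in d.items()} for j, d in ch_pts.items()}
        heel_m = heel_clean.copy()
        grf_m = grf_clean.copy()
        cop_m = cop_clean.copy()
        emg_raw = emg_raw_clean.copy()
        emg_env = env_truth.copy()
    else:
        theta_m = {j: v + noise.angle_sd * rng.standard_normal(n) for j, v in theta.items()}
        omega_m = {j: sig.differentiate(theta_m[j], fs) for j in theta_m}
        alpha_m = {j: sig.differentiate(omega_m[j], fs) for j in theta_m}
        jc_m = {}
        for j, d in ch_pts.items():
            pos = d["pos"] + noise.marker_sd * rng.standard_normal((n, 2))
            vel = np.stack([sig.differentiate(pos[:, i], fs) for i in range(2)], axis=-1)
            acc = np.stack([sig.differentiate(vel[:, i], fs) for i in range(2)], axis=-1)
            jc_m[j] = {"pos": pos, "vel": vel, "acc": acc}
        heel_m = heel_clean + noise.marker_sd * rng.standard_normal((n, 2))
        grf_m = grf_clean + noise.grf_sd * rng.standard_normal((3, n))
        grf_m[2] = np.clip(grf_m[2], 0.0, None)  # vertical GRF stays >= 0
        cop_m = cop_clean + noise.cop_sd * rng.standard_normal((2, n))
        emg_raw = emg_raw_clean + noise.emg_sd * rng.standard_normal(emg_raw_clean.shape)
        env = np.stack([sig.process_emg(ch_raw, fs_emg)[::step]
                        for ch_raw in emg_raw])
        peaks = env.max(axis=1)
        peaks[peaks == 0] = 1.0
        emg_env = env / peaks[:, None]

    return StanceTrial(
        fs=fs, t=t,
        theta=theta_m, omega=omega_m, alpha_ang=alpha_m,
        joint_centres=jc_m, heel_pos=heel_m,
        emg_raw=emg_raw, emg_env=emg_env,
        grf=grf_m, cop=cop_m,
        mass=subject.mass, bw=bw, fs_emg=fs_emg, seed=int(trial_seed),
        truth=truth,
    )


def _joint_points(kin: PlanarStanceKinematics, seg: SegmentParams) -> dict:
    """Heel/ankle/knee/hip positions, velocities, accelerations from the chain."""
    from .dynamics import _chain

    ch = _chain(kin, seg)
    out = {
        "ankle": {"pos": kin.ankle_pos.copy(), "vel": kin.ankle_vel.copy(),
                  "acc": kin.ankle_acc.copy()},
    }
    for j in ("knee", "hip"):
        out[j] = {"pos": ch[f"{j}_pos"], "vel": ch[f"{j}_vel"], "acc": ch[f"{j}_acc"]}
    out["heel"] = {"pos": ch["heel_pos"], "vel": ch["heel_vel"], "acc": ch["heel_acc"]}
    return out


def generate_subject_trials(
    subject: SubjectModel,
    n_trials: int = 4,
    noise_cfg: NoiseConfig | None = None,
    base_trial_seed: int = 0,
    speed_scale: float = 1.0,
) -> list[StanceTrial]:
    """Generate a subject's trial set with subject-level EMG normalisation.

    For noisy trials the EMG envelopes are re-normalised to the peak
    across the subject's whole trial set (the within-trial shapes are
    preserved up to one scalar per channel), matching the subject-wise
    peak-normalisation convention of the processing chain.
    """
    noise = noise_cfg if noise_cfg is not None else NoiseConfig()
    trials = []
    for i in range(n_trials):
        # deterministic rejection sampling: a rare draw whose torques are
        # not realisable within [0,1] excitations is redrawn from an
        # offset seed rather than aborting the whole cohort
        last_err: RuntimeError | None = None
        for attempt in range(4):
            try:
                trials.append(generate_stance_trial(
                    subject, base_trial_seed + i + attempt * 10_007, noise,
                    speed_scale))
                break
            except RuntimeError as err:
                last_err = err
        else:
            raise RuntimeError(
                f"could not generate a feasible trial {i} for subject "
                f"{subject.subject_id}"
            ) from last_err
    if not noise.silent:
        step = int(round(trials[0].fs_emg / trials[0].fs))
        raw_envs = [np.stack([sig.process_emg(ch_raw, t.fs_emg)[::step]
                              for ch_raw in t.emg_raw])
                    for t in trials]
        normed, _ = sig.normalise_emg(raw_envs)
        for t, env in zip(trials, normed):
            t.emg_env = env
    return trials


def generate_cohort(
    n_subjects: int = 5,
    n_trials: int = 4,
    seed: int = 0,
    noise_cfg: NoiseConfig | None = None,
    anthropometry_ranges: dict | None = None,
) -> list[tuple[SubjectModel, list[StanceTrial]]]:
    """A cohort of seeded subjects with their trial sets."""
    out = []
    rng = np.random.default_rng(seed)
    for i in range(n_subjects):
        sub_seed = int(rng.integers(1, 2**31 - 1))
        subject = generate_subject(sub_seed, anthropometry_ranges, subject_id=f"S{i + 1:02d}")
        trials = generate_subject_trials(
            subject, n_trials, noise_cfg, base_trial_seed=int(rng.integers(1, 2**31 - 1))
        )
        out.append((subject, trials))
    return out
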