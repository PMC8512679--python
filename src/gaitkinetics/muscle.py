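"""EMG-driven Hill-type musculotendon modelling and hybrid static optimisation.

Each musculotendon unit (MTU) is a rigid-tendon Hill actuator with
zero pennation whose path length over the sagittal joints is a
per-DoF quadratic polynomial, so moment arms are analytic
(``r_j = -d l_mt / d theta_j``).  Neural excitation passes through a
discrete second-order recursive filter followed by an exponential
nonlinearisation (shape factor ``A``) to yield activation.

Subject specificity comes from five bounded calibration parameters per
MTU (tendon-slack and optimal-fibre multiplicative scales, a strength
coefficient, two activation-filter coefficients and the shape factor),
tuned by tracking inverse-dynamics torques over calibration trials.

The hybrid (EMG-assisted) solver minimises, frame by frame,

    F = alpha * E_trackMOM + beta * E_sumEXC + gamma * E_trackEMG

over all MTU excitations in [0, 1]: it tracks the inverse-dynamics
torques, penalises total squared excitation, and keeps the MTUs that
have a recorded EMG channel close (in absolute deviation) to their
experimental envelopes while synthesising the excitations of the
unrecorded MTUs.  ``alpha`` is fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as _sig

__all__ = [
    "MtuParams",
    "MtuGeometry",
    "HybridWeights",
    "HybridBreakdown",
    "PARAM_BOUNDS",
    "activation_dynamics",
    "mtu_state",
    "mtu_force",
    "emg_driven_torques",
    "expand_channel_excitations",
    "calibrate",
    "hybrid_solve",
    "tune_beta_gamma",
]

#: Calibration box per MTU (lower, upper).  The activation-filter
#: coefficients are kept strictly inside (-1, 1) for filter stability.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "tendon_slack_scale": (0.95, 1.05),
    "optimal_fibre_scale": (0.975, 1.025),
    "strength_coeff": (0.5, 2.0),
    "c1": (-0.99, 0.99),
    "c2": (-0.99, 0.99),
    "shape_factor": (-5.0, 0.0),
}

_PARAM_ORDER = tuple(PARAM_BOUNDS)

# fixed (non-calibrated) curve constants of the Hill model
_FL_WIDTH = 0.45          # variance-like width of the Gaussian force-length curve
_FV_SHAPE = 0.25          # curvature of the concentric force-velocity branch
_FV_ECC_GAIN = 0.5        # eccentric plateau is 1 + gain
_FP_EXP = 10.0            # passive curve exponent
_FP_NORM = np.expm1(_FP_EXP * 0.5)  # passive force reaches F_max at l~ = 1.5
_VMAX_LOPT = 10.0         # max shortening velocity, optimal fibre lengths / s


@dataclass(frozen=True)
class MtuParams:
    """Calibrated per-MTU parameters (all dimensionless)."""

    tendon_slack_scale: float = 1.0
    optimal_fibre_scale: float = 1.0
    strength_coeff: float = 1.0
    c1: float = -0.5
    c2: float = -0.5
    shape_factor: float = -1.5

    def __post_init__(self) -> None:
        for name in _PARAM_ORDER:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(f"{name}={v} outside calibration range [{lo}, {hi}]")
        if abs(self.c1) >= 1 or abs(self.c2) >= 1:
            raise ValueError("activation filter coefficients must satisfy |c| < 1")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _PARAM_ORDER])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "MtuParams":
        return cls(**dict(zip(_PARAM_ORDER, map(float, v))))


@dataclass(frozen=True)
class MtuGeometry:
    """Path geometry and base properties of one MTU.

    ``dof_coeffs`` maps a joint name to ``(k1, k2)``; the MTU length is

        l_mt(theta) = l0 + sum_j [ k1_j * theta_j + 0.5 * k2_j * theta_j^2 ]

    so the (angle-dependent) moment arm about joint j is
    ``r_j = -(k1_j + k2_j * theta_j)``.  Torque sign convention follows
    :mod:`gaitkinetics.dynamics` (positive = extension/plantarflexion),
    so extensors/plantarflexors have ``r_j > 0``.
    """

    label: str
    l0: float                      # m, musculotendon length at neutral posture
    base_optimal_fibre: float      # m
    base_tendon_slack: float       # m
    max_isometric_force: float     # N
    dof_coeffs: dict[str, tuple[float, float]]
    recorded_channel: str | None = None

    def length(self, thetas: dict[str, np.ndarray]) -> np.ndarray:
        l = np.full_like(next(iter(thetas.values()), np.zeros(1)), self.l0, dtype=float)
        for j, (k1, k2) in self.dof_coeffs.items():
            th = np.asarray(thetas[j], dtype=float)
            l = l + k1 * th + 0.5 * k2 * th**2
        return l

    def moment_arm(self, joint: str, theta: np.ndarray) -> np.ndarray:
        k1, k2 = self.dof_coeffs[joint]
        return -(k1 + k2 * np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class HybridWeights:
    """Weights of the hybrid objective; ``alpha`` is fixed at 1."""

    beta: float = 1.0
    gamma: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha != 1.0:
            raise ValueError("alpha is fixed at 1")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be nonnegative")


@dataclass
class HybridBreakdown:
    """Objective terms of one hybrid solve, summed over frames."""

    e_track_mom: float
    e_sum_exc: float
    e_track_emg: float
    beta: float
    gamma: float
    per_frame_mom: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total(self) -> float:
        return self.e_track_mom + self.beta * self.e_sum_exc + self.gamma * self.e_track_emg


# ---------------------------------------------------------------------------
# activation dynamics and the Hill model
# ---------------------------------------------------------------------------

def _filter_coeffs(p: MtuParams) -> tuple[float, float, float]:
    beta1 = p.c1 + p.c2
    beta2 = p.c1 * p.c2
    alpha = 1.0 + beta1 + beta2  # unit steady-state gain
    return alpha, beta1, beta2


def _nonlinearise(u: np.ndarray, shape_factor: float) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    if abs(shape_factor) < 1e-8:
        return u
    return np.expm1(shape_factor * u) / np.expm1(shape_factor)


def activation_dynamics(excitation: np.ndarray, p: MtuParams) -> np.ndarray:
    """Excitation -> activation: recursive filter then exponential shaping.

    ``u(t) = a_g e(t) - b1 u(t-1) - b2 u(t-2)`` with ``b1 = c1 + c2``,
    ``b2 = c1 c2`` and ``a_g = 1 + b1 + b2`` (unit steady-state gain);
    the filter is initialised at steady state for the first sample.
    Then ``a = (exp(A u) - 1) / (exp(A) - 1)`` with the shape factor
    ``A <= 0`` (``a = u`` in the A -> 0 limit).  Output in [0, 1].
    """
    e = np.asarray(excitation, dtype=float)
    if np.any(e < -1e-12) or np.any(e > 1 + 1e-12):
        raise ValueError("excitation must lie within [0, 1]")
    if abs(p.c1) >= 1 or abs(p.c2) >= 1:
        raise ValueError("unstable activation filter: |c1|, |c2| must be < 1")
    alpha, beta1, beta2 = _filter_coeffs(p)
    b = [alpha]
    a = [1.0, beta1, beta2]
    zi = _sig.lfilter_zi(b, a) * (e[0] if e.size else 0.0)
    u, _ = _sig.lfilter(b, a, e, zi=zi)
    return np.clip(_nonlinearise(u, p.shape_factor), 0.0, 1.0)


def mtu_state(
    thetas: dict[str, np.ndarray],
    omegas: dict[str, np.ndarray],
    g: MtuGeometry,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """MTU length (m), lengthening velocity (m/s) and per-DoF moment arms.

    ``v_mt = -sum_j r_j * omega_j`` holds by construction, which gives
    the power balance ``sum_j tau_j omega_j = -F v_mt`` for each MTU.
    """
    l_mt = g.length(thetas)
    arms = {j: g.moment_arm(j, thetas[j]) for j in g.dof_coeffs}
    v_mt = np.zeros_like(l_mt)
    for j, r in arms.items():
        v_mt = v_mt - r * np.asarray(omegas[j], dtype=float)
    return l_mt, v_mt, arms


def _force_length(l_norm: np.ndarray) -> np.ndarray:
    return np.exp(-((l_norm - 1.0) ** 2) / _FL_WIDTH)


def _force_velocity(v_norm: np.ndarray) -> np.ndarray:
    v = np.asarray(v_norm, dtype=float)
    conc = np.clip((1.0 + v) / (1.0 - v / _FV_SHAPE), 0.0, None)
    ecc = 1.0 + _FV_ECC_GAIN * v / (v + _FV_SHAPE)
    return np.where(v < 0, conc, ecc)


def _force_passive(l_norm: np.ndarray) -> np.ndarray:
    return np.where(l_norm > 1.0, np.expm1(_FP_EXP * (l_norm - 1.0)) / _FP_NORM, 0.0)


def mtu_force(
    a: np.ndarray,
    l_mt: np.ndarray,
    v_mt: np.ndarray,
    g: MtuGeometry,
    p: MtuParams,
    include_passive: bool = True,
) -> np.ndarray:
    """Rigid-tendon Hill force (N), always >= 0.

    ``F = strength * F_max * (a * f_l(l~) * f_v(v~) + f_p(l~))`` with a
    Gaussian active force-length curve, a saturating force-velocity
    curve (zero at maximal shortening, plateau 1.5 eccentric) and an
    exponential passive curve that is zero below optimal length.
    """
    l_fibre = np.asarray(l_mt, dtype=float) - p.tendon_slack_scale * g.base_tendon_slack
    if np.any(l_fibre <= 0):
        raise ValueError(f"non-physical fibre length (<= 0) for MTU {g.label!r}")
    l_opt = p.optimal_fibre_scale * g.base_optimal_fibre
    l_norm = l_fibre / l_opt
    v_norm = np.asarray(v_mt, dtype=float) / (_VMAX_LOPT * l_opt)
    active = np.clip(np.asarray(a, dtype=float), 0.0, 1.0) * _force_length(l_norm) * _force_velocity(v_norm)
    passive = _force_passive(l_norm) if include_passive else 0.0
    return np.clip(p.strength_coeff * g.max_isometric_force * (active + passive), 0.0, None)


# ---------------------------------------------------------------------------
# EMG-driven torque computation
# ---------------------------------------------------------------------------

def expand_channel_excitations(
    envelopes: dict[str, np.ndarray],
    channel_map: dict[str, list[str]],
    mtu_labels: list[str],
    default: float | None = 0.0,
) -> dict[str, np.ndarray]:
    """Map recorded channel envelopes onto MTU excitations.

    One envelope may drive several MTUs.  MTUs with no recorded
    channel receive a constant ``default`` excitation (zero: purely
    passive in the EMG-driven model); with ``default=None`` they are
    left out and the caller must supply synthesized series.
    """
    n = len(next(iter(envelopes.values())))
    exc: dict[str, np.ndarray] = {}
    for channel, labels in channel_map.items():
        env = np.asarray(envelopes[channel], dtype=float)
        for lab in labels:
            exc[lab] = env
    for lab in mtu_labels:
        if lab not in exc:
            if default is None:
                continue
            exc[lab] = np.full(n, float(default))
    return exc


def emg_driven_torques(
    thetas: dict[str, np.ndarray],
    omegas: dict[str, np.ndarray],
    mtu_set: list[MtuGeometry],
    params: dict[str, MtuParams],
    excitations: dict[str, np.ndarray],
    include_passive: bool = True,
) -> dict[str, np.ndarray]:
    """Joint torques (Nm) produced by the full MTU set.

    ``tau_j(t) = sum_i r_ij(theta(t)) F_i(t)``.  Every MTU must have an
    excitation series (recorded channels are expanded beforehand with
    :func:`expand_channel_excitations`).
    """
    n = len(next(iter(thetas.values())))
    torques = {j: np.zeros(n) for j in thetas}
    for g in mtu_set:
        if g.label not in excitations:
            raise ValueError(f"no excitation supplied for MTU {g.label!r}")
        p = params[g.label]
        a = activation_dynamics(excitations[g.label], p)
        l_mt, v_mt, arms = mtu_state(thetas, omegas, g)
        force = mtu_force(a, l_mt, v_mt, g, p, include_passive=include_passive)
        for j, r in arms.items():
            torques[j] += r * force
    return torques


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _pack(params: dict[str, MtuParams], labels: list[str]) -> np.ndarray:
    return np.concatenate([params[lab].as_vector() for lab in labels])


def _unpack(x: np.ndarray, labels: list[str]) -> dict[str, MtuParams]:
    k = len(_PARAM_ORDER)
    return {lab: MtuParams.from_vector(x[i * k:(i + 1) * k]) for i, lab in enumerate(labels)}


def calibrate(
    mtu_set: list[MtuGeometry],
    calibration_trials: list[dict],
    measured_torques: list[dict[str, np.ndarray]],
    initial: dict[str, MtuParams] | None = None,
    seed: int = 0,
    max_nfev: int | None = 200,
    include_passive: bool = True,
) -> tuple[dict[str, MtuParams], dict]:
    """Tune MTU parameters by torque tracking over the calibration trials.

    Each trial dict must carry ``thetas``, ``omegas`` (per-DoF series)
    and ``excitations`` (per-MTU series, recorded channels already
    expanded; unrecorded MTUs at zero).  Minimises the summed squared
    difference between EMG-driven and measured torques over the
    Table-style parameter box with a bounded trust-region
    least-squares solver.  Deterministic for a fixed seed and starting
    point.

    Returns the calibrated parameters and an info dict with the
    objective trace (initial/final cost) and solver status.
    """
    labels = [g.label for g in mtu_set]
    if initial is None:
        rng = np.random.default_rng(seed)
        initial = {}
        for lab in labels:
            vals = {}
            for name in _PARAM_ORDER:
                lo, hi = PARAM_BOUNDS[name]
                mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
                vals[name] = mid + 0.2 * half * rng.uniform(-1, 1)
            initial[lab] = MtuParams(**vals)
    x0 = _pack(initial, labels)
    lo = np.concatenate([[PARAM_BOUNDS[n][0] for n in _PARAM_ORDER]] * len(labels))
    hi = np.concatenate([[PARAM_BOUNDS[n][1] for n in _PARAM_ORDER]] * len(labels))

    # Precompute every parameter-independent quantity and stack the
    # (trial, MTU) axes so one residual evaluation is a handful of
    # vectorised array operations plus a single activation recursion.
    m = len(mtu_set)
    joints = list(calibration_trials[0]["thetas"])
    n_j = len(joints)
    lens = [len(next(iter(tr["thetas"].values()))) for tr in calibration_trials]
    n_max = max(lens)
    n_tr = len(calibration_trials)
    L = np.zeros((n_tr, m, n_max))      # musculotendon length
    V = np.zeros((n_tr, m, n_max))      # lengthening velocity
    R = np.zeros((n_tr, m, n_j, n_max))  # moment arms
    E = np.zeros((n_tr, m, n_max))      # excitations
    valid = np.zeros((n_tr, n_max), dtype=bool)
    meas = np.zeros((n_tr, n_j, n_max))
    for ti, trial in enumerate(calibration_trials):
        valid[ti, : lens[ti]] = True
        for jx, j in enumerate(joints):
            meas[ti, jx, : lens[ti]] = measured_torques[ti][j]
        for mi, g in enumerate(mtu_set):
            l_mt, v_mt, arms = mtu_state(trial["thetas"], trial["omegas"], g)
            L[ti, mi, : lens[ti]] = l_mt
            V[ti, mi, : lens[ti]] = v_mt
            # pad with the last value to keep fibre lengths physical
            L[ti, mi, lens[ti]:] = l_mt[-1]
            for jx, j in enumerate(joints):
                if j in arms:
                    R[ti, mi, jx, : lens[ti]] = arms[j]
            E[ti, mi, : lens[ti]] = trial["excitations"][g.label]
    base_slack = np.array([g.base_tendon_slack for g in mtu_set])
    base_opt = np.array([g.base_optimal_fibre for g in mtu_set])
    f_max = np.array([g.max_isometric_force for g in mtu_set])
    k = len(_PARAM_ORDER)
    res_mask = valid[:, None, :].repeat(n_j, axis=1).ravel()

    def residuals(x: np.ndarray) -> np.ndarray:
        P = np.clip(x, lo, hi).reshape(m, k)
        slack_s, opt_s, strength, c1, c2, shape = P.T
        beta1, beta2 = c1 + c2, c1 * c2
        alpha = 1.0 + beta1 + beta2
        # activation recursion over all trials x MTUs at once
        u = np.zeros((n_tr, m, n_max))
        e0 = E[:, :, 0]
        u_1 = e0.copy()
        u_2 = e0.copy()
        for t in range(n_max):
            if t == 0:
                u_t = e0
            else:
                u_t = alpha[None, :] * E[:, :, t] - beta1[None, :] * u_1 - beta2[None, :] * u_2
            u_2, u_1 = u_1, u_t
            u[:, :, t] = u_t
        u = np.clip(u, 0.0, 1.0)
        small = np.abs(shape) < 1e-8
        denom = np.where(small, 1.0, np.expm1(shape))
        act = np.where(small[None, :, None], u,
                       np.expm1(shape[None, :, None] * u) / denom[None, :, None])
        l_opt = opt_s * base_opt
        ln = (L - (slack_s * base_slack)[None, :, None]) / l_opt[None, :, None]
        vn = V / (_VMAX_LOPT * l_opt)[None, :, None]
        scale = strength * f_max
        force = scale[None, :, None] * (act * _force_length(ln) * _force_velocity(vn))
        if include_passive:
            force = force + scale[None, :, None] * _force_passive(ln)
        force = np.clip(force, 0.0, None)
        tau = np.einsum("tmjn,tmn->tjn", R, force)
        return (tau - meas).ravel()[res_mask]

    # Jacobian block sparsity: an MTU's parameters only touch the rows
    # of the joints it spans, so finite differences can be grouped.
    row_blocks = []
    for ti in range(n_tr):
        for j in joints:
            spans = np.array([j in g.dof_coeffs for g in mtu_set])
            row = np.repeat(spans, k)
            row_blocks.append(np.tile(row, (lens[ti], 1)))
    sparsity = np.vstack(row_blocks)

    r0 = residuals(x0)
    sol = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        jac_sparsity=sparsity,
        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=max_nfev,
    )
    if np.any(sol.x < lo - 1e-9) or np.any(sol.x > hi + 1e-9):
        raise RuntimeError("internal error: calibrated parameters violate bounds")
    info = {
        "initial_cost": float(0.5 * np.dot(r0, r0)),
        "final_cost": float(sol.cost),
        "status": int(sol.status),
        "nfev": int(sol.nfev),
        "message": sol.message,
    }
    return _unpack(sol.x, labels), info


# ---------------------------------------------------------------------------
# hybrid (EMG-assisted) static optimisation
# ---------------------------------------------------------------------------

def hybrid_solve(
    thetas: dict[str, np.ndarray],
    omegas: dict[str, np.ndarray],
    mtu_set: list[MtuGeometry],
    params: dict[str, MtuParams],
    target_torques: dict[str, np.ndarray],
    weights: HybridWeights,
    experimental_excitations: dict[str, np.ndarray],
    include_passive: bool = True,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], HybridBreakdown]:
    """Frame-sequential hybrid optimisation over all MTU excitations.

    At each frame the full excitation vector (recorded *and*
    unrecorded MTUs) is optimised in [0, 1] against the hybrid
    objective; the recorded MTUs are pulled toward their experimental
    envelopes (L1), the unrecorded ones only pay the effort penalty.
    Activation-filter history propagates with the adjusted excitations
    of previous frames.  The absolute-deviation term is handled
    exactly with slack variables inside an SLSQP solve; in the
    tracking-dominated regime (beta, gamma < 1e-6) a bounded
    Gauss-Newton polish pushes the torque residual toward zero.

    Returns (adjusted/synthesized excitations, joint torques,
    objective breakdown).  A frame where the optimiser fails raises
    with the frame index and torque residual.
    """
    joints = list(target_torques)
    n = len(next(iter(target_torques.values())))
    labels = [g.label for g in mtu_set]
    m = len(labels)
    recorded = [i for i, g in enumerate(mtu_set) if g.label in experimental_excitations]
    n_rec = len(recorded)

    # precompute geometry, gains and passive torques for every frame
    gains = np.zeros((m, n))        # dF/da
    passive_force = np.zeros((m, n))
    arms = np.zeros((m, len(joints), n))
    filt = np.array([_filter_coeffs(params[lab]) for lab in labels])  # (m, 3): alpha, b1, b2
    shape = np.array([params[lab].shape_factor for lab in labels])
    for i, g in enumerate(mtu_set):
        p = params[g.label]
        l_mt, v_mt, r = mtu_state(thetas, omegas, g)
        l_fibre = l_mt - p.tendon_slack_scale * g.base_tendon_slack
        if np.any(l_fibre <= 0):
            raise ValueError(f"non-physical fibre length for MTU {g.label!r}")
        l_opt = p.optimal_fibre_scale * g.base_optimal_fibre
        l_norm = l_fibre / l_opt
        v_norm = v_mt / (_VMAX_LOPT * l_opt)
        scale = p.strength_coeff * g.max_isometric_force
        gains[i] = scale * _force_length(l_norm) * _force_velocity(v_norm)
        if include_passive:
            passive_force[i] = scale * _force_passive(l_norm)
        for jx, j in enumerate(joints):
            if j in r:
                arms[i, jx] = r[j]

    e_exp = np.zeros((m, n))
    for i in recorded:
        e_exp[i] = np.clip(np.asarray(experimental_excitations[labels[i]], dtype=float), 0, 1)

    tau_passive = np.einsum("mjn,mn->jn", arms, passive_force)
    tau_target = np.stack([np.asarray(target_torques[j], dtype=float) for j in joints])

    adjusted = np.zeros((m, n))
    torques_out = np.zeros((len(joints), n))
    mom_terms = np.zeros(n)
    sum_exc = 0.0
    track_emg = 0.0
    u_hist = np.zeros((m, 2))  # u(t-1), u(t-2)

    beta, gamma = weights.beta, weights.gamma
    tracking_dominated = max(beta, gamma) < 1e-6
    e_prev = e_exp[:, 0].copy()

    for t in range(n):
        g_t = gains[:, t]
        r_t = arms[:, :, t]  # (m, n_joints)
        tgt = tau_target[:, t] - tau_passive[:, t]
        alpha_g, b1, b2 = filt[:, 0], filt[:, 1], filt[:, 2]
        if t == 0:
            # steady-state initialisation: u(0) = e(0)
            drive = np.zeros(m)
            u_gain = np.ones(m)
        else:
            drive = -b1 * u_hist[:, 0] - b2 * u_hist[:, 1]
            u_gain = alpha_g

        def torque_residual(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            u = u_gain * e + drive
            uc = np.clip(u, 0.0, 1.0)
            a = np.where(
                np.abs(shape) < 1e-8, uc, np.expm1(shape * uc) / np.expm1(shape)
            )
            res = r_t.T @ (g_t * a) - tgt  # (n_joints,)
            nl = np.where(  # derivative of the nonlinearisation at uc
                np.abs(shape) < 1e-8, 1.0, shape * np.exp(shape * uc) / np.expm1(shape)
            )
            da_de = np.where((u >= 0) & (u <= 1), nl * u_gain, 0.0)
            jac = r_t.T * (g_t * da_de)  # (n_joints, m)
            return res, jac

        def objective(z: np.ndarray) -> tuple[float, np.ndarray]:
            e, s = z[:m], z[m:]
            res, jac = torque_residual(e)
            f = float(res @ res + beta * e @ e + gamma * s.sum())
            grad_e = 2.0 * (jac.T @ res) + 2.0 * beta * e
            grad = np.concatenate([grad_e, np.full(n_rec, gamma)])
            return f, grad

        e0 = np.clip(e_prev, 0, 1)
        s0 = np.abs(e0[recorded] - e_exp[recorded, t])
        z0 = np.concatenate([e0, s0])
        bounds = [(0.0, 1.0)] * m + [(0.0, 2.0)] * n_rec
        constraints = []
        if n_rec:
            rec_idx = np.array(recorded)
            ee = e_exp[rec_idx, t]

            def c_upper(z, rec_idx=rec_idx, ee=ee):
                return z[m:] - (z[rec_idx] - ee)

            def c_lower(z, rec_idx=rec_idx, ee=ee):
                return z[m:] + (z[rec_idx] - ee)

            j_upper = np.zeros((n_rec, m + n_rec))
            j_upper[np.arange(n_rec), rec_idx] = -1.0
            j_upper[np.arange(n_rec), m + np.arange(n_rec)] = 1.0
            j_lower = np.zeros((n_rec, m + n_rec))
            j_lower[np.arange(n_rec), rec_idx] = 1.0
            j_lower[np.arange(n_rec), m + np.arange(n_rec)] = 1.0
            constraints = [
                {"type": "ineq", "fun": c_upper, "jac": lambda z, J=j_upper: J},
                {"type": "ineq", "fun": c_lower, "jac": lambda z, J=j_lower: J},
            ]
        sol = optimize.minimize(
            objective, z0, jac=True, method="SLSQP", bounds=bounds,
            constraints=constraints, options={"maxiter": 200, "ftol": 1e-14},
        )

        def full_objective(e):
            res, _ = torque_residual(e)
            track_pen = gamma * np.abs(e[recorded] - e_exp[recorded, t]).sum() if n_rec else 0.0
            return float(res @ res + beta * e @ e + track_pen)

        candidates = [np.clip(e0, 0.0, 1.0), np.clip(sol.x[:m], 0.0, 1.0)]
        if n_rec:
            # exact-pinning candidate: optimal in the gamma-dominated limit,
            # where the generic solver becomes numerically stiff
            e_pin = np.clip(e0, 0.0, 1.0).copy()
            e_pin[recorded] = e_exp[recorded, t]
            candidates.append(e_pin)
        if tracking_dominated or not sol.success:
            # bounded Gauss-Newton polish of the torque residual alone;
            # with near-zero beta/gamma this is the dominant term, and on
            # an SLSQP breakdown it is a robust fallback (targets beyond
            # muscle capacity legitimately leave a saturated residual)
            def rfun(e):
                return torque_residual(e)[0]

            def rjac(e):
                return torque_residual(e)[1]

            if tracking_dominated:
                gn_kw = dict(xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=50)
            else:  # coarse rescue is enough when beta/gamma are not tiny
                gn_kw = dict(xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=10)
            gn = optimize.least_squares(
                rfun, candidates[-1], jac=rjac, bounds=(0.0, 1.0), **gn_kw,
            )
            candidates.append(np.clip(gn.x, 0.0, 1.0))
        scores = [full_objective(e) for e in candidates]
        e_t = candidates[int(np.argmin(scores))]
        res_t, _ = torque_residual(e_t)
        if not np.all(np.isfinite(e_t)) or not np.isfinite(min(scores)):
            raise RuntimeError(
                f"hybrid optimisation failed at frame {t}: "
                f"torque residual {np.linalg.norm(res_t, ord=np.inf):.3e} Nm ({sol.message})"
            )
        # commit the frame and propagate activation history
        u_t = np.clip(u_gain * e_t + drive, 0.0, 1.0)
        if t == 0:
            u_hist[:, 0] = u_t
            u_hist[:, 1] = u_t
        else:
            u_hist[:, 1] = u_hist[:, 0]
            u_hist[:, 0] = u_t
        adjusted[:, t] = e_t
        a_t = np.where(np.abs(shape) < 1e-8, u_t, np.expm1(shape * u_t) / np.expm1(shape))
        torques_out[:, t] = r_t.T @ (g_t * a_t) + tau_passive[:, t]
        mom_terms[t] = float(res_t @ res_t)
        sum_exc += float(e_t @ e_t)
        track_emg += float(np.abs(e_t[recorded] - e_exp[recorded, t]).sum())
        e_prev = e_t

    breakdown = HybridBreakdown(
        e_track_mom=float(mom_terms.sum()),
        e_sum_exc=sum_exc,
        e_track_emg=track_emg,
        beta=beta,
        gamma=gamma,
        per_frame_mom=mom_terms,
    )
    exc_out = {lab: adjusted[i] for i, lab in enumerate(labels)}
    torq_out = {j: torques_out[jx] for jx, j in enumerate(joints)}
    return exc_out, torq_out, breakdown


def tune_beta_gamma(
    solve_candidate,
    grid: list[tuple[float, float]],
) -> tuple[HybridWeights, list[dict]]:
    """Pick (beta, gamma) minimising min-max-normalised E_trackMOM + E_trackEMG.

    ``solve_candidate(weights)`` must run the hybrid solver over the
    calibration trials and return a :class:`HybridBreakdown` (or an
    object with ``e_track_mom``/``e_track_emg`` totals).  The full grid
    table is returned for logging.
    """
    if not grid:
        raise ValueError("empty (beta, gamma) grid")
    rows = []
    for b, g in grid:
        br = solve_candidate(HybridWeights(beta=b, gamma=g))
        rows.append({"beta": b, "gamma": g,
                     "e_track_mom": float(br.e_track_mom),
                     "e_track_emg": float(br.e_track_emg)})
    mom = np.array([r["e_track_mom"] for r in rows])
    emg = np.array([r["e_track_emg"] for r in rows])

    def norm(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        return np.zeros_like(v) if span == 0 else (v - v.min()) / span

    score = norm(mom) + norm(emg)
    for r, s in zip(rows, score):
        r["score"] = float(s)
    best = int(np.argmin(score))
    return HybridWeights(beta=rows[best]["beta"], gamma=rows[best]["gamma"]), rows
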