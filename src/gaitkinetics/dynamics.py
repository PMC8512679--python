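"""Planar sagittal rigid-body dynamics of the stance leg.

The stance-phase body is modelled as four planar segments: foot,
shank, thigh and a HAT lump (head-arms-trunk, which here also absorbs
the swing leg so that segment masses close the whole-body force
balance).  The lab frame has x anterior, y up and the ground at y = 0;
segment orientations ``phi`` are measured from the vertical, positive
when the proximal end leans anteriorly.  With z out of the page
(counter-clockwise moments positive), a segment's angular velocity is
``omega_z = -phi_dot``.

Reported joint torques follow the gait convention: positive means
extension at hip and knee and plantarflexion at the ankle.

Two complementary entry points make the module self-checking:

* :func:`forward_ground_reaction` synthesises the AP/vertical ground
  reaction force and the AP centre of pressure that are dynamically
  consistent with a given whole-body motion (used by the synthetic
  trial generator);
* :func:`inverse_dynamics` runs the distal-to-proximal Newton-Euler
  recursion (foot -> shank -> thigh) from measured GRF/COP and returns
  hip/knee/ankle torques.

On noiseless data the two are exact inverses of each other, which the
test suite exploits as a machine-precision round-trip oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentParams",
    "PlanarStanceKinematics",
    "JointTorques",
    "segment_parameters",
    "forward_ground_reaction",
    "inverse_dynamics",
    "hat_reference_hip_torque",
]

GRAVITY = 9.81  # m/s^2

# Anthropometric fractions adapted from Winter's standard tables.
# Segment masses are fractions of body mass; the HAT lump absorbs the
# remainder (trunk, head, arms and the swing leg).  Lengths are
# fractions of stature; COM locations are fractions of segment length
# from the proximal end; radii of gyration are about the segment COM.
_TABLES: dict[str, dict[str, float]] = {
    "winter_hat": {
        "foot_mass": 0.0145,
        "shank_mass": 0.0465,
        "thigh_mass": 0.100,
        "foot_len": 0.152,
        "shank_len": 0.246,
        "thigh_len": 0.245,
        "shank_com_prox": 0.433,
        "thigh_com_prox": 0.433,
        "foot_rog": 0.475,
        "shank_rog": 0.302,
        "thigh_rog": 0.323,
        "ankle_height": 0.039,     # of stature
        "ankle_forward": 0.20,     # of foot length, anterior of the heel
        "hat_com_dist": 0.30,      # of stature, above the hip joint
        "hat_rog": 0.50,           # of hat_com_dist
    }
}


@dataclass(frozen=True)
class SegmentParams:
    """Anthropometric parameters of the planar stance-leg model."""

    masses: dict[str, float]          # kg; keys foot/shank/thigh/hat
    lengths: dict[str, float]         # m; keys foot/shank/thigh
    com_from_distal: dict[str, float]  # shank/thigh, fraction of length
    inertias: dict[str, float]        # kg m^2 about COM; foot/shank/thigh/hat
    ankle_offset: tuple[float, float]   # foot frame, m from the heel
    foot_com_offset: tuple[float, float]  # foot frame, m from the heel
    hat_com_dist: float               # m above the hip along the HAT axis
    g: float = GRAVITY

    @property
    def total_mass(self) -> float:
        return float(sum(self.masses.values()))

    def __post_init__(self) -> None:
        for name, m in self.masses.items():
            if m < 0:
                raise ValueError(f"negative mass for segment {name!r}")
        for name, i in self.inertias.items():
            if i < 0:
                raise ValueError(f"negative inertia for segment {name!r}")


def segment_parameters(mass: float, height: float, table_id: str = "winter_hat") -> SegmentParams:
    """Build :class:`SegmentParams` from body mass (kg) and stature (m).

    The HAT lump takes ``mass`` minus the three stance-leg segments,
    so segment masses always sum to the subject mass exactly.
    """
    if mass <= 0 or height <= 0:
        raise ValueError("mass and height must be positive")
    try:
        tab = _TABLES[table_id]
    except KeyError:
        raise ValueError(
            f"unknown anthropometric table {table_id!r}; available: {sorted(_TABLES)}"
        ) from None
    m_foot = tab["foot_mass"] * mass
    m_shank = tab["shank_mass"] * mass
    m_thigh = tab["thigh_mass"] * mass
    m_hat = mass - m_foot - m_shank - m_thigh
    l_foot = tab["foot_len"] * height
    l_shank = tab["shank_len"] * height
    l_thigh = tab["thigh_len"] * height
    ankle_h = tab["ankle_height"] * height
    d_hat = tab["hat_com_dist"] * height
    inertias = {
        "foot": m_foot * (tab["foot_rog"] * l_foot) ** 2,
        "shank": m_shank * (tab["shank_rog"] * l_shank) ** 2,
        "thigh": m_thigh * (tab["thigh_rog"] * l_thigh) ** 2,
        "hat": m_hat * (tab["hat_rog"] * d_hat) ** 2,
    }
    return SegmentParams(
        masses={"foot": m_foot, "shank": m_shank, "thigh": m_thigh, "hat": m_hat},
        lengths={"foot": l_foot, "shank": l_shank, "thigh": l_thigh},
        com_from_distal={
            "shank": 1.0 - tab["shank_com_prox"],
            "thigh": 1.0 - tab["thigh_com_prox"],
        },
        inertias=inertias,
        ankle_offset=(tab["ankle_forward"] * l_foot, ankle_h),
        foot_com_offset=(0.5 * l_foot, 0.5 * ankle_h),
        hat_com_dist=d_hat,
    )


@dataclass
class PlanarStanceKinematics:
    """Segment-level description of one stance phase.

    Carries segment orientations (rad, from vertical, anterior lean
    positive) with their time derivatives, plus the ankle-point
    trajectory.  All other points (knee, hip, segment COMs, heel) are
    derived analytically through the kinematic chain, which keeps
    forward and inverse dynamics mutually consistent to round-off.
    """

    t: np.ndarray
    fs: float
    phi_shank: np.ndarray
    phi_thigh: np.ndarray
    phi_hat: np.ndarray
    dphi_shank: np.ndarray
    dphi_thigh: np.ndarray
    dphi_hat: np.ndarray
    ddphi_shank: np.ndarray
    ddphi_thigh: np.ndarray
    ddphi_hat: np.ndarray
    ankle_pos: np.ndarray  # (n, 2)
    ankle_vel: np.ndarray
    ankle_acc: np.ndarray
    phi_foot: np.ndarray | None = None     # ccw-positive; None -> flat foot
    dphi_foot: np.ndarray | None = None
    ddphi_foot: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if self.phi_foot is None:
            self.phi_foot = np.zeros(n)
            self.dphi_foot = np.zeros(n)
            self.ddphi_foot = np.zeros(n)
        for name in (
            "phi_shank", "phi_thigh", "phi_hat",
            "dphi_shank", "dphi_thigh", "dphi_hat",
            "ddphi_shank", "ddphi_thigh", "ddphi_hat",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in {name}")
        if self.ankle_pos.shape != (n, 2):
            raise ValueError("ankle_pos must have shape (n, 2)")

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass
class JointTorques:
    """Sagittal joint torque series (Nm); positive = extension/plantarflexion."""

    tau_hip: np.ndarray
    tau_knee: np.ndarray
    tau_ankle: np.ndarray

    def normalised(self, mass: float) -> "JointTorques":
        """Return torques divided by body mass (Nm/kg)."""
        return JointTorques(self.tau_hip / mass, self.tau_knee / mass, self.tau_ankle / mass)

    def as_array(self) -> np.ndarray:
        """Stack as (3, n) in the order hip, knee, ankle."""
        return np.stack([self.tau_hip, self.tau_knee, self.tau_ankle])


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the 2-D cross product, elementwise over (n, 2) arrays."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _seg_dir(phi: np.ndarray) -> np.ndarray:
    """Unit vector along a leg segment (distal -> proximal)."""
    return np.stack([np.sin(phi), np.cos(phi)], axis=-1)


def _chain(kin: PlanarStanceKinematics, seg: SegmentParams) -> dict[str, np.ndarray]:
    """Positions, velocities and accelerations of every point of interest."""
    out: dict[str, np.ndarray] = {}

    def offset(phi, dphi, ddphi, length):
        u = _seg_dir(phi)
        udot = np.stack([np.cos(phi), -np.sin(phi)], axis=-1)
        vel = length * dphi[:, None] * udot
        acc = length * (ddphi[:, None] * udot - dphi[:, None] ** 2 * u)
        return length * u, vel, acc

    # shank chain: ankle -> knee, COM measured from the distal (ankle) end
    for frac, key in ((seg.com_from_distal["shank"], "shank_com"), (1.0, "knee")):
        d, v, a = offset(kin.phi_shank, kin.dphi_shank, kin.ddphi_shank, frac * seg.lengths["shank"])
        out[f"{key}_pos"] = kin.ankle_pos + d
        out[f"{key}_vel"] = kin.ankle_vel + v
        out[f"{key}_acc"] = kin.ankle_acc + a
    # thigh chain: knee -> hip
    for frac, key in ((seg.com_from_distal["thigh"], "thigh_com"), (1.0, "hip")):
        d, v, a = offset(kin.phi_thigh, kin.dphi_thigh, kin.ddphi_thigh, frac * seg.lengths["thigh"])
        out[f"{key}_pos"] = out["knee_pos"] + d
        out[f"{key}_vel"] = out["knee_vel"] + v
        out[f"{key}_acc"] = out["knee_acc"] + a
    # HAT lump above the hip
    d, v, a = offset(kin.phi_hat, kin.dphi_hat, kin.ddphi_hat, seg.hat_com_dist)
    out["hat_com_pos"] = out["hip_pos"] + d
    out["hat_com_vel"] = out["hip_vel"] + v
    out["hat_com_acc"] = out["hip_acc"] + a

    # foot: rigid body about the ankle; phi_foot is a ccw-positive lab angle
    phi_f, dphi_f, ddphi_f = kin.phi_foot, kin.dphi_foot, kin.ddphi_foot
    cosf, sinf = np.cos(phi_f), np.sin(phi_f)

    def foot_point(b: tuple[float, float]):
        bx = b[0] - seg.ankle_offset[0]
        by = b[1] - seg.ankle_offset[1]
        r = np.stack([cosf * bx - sinf * by, sinf * bx + cosf * by], axis=-1)
        perp = np.stack([-r[:, 1], r[:, 0]], axis=-1)
        pos = kin.ankle_pos + r
        vel = kin.ankle_vel + (-dphi_f)[:, None] * perp
        acc = kin.ankle_acc + (-ddphi_f)[:, None] * perp - dphi_f[:, None] ** 2 * r
        return pos, vel, acc

    out["heel_pos"], out["heel_vel"], out["heel_acc"] = foot_point((0.0, 0.0))
    out["foot_com_pos"], out["foot_com_vel"], out["foot_com_acc"] = foot_point(seg.foot_com_offset)

    # angular accelerations about z (ccw positive): omega_z = -phi_dot for
    # vertical-referenced segments, +phi_dot for the ccw foot angle
    out["alpha_foot"] = kin.ddphi_foot
    out["alpha_shank"] = -kin.ddphi_shank
    out["alpha_thigh"] = -kin.ddphi_thigh
    out["alpha_hat"] = -kin.ddphi_hat
    return out


def forward_ground_reaction(
    kin: PlanarStanceKinematics, seg: SegmentParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dynamically consistent GRF_AP, GRF_V (N) and heel-referenced COP_AP (m).

    The GRF follows from the whole-body Newton equation
    ``GRF = sum_s m_s (a_s - g)`` and the COP from the whole-body
    moment balance about the ground contact line (ground plane y = 0).
    Raises if the required vertical force is not positive (flight: the
    stance assumption is violated).
    """
    ch = _chain(kin, seg)
    g_vec = np.array([0.0, -seg.g])
    grf = np.zeros((kin.n, 2))
    moment = np.zeros(kin.n)  # net rate of angular momentum minus gravity moment, about lab origin
    for name in ("foot", "shank", "thigh", "hat"):
        m = seg.masses[name]
        inertia = seg.inertias[name]
        pos = ch[f"{name}_com_pos"]
        acc = ch[f"{name}_com_acc"]
        grf += m * (acc - g_vec)
        moment += inertia * ch[f"alpha_{name}"] + m * _cross2(pos, acc) - m * _cross2(pos, g_vec)
    grf_v = grf[:, 1]
    if np.any(grf_v <= 0):
        i = int(np.argmin(grf_v))
        raise ValueError(
            f"stance assumption violated: required vertical GRF {grf_v[i]:.2f} N "
            f"at sample {i} is not positive"
        )
    # moment of GRF applied at (cop_x, 0): cross((cop_x, 0), grf) = cop_x * grf_v
    cop_x = moment / grf_v
    cop_ap = cop_x - ch["heel_pos"][:, 0]
    return grf[:, 0], grf_v, cop_ap


def hat_reference_hip_torque(kin: PlanarStanceKinematics, seg: SegmentParams) -> np.ndarray:
    """Hip torque required by the HAT segment alone (top-down check).

    Equals the bottom-up Newton-Euler hip torque whenever the applied
    GRF/COP are consistent with the whole-body dynamics; used as an
    internal consistency oracle by the synthetic generator.
    """
    ch = _chain(kin, seg)
    g_vec = np.array([0.0, -seg.g])
    m = seg.masses["hat"]
    f_hip = m * (ch["hat_com_acc"] - g_vec)  # force thigh exerts on HAT
    lever = ch["hip_pos"] - ch["hat_com_pos"]
    # I alpha = -M_hip_on_thigh + cross(lever, f_hip)  (HAT receives -M by reaction)
    m_hip = _cross2(lever, f_hip) - seg.inertias["hat"] * ch["alpha_hat"]
    return -m_hip  # extension-positive convention


def inverse_dynamics(
    kin: PlanarStanceKinematics,
    grf_ap: np.ndarray,
    grf_v: np.ndarray,
    cop_ap: np.ndarray,
    seg: SegmentParams,
    per_mass: bool = False,
) -> JointTorques:
    """Distal-to-proximal Newton-Euler recursion: foot -> shank -> thigh.

    Parameters
    ----------
    grf_ap, grf_v
        Ground reaction force components, N (AP anterior-positive,
        vertical up-positive).  Any ML component is ignored by the
        planar recursion.
    cop_ap
        Centre of pressure, m, anterior-positive *relative to the heel*.
    per_mass
        If true, return torques normalised to body mass (Nm/kg).
    """
    for name, arr in (("grf_ap", grf_ap), ("grf_v", grf_v), ("cop_ap", cop_ap)):
        arr = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in input channel {name!r}")
    ch = _chain(kin, seg)
    heel_x = ch["heel_pos"][:, 0]
    foot_len = seg.lengths["foot"]
    if np.any(cop_ap < -0.02) or np.any(cop_ap > foot_len + 0.05):
        warnings.warn(
            "COP_AP outside the plausible foot band "
            f"[-0.02, {foot_len + 0.05:.3f}] m (min {np.min(cop_ap):.3f}, "
            f"max {np.max(cop_ap):.3f}); proceeding without clamping",
            stacklevel=2,
        )
    g_vec = np.array([0.0, -seg.g])
    f_grf = np.stack([np.asarray(grf_ap, float), np.asarray(grf_v, float)], axis=-1)
    r_cop = np.stack([heel_x + cop_ap, np.zeros(kin.n)], axis=-1)

    # --- foot ---
    m_f = seg.masses["foot"]
    f_ankle = m_f * (ch["foot_com_acc"] - g_vec) - f_grf  # shank on foot
    m_ankle = (
        seg.inertias["foot"] * ch["alpha_foot"]
        - _cross2(r_cop - ch["foot_com_pos"], f_grf)
        - _cross2(kin.ankle_pos - ch["foot_com_pos"], f_ankle)
    )
    # --- shank ---
    m_s = seg.masses["shank"]
    f_knee = m_s * (ch["shank_com_acc"] - g_vec) + f_ankle  # thigh on shank
    m_knee = (
        seg.inertias["shank"] * ch["alpha_shank"]
        + m_ankle
        - _cross2(ch["knee_pos"] - ch["shank_com_pos"], f_knee)
        + _cross2(kin.ankle_pos - ch["shank_com_pos"], f_ankle)
    )
    # --- thigh ---
    m_t = seg.masses["thigh"]
    f_hip = m_t * (ch["thigh_com_acc"] - g_vec) + f_knee  # HAT on thigh
    m_hip = (
        seg.inertias["thigh"] * ch["alpha_thigh"]
        + m_knee
        - _cross2(ch["hip_pos"] - ch["thigh_com_pos"], f_hip)
        + _cross2(ch["knee_pos"] - ch["thigh_com_pos"], f_knee)
    )

    # map internal z-moments to the gait convention (positive = extension /
    # plantarflexion): the joint power analysis gives tau_hip = -M_hip,
    # tau_knee = +M_knee, tau_ankle = -M_ankle
    tq = JointTorques(tau_hip=-m_hip, tau_knee=m_knee, tau_ankle=-m_ankle)
    if per_mass:
        tq = tq.normalised(seg.total_mass)
    return tq
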