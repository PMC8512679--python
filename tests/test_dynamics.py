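"""Planar stance-leg dynamics: anthropometrics, statics, recursion, sensitivity."""

import numpy as np
import pytest

from gaitkinetics.dynamics import (
    JointTorques,
    PlanarStanceKinematics,
    SegmentParams,
    forward_ground_reaction,
    hat_reference_hip_torque,
    inverse_dynamics,
    segment_parameters,
)


def static_kinematics(seg, n=5, phi_shank=0.0, phi_thigh=0.0, phi_hat=0.0):
    """Motionless posture: all velocities and accelerations zero."""
    z = np.zeros(n)
    ankle = np.tile(np.asarray(seg.ankle_offset), (n, 1))
    return PlanarStanceKinematics(
        t=np.arange(n) / 100.0, fs=100.0,
        phi_shank=z + phi_shank, phi_thigh=z + phi_thigh, phi_hat=z + phi_hat,
        dphi_shank=z.copy(), dphi_thigh=z.copy(), dphi_hat=z.copy(),
        ddphi_shank=z.copy(), ddphi_thigh=z.copy(), ddphi_hat=z.copy(),
        ankle_pos=ankle, ankle_vel=np.zeros((n, 2)), ankle_acc=np.zeros((n, 2)),
    )


class TestSegmentParameters:
    def test_mass_closure_is_exact(self):
        seg = segment_parameters(71.0, 1.71)
        assert sum(seg.masses.values()) == pytest.approx(71.0, abs=1e-12)

    def test_foot_mass_fraction(self):
        # Winter-style foot mass fraction 0.0145 of body mass
        seg = segment_parameters(70.0, 1.75)
        assert seg.masses["foot"] == pytest.approx(70.0 * 0.0145)

    def test_linearity_in_mass(self):
        a = segment_parameters(60.0, 1.70)
        b = segment_parameters(120.0, 1.70)
        for name in a.masses:
            assert b.masses[name] == pytest.approx(2 * a.masses[name])
            assert b.inertias[name] == pytest.approx(2 * a.inertias[name])

    def test_unknown_table_raises(self):
        with pytest.raises(ValueError, match="unknown anthropometric table"):
            segment_parameters(70.0, 1.75, table_id="nonexistent")

    def test_positivity_validation(self):
        with pytest.raises(ValueError):
            segment_parameters(-1.0, 1.7)


class TestForwardGroundReaction:
    def test_static_standing(self):
        seg = segment_parameters(70.0, 1.75)
        kin = static_kinematics(seg)
        grf_ap, grf_v, cop = forward_ground_reaction(kin, seg)
        assert np.allclose(grf_v, 70.0 * seg.g, atol=1e-9)
        assert np.allclose(grf_ap, 0.0, atol=1e-9)

    def test_static_cop_under_whole_body_com(self):
        # with zero accelerations the COP sits exactly below the COM
        seg = segment_parameters(70.0, 1.75)
        kin = static_kinematics(seg, phi_hat=0.1)
        from gaitkinetics.dynamics import _chain

        ch = _chain(kin, seg)
        com_x = sum(seg.masses[s] * ch[f"{s}_com_pos"][:, 0]
                    for s in ("foot", "shank", "thigh", "hat")) / seg.total_mass
        _, _, cop = forward_ground_reaction(kin, seg)
        heel_x = ch["heel_pos"][:, 0]
        assert np.allclose(cop + heel_x, com_x, atol=1e-12)

    def test_added_vertical_acceleration(self):
        # a shared vertical COM acceleration a gives GRF_V = m (g + a)
        seg = segment_parameters(70.0, 1.75)
        kin = static_kinematics(seg)
        a = 1.3
        kin.ankle_acc = np.tile([0.0, a], (kin.n, 1))
        _, grf_v, _ = forward_ground_reaction(kin, seg)
        assert np.allclose(grf_v, 70.0 * (seg.g + a), atol=1e-9)

    def test_flight_raises(self):
        seg = segment_parameters(70.0, 1.75)
        kin = static_kinematics(seg)
        kin.ankle_acc = np.tile([0.0, -2 * seg.g], (kin.n, 1))
        with pytest.raises(ValueError, match="stance assumption"):
            forward_ground_reaction(kin, seg)


def massless_foot_params(mass=70.0, height=1.75):
    seg = segment_parameters(mass, height)
    masses = dict(seg.masses)
    masses["hat"] += masses["foot"]
    masses["foot"] = 0.0
    inertias = dict(seg.inertias)
    inertias["foot"] = 0.0
    return SegmentParams(
        masses=masses, lengths=seg.lengths,
        com_from_distal=seg.com_from_distal, inertias=inertias,
        ankle_offset=seg.ankle_offset, foot_com_offset=seg.foot_com_offset,
        hat_com_dist=seg.hat_com_dist,
    )


class TestInverseDynamics:
    def test_static_ankle_torque_hand_value(self):
        # massless foot, 700 N vertical at 5 cm anterior of the ankle:
        # plantarflexion torque +35 Nm
        seg = massless_foot_params()
        kin = static_kinematics(seg)
        n = kin.n
        cop_ap = np.full(n, seg.ankle_offset[0] + 0.05)  # heel-referenced
        tq = inverse_dynamics(kin, np.zeros(n), np.full(n, 700.0), cop_ap, seg)
        assert np.allclose(tq.tau_ankle, 35.0, atol=1e-9)

    def test_implausible_cop_warns(self):
        seg = massless_foot_params()
        kin = static_kinematics(seg)
        n = kin.n
        with pytest.warns(UserWarning, match="COP_AP"):
            inverse_dynamics(kin, np.zeros(n), np.full(n, 700.0),
                             np.full(n, seg.lengths["foot"] + 0.2), seg)

    def test_cop_shift_sensitivity_is_grfv_times_delta(self, noiseless_trial, subject):
        tr = noiseless_trial.truth
        kin = tr["kinematics"]
        seg = subject.segment_params
        grf_ap, grf_v = tr["grf"][0], tr["grf"][2]
        cop = tr["cop"][0] / 1000.0
        delta = 0.004
        t0 = inverse_dynamics(kin, grf_ap, grf_v, cop, seg)
        t1 = inverse_dynamics(kin, grf_ap, grf_v, cop + delta, seg)
        assert np.allclose(t1.tau_ankle - t0.tau_ankle, grf_v * delta, atol=1e-9)

    def test_round_trip_recovers_truth_torques(self, noiseless_trial, subject):
        tr = noiseless_trial.truth
        tq = inverse_dynamics(tr["kinematics"], tr["grf"][0], tr["grf"][2],
                              tr["cop"][0] / 1000.0, subject.segment_params)
        ref = tr["torques"]
        assert np.max(np.abs(tq.as_array() - ref.as_array())) < 1e-8

    def test_hat_top_down_consistency(self, noiseless_trial, subject):
        tr = noiseless_trial.truth
        hip = hat_reference_hip_torque(tr["kinematics"], subject.segment_params)
        assert np.max(np.abs(hip - tr["torques"].tau_hip)) < 1e-8

    def test_grf_error_propagates_more_to_the_hip(self, noiseless_trial, subject):
        # the foot is solved first: an AP-force error works through the
        # full joint-height lever at the hip but a short one at the ankle
        tr = noiseless_trial.truth
        kin, seg = tr["kinematics"], subject.segment_params
        grf_ap, grf_v = tr["grf"][0], tr["grf"][2]
        cop = tr["cop"][0] / 1000.0
        base = inverse_dynamics(kin, grf_ap, grf_v, cop, seg)
        pert = inverse_dynamics(kin, grf_ap + 10.0, grf_v, cop, seg)
        d_hip = np.mean(np.abs(pert.tau_hip - base.tau_hip))
        d_ankle = np.mean(np.abs(pert.tau_ankle - base.tau_ankle))
        assert d_hip > d_ankle

    def test_cop_error_only_enters_through_the_grf_moment(self, noiseless_trial, subject):
        # shifting the COP changes no segment force balance, so every
        # joint torque shifts by exactly the transported GRF moment
        tr = noiseless_trial.truth
        kin, seg = tr["kinematics"], subject.segment_params
        grf_ap, grf_v = tr["grf"][0], tr["grf"][2]
        cop = tr["cop"][0] / 1000.0
        delta = 0.006
        base = inverse_dynamics(kin, grf_ap, grf_v, cop, seg)
        pert = inverse_dynamics(kin, grf_ap, grf_v, cop + delta, seg)
        assert np.allclose(pert.tau_ankle - base.tau_ankle, grf_v * delta, atol=1e-9)
        assert np.allclose(pert.tau_knee - base.tau_knee, -grf_v * delta, atol=1e-9)

    def test_non_finite_input_raises_with_channel_name(self, noiseless_trial, subject):
        tr = noiseless_trial.truth
        bad = tr["grf"][2].copy()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="grf_v"):
            inverse_dynamics(tr["kinematics"], tr["grf"][0], bad,
                             tr["cop"][0] / 1000.0, subject.segment_params)

    def test_per_mass_normalisation(self, noiseless_trial, subject):
        tr = noiseless_trial.truth
        tq = inverse_dynamics(tr["kinematics"], tr["grf"][0], tr["grf"][2],
                              tr["cop"][0] / 1000.0, subject.segment_params,
                              per_mass=True)
        assert np.allclose(tq.tau_hip * subject.mass, tr["torques"].tau_hip)


def test_joint_torques_container():
    tq = JointTorques(np.ones(3), np.full(3, 2.0), np.full(3, 3.0))
    arr = tq.normalised(2.0).as_array()
    assert arr.shape == (3, 3)
    assert np.allclose(arr[0], 0.5)
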