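"""Hill-type MTU model, activation dynamics, calibration, hybrid optimisation."""

from types import SimpleNamespace

import numpy as np
import pytest

from gaitkinetics.muscle import (
    HybridBreakdown,
    HybridWeights,
    MtuGeometry,
    MtuParams,
    PARAM_BOUNDS,
    activation_dynamics,
    emg_driven_torques,
    expand_channel_excitations,
    mtu_force,
    mtu_state,
    tune_beta_gamma,
)


def toy_geometry(r_ankle=0.05, fmax=100.0, label="toy", channel=None):
    """Constant-moment-arm single-DoF MTU with l~ = 1 at theta = 0."""
    return MtuGeometry(
        label=label, l0=0.30, base_optimal_fibre=0.10, base_tendon_slack=0.20,
        max_isometric_force=fmax, dof_coeffs={"ankle": (-r_ankle, 0.0)},
        recorded_channel=channel,
    )


NEUTRAL = MtuParams(tendon_slack_scale=1.0, optimal_fibre_scale=1.0,
                    strength_coeff=1.0, c1=0.0, c2=0.0, shape_factor=-1e-12)


class TestMtuParams:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            MtuParams(strength_coeff=3.0)
        with pytest.raises(ValueError):
            MtuParams(shape_factor=1.0)
        for name, (lo, hi) in PARAM_BOUNDS.items():
            MtuParams(**{name: lo})
            MtuParams(**{name: hi})

    def test_vector_round_trip(self):
        p = MtuParams(1.02, 0.99, 1.5, -0.3, -0.2, -2.0)
        assert MtuParams.from_vector(p.as_vector()) == p


class TestActivationDynamics:
    def test_unit_steady_state(self):
        p = MtuParams(c1=-0.4, c2=-0.3, shape_factor=-1e-12)
        a = activation_dynamics(np.ones(200), p)
        assert a[-1] == pytest.approx(1.0, abs=1e-9)

    def test_nonlinearisation_hand_value(self):
        # A = -3, u = 0.5: a = (e^-1.5 - 1)/(e^-3 - 1) = 0.81757...
        p = MtuParams(c1=0.0, c2=0.0, shape_factor=-3.0)
        a = activation_dynamics(np.full(10, 0.5), p)
        expected = np.expm1(-1.5) / np.expm1(-3.0)
        assert np.allclose(a, expected, atol=1e-12)
        assert expected == pytest.approx(0.8176, abs=1e-4)

    def test_shape_factor_zero_limit(self):
        p = MtuParams(c1=0.0, c2=0.0, shape_factor=-1e-8)
        u = np.linspace(0, 1, 50)
        assert np.allclose(activation_dynamics(u, p), u, atol=1e-9)

    def test_output_stays_in_unit_interval(self, rng):
        for _ in range(5):
            c1, c2 = rng.uniform(-0.9, 0.9, 2)
            p = MtuParams(c1=c1, c2=c2, shape_factor=rng.uniform(-5, -0.1))
            e = rng.uniform(0, 1, 150)
            a = activation_dynamics(e, p)
            assert a.min() >= 0.0 and a.max() <= 1.0

    def test_unstable_filter_raises(self):
        bad = SimpleNamespace(c1=1.2, c2=0.0, shape_factor=-1.0)
        with pytest.raises(ValueError, match="unstable"):
            activation_dynamics(np.zeros(10), bad)

    def test_excitation_out_of_range_raises(self):
        with pytest.raises(ValueError, match="0, 1"):
            activation_dynamics(np.array([0.5, 1.5]), NEUTRAL)


class TestMtuState:
    def test_moment_arm_matches_numeric_derivative(self):
        g = MtuGeometry(label="x", l0=0.3, base_optimal_fibre=0.1,
                        base_tendon_slack=0.2, max_isometric_force=100.0,
                        dof_coeffs={"knee": (-0.04, 0.006)})
        h = 1e-6
        for th in (-0.5, 0.0, 0.7):
            l_p = g.length({"knee": np.array([th + h])})
            l_m = g.length({"knee": np.array([th - h])})
            numeric = -(l_p - l_m) / (2 * h)
            assert abs(g.moment_arm("knee", np.array([th]))[0] - numeric[0]) < 1e-6

    def test_zero_velocity_zero_lengthening(self, rng):
        g = toy_geometry()
        _, v, _ = mtu_state({"ankle": rng.uniform(-0.5, 0.5, 20)},
                            {"ankle": np.zeros(20)}, g)
        assert np.allclose(v, 0.0)

    def test_constant_length_mtu_has_zero_arms(self):
        g = MtuGeometry(label="c", l0=0.3, base_optimal_fibre=0.1,
                        base_tendon_slack=0.2, max_isometric_force=50.0,
                        dof_coeffs={"hip": (0.0, 0.0)})
        _, v, arms = mtu_state({"hip": np.linspace(-1, 1, 9)},
                               {"hip": np.ones(9)}, g)
        assert np.allclose(arms["hip"], 0.0)
        assert np.allclose(v, 0.0)

    def test_power_balance(self, rng):
        # sum_j tau_j omega_j = -F v_mt for each MTU at every frame
        g = MtuGeometry(label="bi", l0=0.4, base_optimal_fibre=0.1,
                        base_tendon_slack=0.3, max_isometric_force=200.0,
                        dof_coeffs={"knee": (-0.04, 0.004), "ankle": (0.03, -0.002)})
        thetas = {j: rng.uniform(-0.5, 0.5, 30) for j in ("knee", "ankle")}
        omegas = {j: rng.uniform(-2, 2, 30) for j in ("knee", "ankle")}
        l_mt, v_mt, arms = mtu_state(thetas, omegas, g)
        force = mtu_force(np.full(30, 0.6), l_mt, v_mt, g, NEUTRAL)
        power_joints = sum(arms[j] * force * omegas[j] for j in arms)
        assert np.allclose(power_joints, -force * v_mt, atol=1e-9)


class TestMtuForce:
    def test_passive_free_at_optimal_length_zero_activation(self):
        g = toy_geometry()
        f = mtu_force(np.zeros(5), np.full(5, 0.30), np.zeros(5), g, NEUTRAL)
        assert np.allclose(f, 0.0)

    def test_maximal_isometric_force_normalisation(self):
        g = toy_geometry(fmax=123.0)
        f = mtu_force(np.ones(3), np.full(3, 0.30), np.zeros(3), g, NEUTRAL)
        assert np.allclose(f, 123.0, atol=1e-9)

    def test_strength_coefficient_scales_linearly(self):
        g = toy_geometry(fmax=100.0)
        strong = MtuParams(strength_coeff=2.0, c1=0.0, c2=0.0, shape_factor=-1e-12)
        f1 = mtu_force(np.full(3, 0.5), np.full(3, 0.305), np.full(3, 0.01), g, NEUTRAL)
        f2 = mtu_force(np.full(3, 0.5), np.full(3, 0.305), np.full(3, 0.01), g, strong)
        assert np.allclose(f2, 2.0 * f1)

    def test_non_physical_fibre_length_raises(self):
        g = toy_geometry()
        with pytest.raises(ValueError, match="toy"):
            mtu_force(np.ones(2), np.full(2, 0.19), np.zeros(2), g, NEUTRAL)

    def test_force_is_nonnegative(self, rng):
        g = toy_geometry()
        l = rng.uniform(0.25, 0.36, 50)
        v = rng.uniform(-0.3, 0.3, 50)
        f = mtu_force(rng.uniform(0, 1, 50), l, v, g, NEUTRAL)
        assert np.all(f >= 0)


class TestEmgDrivenTorques:
    def test_zero_excitation_passive_disabled_gives_zero(self):
        g = toy_geometry()
        tq = emg_driven_torques({"ankle": np.zeros(10)}, {"ankle": np.zeros(10)},
                                [g], {"toy": NEUTRAL},
                                {"toy": np.zeros(10)}, include_passive=False)
        assert np.allclose(tq["ankle"], 0.0)

    def test_single_mtu_torque_is_arm_times_force(self):
        # r = 0.05 m, F = F_max = 100 N at full activation -> 5 Nm
        g = toy_geometry(r_ankle=0.05, fmax=100.0)
        tq = emg_driven_torques({"ankle": np.zeros(6)}, {"ankle": np.zeros(6)},
                                [g], {"toy": NEUTRAL}, {"toy": np.ones(6)})
        assert np.allclose(tq["ankle"], 5.0, atol=1e-9)

    def test_equal_antagonists_cancel(self):
        a = toy_geometry(r_ankle=0.05, label="ag")
        b = toy_geometry(r_ankle=-0.05, label="an")
        e = np.full(8, 0.4)
        tq = emg_driven_torques({"ankle": np.zeros(8)}, {"ankle": np.zeros(8)},
                                [a, b], {"ag": NEUTRAL, "an": NEUTRAL},
                                {"ag": e, "an": e})
        assert np.allclose(tq["ankle"], 0.0, atol=1e-9)

    def test_missing_excitation_names_the_mtu(self):
        g = toy_geometry()
        with pytest.raises(ValueError, match="toy"):
            emg_driven_torques({"ankle": np.zeros(4)}, {"ankle": np.zeros(4)},
                               [g], {"toy": NEUTRAL}, {})


class TestExpandChannelExcitations:
    def test_one_channel_drives_several_mtus(self):
        env = {"gastrocnemius_medialis": np.array([0.1, 0.2])}
        exc = expand_channel_excitations(env, {"gastrocnemius_medialis": ["med", "lat"]},
                                         ["med", "lat", "deep"])
        assert np.array_equal(exc["med"], exc["lat"])
        assert np.allclose(exc["deep"], 0.0)

    def test_default_none_leaves_unrecorded_out(self):
        env = {"soleus": np.zeros(3)}
        exc = expand_channel_excitations(env, {"soleus": ["sol"]}, ["sol", "deep"],
                                         default=None)
        assert "deep" not in exc


class TestHybridDegenerateEquivalence:
    def test_large_gamma_tracks_experimental_envelopes(self, subject, noiseless_trial):
        # gamma -> inf with every MTU recorded: the hybrid torques equal
        # the plain EMG-driven torques of the experimental envelopes
        from gaitkinetics.muscle import hybrid_solve

        tr = noiseless_trial.truth
        sl = slice(0, 12)
        thetas = {j: v[sl] for j, v in tr["theta"].items()}
        omegas = {j: v[sl] for j, v in tr["omega"].items()}
        exc_exp = {lab: v[sl] for lab, v in tr["excitations"].items()}
        target = {"hip": tr["torques"].tau_hip[sl], "knee": tr["torques"].tau_knee[sl],
                  "ankle": tr["torques"].tau_ankle[sl]}
        adj, torques, _ = hybrid_solve(
            thetas, omegas, subject.mtu_set, subject.truth_params, target,
            HybridWeights(beta=0.0, gamma=1e6), exc_exp,
        )
        ref = emg_driven_torques(thetas, omegas, subject.mtu_set,
                                 subject.truth_params, exc_exp)
        for j in target:
            assert np.allclose(torques[j], ref[j], atol=2e-2)
        for lab in exc_exp:
            assert np.max(np.abs(adj[lab] - exc_exp[lab])) < 1e-3


class TestTuneBetaGamma:
    def _fake_solver(self, table):
        def solve(w):
            mom, emg = table[(w.beta, w.gamma)]
            return HybridBreakdown(e_track_mom=mom, e_sum_exc=0.0,
                                   e_track_emg=emg, beta=w.beta, gamma=w.gamma)
        return solve

    def test_single_candidate_returned(self):
        w, rows = tune_beta_gamma(self._fake_solver({(1.0, 2.0): (3.0, 4.0)}),
                                  [(1.0, 2.0)])
        assert (w.beta, w.gamma) == (1.0, 2.0)
        assert len(rows) == 1

    def test_argmin_of_normalised_sum(self):
        table = {(0.1, 1.0): (10.0, 1.0), (1.0, 1.0): (5.0, 5.0), (2.0, 0.5): (1.0, 10.0)}
        w, rows = tune_beta_gamma(self._fake_solver(table), list(table))
        best = min(rows, key=lambda r: r["score"])
        assert (w.beta, w.gamma) == (best["beta"], best["gamma"])

    def test_limit_grid_trade_off(self, subject, noiseless_trial):
        # tracking-only vs EMG-pinning weights trade E_trackEMG against E_sumEXC
        from gaitkinetics.muscle import hybrid_solve

        tr = noiseless_trial.truth
        sl = slice(20, 32)
        thetas = {j: v[sl] for j, v in tr["theta"].items()}
        omegas = {j: v[sl] for j, v in tr["omega"].items()}
        exc_exp = {lab: v[sl] for lab, v in tr["excitations"].items()}
        target = {"hip": tr["torques"].tau_hip[sl], "knee": tr["torques"].tau_knee[sl],
                  "ankle": tr["torques"].tau_ankle[sl]}

        def run(w):
            return hybrid_solve(thetas, omegas, subject.mtu_set,
                                subject.truth_params, target, w, exc_exp)[2]

        pin_emg = run(HybridWeights(beta=0.0, gamma=1e6))
        pin_eff = run(HybridWeights(beta=1e6, gamma=0.0))
        assert pin_emg.e_track_emg < pin_eff.e_track_emg
        assert pin_eff.e_sum_exc < pin_emg.e_sum_exc

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            tune_beta_gamma(lambda w: None, [])


def test_weights_validation():
    with pytest.raises(ValueError):
        HybridWeights(beta=-1.0)
    with pytest.raises(ValueError):
        HybridWeights(alpha=2.0)
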