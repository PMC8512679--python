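"""Synthetic subjects and stance trials: determinism, invariants, consistency."""

import numpy as np
import pytest

from gaitkinetics.muscle import emg_driven_torques
from gaitkinetics.synthetic import (
    EMG_CHANNELS,
    NoiseConfig,
    excitations_from_torques,
    generate_stance_trial,
    generate_subject,
    synthesize_raw_emg,
)

SILENT = NoiseConfig(0, 0, 0, 0, 0)


class TestGenerateSubject:
    def test_seed_determinism_bytewise(self):
        assert generate_subject(7).serialise() == generate_subject(7).serialise()

    def test_anthropometry_within_ranges(self):
        ranges = {"mass": (60.0, 70.0), "height": (1.60, 1.70)}
        for seed in range(5):
            s = generate_subject(seed, ranges)
            assert 60.0 <= s.mass <= 70.0
            assert 1.60 <= s.height <= 1.70

    def test_at_least_two_unrecorded_mtus(self):
        assert len(generate_subject(3).unrecorded_mtus()) >= 2

    def test_every_dof_has_antagonists(self):
        s = generate_subject(5)
        for joint in ("hip", "knee", "ankle"):
            arms = [g.moment_arm(joint, np.zeros(1))[0]
                    for g in s.mtu_set if joint in g.dof_coeffs]
            assert any(a > 0 for a in arms) and any(a < 0 for a in arms)

    def test_moment_arms_in_band_over_motion_range(self):
        theta = np.linspace(-0.8, 0.8, 50)
        for seed in (1, 2, 3):
            for g in generate_subject(seed).mtu_set:
                for joint in g.dof_coeffs:
                    r = np.abs(g.moment_arm(joint, theta))
                    assert r.min() > 0.005 and r.max() < 0.060

    def test_degenerate_ranges_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_subject(1, {"mass": (70.0, 70.0)})


class TestGenerateStanceTrial:
    def test_noiseless_inverse_dynamics_round_trip(self, subject, noiseless_trial):
        from gaitkinetics.dynamics import inverse_dynamics

        tr = noiseless_trial.truth
        tq = inverse_dynamics(tr["kinematics"], noiseless_trial.grf[0],
                              noiseless_trial.grf[2],
                              noiseless_trial.cop[0] / 1000.0,
                              subject.segment_params)
        assert np.max(np.abs(tq.as_array() - tr["torques"].as_array())) < 1e-8

    def test_noiseless_measured_equals_truth(self, noiseless_trial):
        tr = noiseless_trial.truth
        assert np.array_equal(noiseless_trial.grf, tr["grf"])
        assert np.array_equal(noiseless_trial.cop, tr["cop"])
        assert np.array_equal(noiseless_trial.emg_env, tr["emg_env"])
        for j in ("hip", "knee", "ankle"):
            assert np.array_equal(noiseless_trial.theta[j], tr["theta"][j])

    def test_series_invariants(self, noiseless_trial):
        t = noiseless_trial
        n = t.n
        assert all(len(v) == n for v in t.theta.values())
        assert t.emg_env.shape == (len(EMG_CHANNELS), n)
        assert np.all(np.diff(t.t) > 0)
        assert np.allclose(np.diff(t.t), 1.0 / t.fs)
        assert np.all(t.grf[2] >= 0)
        assert t.emg_env.min() >= 0 and t.emg_env.max() <= 1

    def test_distinct_trial_seeds_give_distinct_grf(self, subject):
        a = generate_stance_trial(subject, 1, SILENT)
        b = generate_stance_trial(subject, 2, SILENT)
        assert np.max(np.abs(a.grf[2][: min(a.n, b.n)] - b.grf[2][: min(a.n, b.n)])) > 0

    def test_trial_seed_determinism(self, subject):
        a = generate_stance_trial(subject, 5, NoiseConfig())
        b = generate_stance_trial(subject, 5, NoiseConfig())
        assert np.array_equal(a.grf, b.grf)
        assert np.array_equal(a.emg_raw, b.emg_raw)

    def test_negative_noise_amplitude_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(angle_sd=-1.0)


class TestExcitationsFromTorques:
    def test_replay_reproduces_targets(self, subject, noiseless_trial):
        tr = noiseless_trial.truth
        tq = emg_driven_torques(tr["theta"], tr["omega"], subject.mtu_set,
                                subject.truth_params, tr["excitations"])
        for j in ("hip", "knee", "ankle"):
            ref = {"hip": tr["torques"].tau_hip, "knee": tr["torques"].tau_knee,
                   "ankle": tr["torques"].tau_ankle}[j]
            assert np.sqrt(np.mean((tq[j] - ref) ** 2)) < 1e-3

    def test_box_constraint(self, noiseless_trial):
        exc = np.stack(list(noiseless_trial.truth["excitations"].values()))
        assert exc.min() >= 0.0 and exc.max() <= 1.0

    def test_zero_targets_with_passive_disabled_give_zero_excitations(self, subject,
                                                                      noiseless_trial):
        tr = noiseless_trial.truth
        n = noiseless_trial.n
        zeros = {j: np.zeros(n) for j in ("hip", "knee", "ankle")}
        exc = excitations_from_torques(tr["theta"], tr["omega"], zeros, subject,
                                      include_passive=False)
        assert np.max(np.abs(np.stack(list(exc.values())))) < 1e-6

    def test_infeasible_targets_report_frame(self, subject, noiseless_trial):
        tr = noiseless_trial.truth
        n = noiseless_trial.n
        huge = {j: np.full(n, 1e4) for j in ("hip", "knee", "ankle")}
        with pytest.raises(RuntimeError, match="frame 0"):
            excitations_from_torques(tr["theta"], tr["omega"], huge, subject)


class TestSynthesizeRawEmg:
    def test_zero_envelope_zero_raw(self):
        assert np.allclose(synthesize_raw_emg(np.zeros(500), 1000.0, seed=0), 0.0)

    def test_constant_envelope_recovered_by_processing_chain(self):
        from gaitkinetics.signal import process_emg

        fs, c = 1000.0, 0.6
        raw = synthesize_raw_emg(np.full(4000, c), fs, seed=2)
        env = process_emg(raw, fs)
        plateau = env[1000:3000]
        assert abs(plateau.mean() - c) < 0.15 * c

    def test_seed_reproducibility(self):
        env = np.linspace(0, 1, 800)
        a = synthesize_raw_emg(env, 1000.0, seed=9)
        b = synthesize_raw_emg(env, 1000.0, seed=9)
        assert np.array_equal(a, b)

    def test_low_fs_raises(self):
        with pytest.raises(ValueError, match="fs"):
            synthesize_raw_emg(np.ones(100), 50.0, seed=0)

    def test_negative_envelope_rejected(self):
        with pytest.raises(ValueError):
            synthesize_raw_emg(np.array([-0.1, 0.2]), 1000.0, seed=0)


class TestNoiseMonotonicity:
    def test_grf_and_envelope_rmse_grow_with_noise(self, subject):
        # expectation over >= 10 trial seeds: more measurement noise can
        # only worsen agreement with the truth channels
        scales = (0.5, 1.0, 2.0)
        mean_grf, mean_env = [], []
        for scale in scales:
            noise = NoiseConfig().scaled(scale)
            g_err, e_err = [], []
            for ts in range(10):
                t = generate_stance_trial(subject, 300 + ts, noise)
                g_err.append(np.sqrt(np.mean((t.grf - t.truth["grf"]) ** 2)))
                env_t = t.truth["emg_env"]
                scalefree = t.emg_env * (env_t.max() / max(t.emg_env.max(), 1e-12))
                e_err.append(np.sqrt(np.mean((scalefree - env_t) ** 2)))
            mean_grf.append(np.mean(g_err))
            mean_env.append(np.mean(e_err))
        assert mean_grf[0] < mean_grf[1] < mean_grf[2]
        assert mean_env[0] <= mean_env[1] <= mean_env[2]


def test_subject_trials_emg_normalised_to_global_peak(noisy_trials):
    peaks = np.max([t.emg_env.max(axis=1) for t in noisy_trials], axis=0)
    assert np.allclose(peaks, 1.0)
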