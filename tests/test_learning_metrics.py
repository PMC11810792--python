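"""Alignment, ramp amplitudes, activation, zone preference, reinforcement."""

import numpy as np
import pytest

from vr2p.learning_metrics import (
    AlignedResponses,
    align_to_zone_end,
    activation_ratio,
    classify_zone_preference,
    correlate_learning,
    decompose_reinforcement,
    ramp_amplitude,
)
from vr2p.synthetic_data import (
    SimConfig,
    generate_session,
    generate_transients,
    sample_ground_truth,
)


def make_aligned(data, rate=10.0, labels=None, velocity=None):
    data = np.asarray(data, dtype=float)
    n_t = data.shape[1]
    time = (np.arange(n_t) - (n_t - 1)) / rate
    if labels is None:
        labels = np.array(["AVER"] * data.shape[2])
    if velocity is None:
        velocity = np.zeros((n_t, data.shape[2]))
    return AlignedResponses(data=data, time=time, labels=np.asarray(labels),
                            velocity=velocity, frame_rate=rate)


class TestAlignment:
    def test_segment_length_is_rounded_window(self, small_session, small_config,
                                              small_transients):
        aligned = align_to_zone_end(
            small_transients.total, small_session, pre_window=5.0,
            frame_rate=small_config.imaging_rate,
        )
        assert aligned.data.shape[1] == round(5.0 * 14.31)  # 72 samples
        assert aligned.time[-1] == 0.0
        assert aligned.data.shape[0] == small_config.n_neurons

    def test_right_closed_convention_at_frame_boundary(self):
        """Zone exit exactly on a frame boundary: that frame is the last sample."""
        rate = 10.0
        dff = np.arange(100, dtype=float)[None, :]  # value == frame index

        class FakeSession:
            dt = 0.01
            velocity = np.zeros(10_000)

            def trials(self):
                import pandas as pd
                return pd.DataFrame([{
                    "zone": "AVER_0", "t_enter": 1.0, "t_exit": 5.0,
                    "scheduled_first_puff": 4.5, "n_puffs": 0, "escaped": False,
                }])

        aligned = align_to_zone_end(dff, FakeSession(), pre_window=2.0,
                                    frame_rate=rate)
        assert aligned.data[0, -1, 0] == 50.0  # frame at t = 5.0 exactly

    def test_short_trials_dropped_and_counted(self, small_session, small_config,
                                              small_transients):
        aligned = align_to_zone_end(
            small_transients.total, small_session, pre_window=20.0,
            frame_rate=small_config.imaging_rate, min_trial_duration=20.0,
        ) if False else None
        # all trials are far shorter than 20 s -> everything dropped -> error
        with pytest.raises(ValueError, match="no trial"):
            align_to_zone_end(
                small_transients.total, small_session, pre_window=20.0,
                frame_rate=small_config.imaging_rate,
            )

    def test_scheduled_puff_capping_shortens_aversive_trials(self, small_session,
                                                             small_config,
                                                             small_transients):
        exit_aligned = align_to_zone_end(
            small_transients.total, small_session, pre_window=3.0,
            frame_rate=small_config.imaging_rate, min_trial_duration=0.0)
        puff_aligned = align_to_zone_end(
            small_transients.total, small_session, pre_window=3.0,
            frame_rate=small_config.imaging_rate, end_event="scheduled_puff",
            min_trial_duration=0.0)
        aver = exit_aligned.labels == "AVER"
        assert not np.allclose(exit_aligned.data[:, :, aver],
                               puff_aligned.data[:, :, aver])
        ctrl = exit_aligned.labels == "CTRL"
        np.testing.assert_allclose(exit_aligned.data[:, :, ctrl],
                                   puff_aligned.data[:, :, ctrl])


class TestRampAmplitude:
    def test_zero_trace_gives_zero(self):
        aligned = make_aligned(np.zeros((3, 50, 4)))
        assert np.all(ramp_amplitude(aligned).per_trial == 0.0)

    def test_linear_trace_closed_form(self):
        """trace(t) = t + 5 on [-5, 0]: mean over (-1, -0.4) equals 4.3."""
        rate = 1000.0
        n = 5001
        time = (np.arange(n) - (n - 1)) / rate
        data = (time + 5)[None, :, None]
        aligned = AlignedResponses(data=data, time=time,
                                   labels=np.array(["AVER"]),
                                   velocity=np.zeros((n, 1)), frame_rate=rate)
        amp = ramp_amplitude(aligned, window=(-1.0, -0.4)).per_trial[0, 0]
        assert amp == pytest.approx(4.3, abs=2e-3)

    def test_linearity_in_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 60, 5))
        y = rng.normal(size=(4, 60, 5))
        a, b = 2.5, -1.25
        amp = lambda d: ramp_amplitude(make_aligned(d)).per_trial
        np.testing.assert_allclose(amp(a * x + b * y), a * amp(x) + b * amp(y))

    def test_planted_amplitudes_recovered_with_high_correlation(self):
        cfg = SimConfig(seed=33, n_neurons=100, grid_shape=(10, 10),
                        n_trials_per_zone=6, noise_sd=0.05,
                        mean_interteleport=5.0, p_immobility=0.0)
        session = generate_session(cfg)
        truth = sample_ground_truth(cfg)
        traces = generate_transients(session, truth, cfg)
        aligned = align_to_zone_end(traces.total, session, pre_window=5.0,
                                    frame_rate=cfg.imaging_rate)
        est = ramp_amplitude(aligned, baseline_window=(-4.9, -4.0)) \
            .per_neuron["AVER"].to_numpy()
        assert np.corrcoef(est, truth.ramp_amp_aver)[0, 1] > 0.95

    def test_window_endpoints_give_identical_ranking_on_noiseless_ramps(self):
        """(-1, -0.4) and (-1, -0.3) rank noiseless planted ramps identically."""
        rng = np.random.default_rng(5)
        rate, n_t = 14.31, 72
        time = (np.arange(n_t) - (n_t - 1)) / rate
        amps = rng.uniform(0.1, 2.0, 30)
        ramp_shape = np.clip((time + 3) / 3, 0, None)
        data = amps[:, None, None] * ramp_shape[None, :, None]
        aligned = AlignedResponses(data=data, time=time, labels=np.array(["AVER"]),
                                   velocity=np.zeros((n_t, 1)), frame_rate=rate)
        a1 = ramp_amplitude(aligned, window=(-1.0, -0.4)).per_trial[:, 0]
        a2 = ramp_amplitude(aligned, window=(-1.0, -0.3)).per_trial[:, 0]
        from scipy.stats import spearmanr
        assert spearmanr(a1, a2).statistic == pytest.approx(1.0)

    def test_invalid_window_rejected(self):
        aligned = make_aligned(np.zeros((2, 20, 3)))
        with pytest.raises(ValueError):
            ramp_amplitude(aligned, window=(-0.1, -0.05 - 10.0))


class TestActivationRatio:
    def test_deterministic_toy_threshold(self):
        """baseline trials [0,0,0], response [1,1,1] -> active."""
        data = np.zeros((1, 20, 3))
        data[0, 10:, :] = 1.0
        aligned = make_aligned(data, rate=10.0)
        out = activation_ratio(aligned, baseline_window=(-1.95, -1.0),
                               response_window=(-0.95, 0.0))
        assert out["fraction"] == 1.0

    def test_type_one_error_calibration_of_paired_test(self):
        """All-noise population at alpha = 0.05: ~5% false positives."""
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(60):
            data = rng.standard_normal((40, 20, 10))
            aligned = make_aligned(data, rate=10.0)
            out = activation_ratio(aligned, baseline_window=(-1.95, -1.0),
                                   response_window=(-0.95, 0.0),
                                   method="paired_test")
            fracs.append(out["fraction"])
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_power_on_planted_responders(self):
        """80% of neurons with SNR >= 5 respond: fraction ~ 0.80."""
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(20):
            data = rng.standard_normal((100, 20, 12)) * 0.1
            responders = np.arange(80)
            data[responders, 10:, :] += 1.0  # SNR 10 in the response window
            aligned = make_aligned(data, rate=10.0)
            out = activation_ratio(aligned, baseline_window=(-1.95, -1.0),
                                   response_window=(-0.95, 0.0),
                                   method="paired_test")
            fracs.append(out["fraction"])
        assert np.mean(fracs) == pytest.approx(0.80, abs=0.05)

    def test_threshold_method_monotone_in_amplitude(self):
        rng = np.random.default_rng(2)
        noise = rng.standard_normal((50, 20, 8)) * 0.2
        fractions = []
        for amp in (0.0, 0.1, 0.3, 1.0):
            data = noise.copy()
            data[:, 10:, :] += amp
            aligned = make_aligned(data, rate=10.0)
            out = activation_ratio(aligned, baseline_window=(-1.95, -1.0),
                                   response_window=(-0.95, 0.0))
            fractions.append(out["fraction"])
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))

    def test_single_trial_paired_test_rejected(self):
        aligned = make_aligned(np.zeros((2, 20, 1)))
        with pytest.raises(ValueError, match=">= 2 trials"):
            activation_ratio(aligned, (-1.95, -1.0), (-0.95, 0.0),
                             method="paired_test")


class TestZonePreference:
    def test_identical_zones_label_almost_nobody(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((200, 20, 16))
        labels = np.array(["AVER"] * 8 + ["CTRL"] * 8)
        aligned = make_aligned(data, labels=labels)
        out = classify_zone_preference(aligned, window=(-1.0, -0.4))
        labeled = (out["labels"] != "none").mean()
        assert labeled < 0.12  # ~ alpha

    def test_planted_population_fractions_recovered(self):
        """44% aversive-coding / 14% control-coding planted at SNR >= 3."""
        rng = np.random.default_rng(4)
        n, n_trials = 300, 10
        pref = np.array(["AVER"] * 132 + ["CTRL"] * 42 + ["none"] * 126)
        data = rng.standard_normal((n, 20, 2 * n_trials)) * 0.1
        labels = np.array(["AVER"] * n_trials + ["CTRL"] * n_trials)
        window_rows = slice(10, 20)
        for i, p in enumerate(pref):
            if p == "AVER":
                data[i, window_rows, :n_trials] += 0.5
            elif p == "CTRL":
                data[i, window_rows, n_trials:] += 0.5
        aligned = make_aligned(data, labels=labels)
        out = classify_zone_preference(aligned, window=(-0.95, 0.0))
        assert out["fractions"]["AVER"] == pytest.approx(0.44, abs=0.05)
        assert out["fractions"]["CTRL"] == pytest.approx(0.14, abs=0.05)

    def test_single_strong_neuron_labeled_aversive(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((1, 20, 20)) * 0.05
        labels = np.array(["AVER"] * 10 + ["CTRL"] * 10)
        data[0, :, :10] += 1.0
        aligned = make_aligned(data, labels=labels)
        out = classify_zone_preference(aligned, window=(-0.95, 0.0))
        assert out["labels"][0] == "AVER"

    def test_missing_zone_rejected(self):
        aligned = make_aligned(np.zeros((2, 20, 4)))
        with pytest.raises(ValueError, match="CTRL"):
            classify_zone_preference(aligned)


class TestReinforcementDecomposition:
    def setup_window(self, dt=0.07, seconds=4.0):
        n = int(seconds / dt)
        t = np.arange(n) * dt
        return t, dt

    def test_pure_exponential_has_zero_second_component(self):
        t, dt = self.setup_window()
        resp = 2.0 * np.exp(-t / 0.5)
        out = decompose_reinforcement(resp[None, :], np.zeros_like(t), dt)
        assert out.second_component[0] == pytest.approx(0.0, abs=1e-4)
        assert out.first_amplitude[0] == pytest.approx(2.0, rel=1e-3)
        assert out.tau[0] == pytest.approx(0.5, rel=0.1)

    def test_planted_second_component_integral_recovered(self):
        t, dt = self.setup_window()
        bump = np.exp(-0.5 * ((t - 1.5) / 0.4) ** 2)
        bump *= 0.5 / (bump.sum() * dt)  # integral exactly 0.5
        resp = 1.0 * np.exp(-t / 0.4) + bump
        out = decompose_reinforcement(resp[None, :], np.zeros_like(t), dt)
        assert out.second_component[0] == pytest.approx(0.5, abs=0.05)

    def test_zero_response_gives_zero_components(self):
        t, dt = self.setup_window()
        out = decompose_reinforcement(np.zeros((3, t.size)), np.zeros_like(t), dt)
        assert np.all(out.first_amplitude == 0)
        assert np.all(out.second_component == 0)

    def test_velocity_matched_part_assigned_to_first_component(self):
        t, dt = self.setup_window()
        vel = np.clip(np.sin(t), 0, None)
        resp = 0.8 * vel / vel.max()
        out = decompose_reinforcement(resp[None, :], vel, dt)
        assert out.velocity_gain[0] == pytest.approx(0.8, rel=0.05)
        assert out.second_component[0] == pytest.approx(0.0, abs=0.02)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="3 s"):
            decompose_reinforcement(np.zeros((1, 10)), np.zeros(10), 0.1)


class TestCorrelateLearning:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 1, 20)
        out = correlate_learning(x, 2.0 * x)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_independent_values_have_small_correlation(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(40):
            x, y = rng.standard_normal((2, 100))
            if abs(correlate_learning(x, y)["r"]) < 0.2:
                hits += 1
        assert hits >= 36  # ~95% of null draws

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 200)
        y = 1.5 * x + 0.2 * 1.5 * x.std() * rng.standard_normal(200)
        out = correlate_learning(x, y)
        assert out["slope"] == pytest.approx(1.5, abs=0.2)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlate_learning(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_generator_plants_the_learning_correlation(self, small_truth):
        out = correlate_learning(small_truth.reinf_second_amp,
                                 small_truth.ramp_amp_aver)
        assert out["r"] > 0.6
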