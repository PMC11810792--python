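"""Hub detection, spatial clustering, decoder, trial clusters, lead--lag."""

import numpy as np
import pytest
from scipy import stats

from vr2p.assemblies import (
    build_and_apply_decoder,
    cluster_trials,
    detect_amplitude_threshold,
    hub_spatial_clustering,
    lead_lag,
    onset_time,
    spontaneous_crosscorr,
)
from vr2p.learning_metrics import AlignedResponses
from vr2p.synthetic_data import SimConfig, sample_ground_truth


def max_gap_oracle(amps, quartile=0.75):
    """Exhaustive search for the largest sorted gap in the top quartile."""
    a = np.sort(np.asarray(amps, float))
    cutoff = int(np.ceil(quartile * a.size)) - 1
    best_j, best_gap = None, -np.inf
    for j in range(len(a) - 1):
        if j + 1 >= cutoff and a[j + 1] - a[j] > best_gap:
            best_gap, best_j = a[j + 1] - a[j], j
    return best_j, best_gap


class TestAmplitudeThreshold:
    def test_matches_max_gap_oracle_on_example(self):
        amps = [0.10, 0.12, 0.13, 0.15, 1.00, 1.05, 0.11, 0.14, 0.12, 0.13]
        out = detect_amplitude_threshold(amps)
        j, gap = max_gap_oracle(amps)
        assert not out.no_jump
        assert out.jump_index == j
        assert gap == pytest.approx(1.00 - 0.15)
        assert set(out.hub_ids) == {4, 5}  # the two top amplitudes

    def test_linear_amplitudes_flag_no_jump(self):
        out = detect_amplitude_threshold(np.linspace(0.1, 1.0, 20))
        assert out.no_jump
        assert out.hub_ids.size == 0

    def test_bimodal_population_zero_misassignments_over_seeds(self):
        """90 low ~N(0.1, 0.02) and 10 high ~N(1.0, 0.05): perfect split."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            low = rng.normal(0.1, 0.02, 90)
            high = rng.normal(1.0, 0.05, 10)
            amps = np.concatenate([low, high])
            out = detect_amplitude_threshold(amps)
            assert not out.no_jump
            assert set(out.hub_ids) == set(range(90, 100))

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        amps = np.concatenate([rng.normal(0.1, 0.02, 40), rng.normal(1, 0.05, 6)])
        out1 = detect_amplitude_threshold(amps)
        out2 = detect_amplitude_threshold(3.0 * amps + 7.0)
        np.testing.assert_array_equal(out1.hub_ids, out2.hub_ids)
        assert out1.jump_index == out2.jump_index

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            detect_amplitude_threshold(np.arange(5.0))


class TestHubSpatialClustering:
    def test_coincident_hubs_have_zero_ratio(self):
        xyz = np.random.default_rng(0).uniform(0, 650, (30, 3))
        xyz[:3] = (100.0, 100.0, 100.0)
        out = hub_spatial_clustering(xyz, np.arange(3), np.arange(30), seed=0)
        assert out["hub_mean_distance"] == 0.0
        assert out["ratio"] == 0.0

    def test_uniform_hubs_have_unit_ratio(self):
        ratios = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            xyz = rng.uniform(0, 650, (60, 3))
            hubs = rng.choice(60, 6, replace=False)
            out = hub_spatial_clustering(xyz, hubs, np.arange(60),
                                         n_draws=400, seed=seed)
            ratios.append(out["ratio"])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_planted_cluster_detected(self):
        """50-um hub ball inside a 650-um field: ratio < 1, p < 0.01."""
        cfg = SimConfig(seed=2, n_neurons=80, grid_shape=(9, 9), hub_fraction=0.12)
        truth = sample_ground_truth(cfg, hub_cluster_radius=50.0)
        hubs = np.flatnonzero(truth.hub_flag)
        out = hub_spatial_clustering(truth.soma_xyz, hubs, np.arange(80),
                                     n_draws=1000, seed=0)
        assert out["ratio"] < 1.0
        assert out["p_value"] < 0.01

    def test_permutation_p_uniform_under_null(self):
        """p-values are uniform when hubs are ordinary coding neurons."""
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            xyz = rng.uniform(0, 650, (40, 3))
            hubs = rng.choice(40, 5, replace=False)
            out = hub_spatial_clustering(xyz, hubs, np.arange(40),
                                         n_draws=99, seed=seed + 1)
            pvals.append(out["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_hubs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            hub_spatial_clustering(np.zeros((10, 3)), [0, 1], np.arange(10))


class TestSpontaneousCrosscorr:
    def test_identical_traces_fully_correlated(self):
        base = np.sin(np.linspace(0, 20, 600))
        dff = np.tile(base, (4, 1))
        t = np.linspace(0, 60, 600)
        out = spontaneous_crosscorr(dff, t, [])
        off = out["matrix"][~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_independent_noise_has_near_zero_mean(self):
        rng = np.random.default_rng(0)
        dff = rng.standard_normal((100, 1000))
        t = np.linspace(0, 100, 1000)
        out = spontaneous_crosscorr(dff, t, [])
        off = out["matrix"][~np.eye(100, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_shared_latent_raises_hub_group_mean(self):
        rng = np.random.default_rng(1)
        n, n_t = 40, 2000
        latent = rng.standard_normal(n_t)
        dff = rng.standard_normal((n, n_t))
        hub_ids = np.arange(8)
        dff[hub_ids] += 1.5 * latent  # shared drive in hubs only
        t = np.linspace(0, 200, n_t)
        out = spontaneous_crosscorr(dff, t, [], hub_ids=hub_ids)
        assert out["group_means"]["hub"] > out["group_means"]["rest"] + 0.3

    def test_aversive_intervals_are_excluded(self):
        rng = np.random.default_rng(2)
        n_t = 1000
        t = np.linspace(0, 100, n_t)
        dff = rng.standard_normal((3, n_t))
        # plant perfect correlation only inside the excluded interval
        inside = (t >= 40) & (t <= 60)
        dff[:, inside] = np.sin(t[inside] * 5)
        out = spontaneous_crosscorr(dff, t, [(40.0, 60.0)])
        off = out["matrix"][~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.2)
        assert out["n_samples"] == int((~inside).sum())

    def test_insufficient_samples_rejected(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(ValueError, match="spontaneous"):
            spontaneous_crosscorr(np.zeros((2, 100)), t, [(0.0, 10.0)])


def make_separable_aligned(seed=0, n_neurons=30, trials_per_zone=10,
                           snr=3.0, rate=14.31, pre=5.0):
    """AVER-only ramps in a subset of neurons, noise elsewhere."""
    rng = np.random.default_rng(seed)
    n_t = int(round(pre * rate))
    time = (np.arange(n_t) - (n_t - 1)) / rate
    n_trials = 2 * trials_per_zone
    labels = np.array(["AVER"] * trials_per_zone + ["CTRL"] * trials_per_zone)
    noise_sd = 0.1
    data = rng.standard_normal((n_neurons, n_t, n_trials)) * noise_sd
    ramp = np.clip((time + 5) / 5, 0, None)
    coders = np.arange(10)
    for tr in range(trials_per_zone):  # aversive trials only
        data[coders, :, tr] += snr * noise_sd * ramp[None, :]
    velocity = np.zeros((n_t, n_trials))
    return AlignedResponses(data=data, time=time, labels=labels,
                            velocity=velocity, frame_rate=rate)


class TestDecoder:
    def test_reliability_on_separable_population(self):
        scores = []
        for seed in range(10):
            aligned = make_separable_aligned(seed=seed)
            n = aligned.data.shape[2]
            train = np.concatenate([np.arange(0, 5), np.arange(10, 15)])
            test = np.setdiff1d(np.arange(n), train)
            out = build_and_apply_decoder(aligned, train, test, seed=seed)
            scores.append(out["reliability"])
        assert np.mean(scores) >= 0.95

    def test_chance_level_under_permuted_labels(self):
        rng = np.random.default_rng(3)
        scores = []
        for seed in range(20):
            aligned = make_separable_aligned(seed=seed)
            aligned.labels = rng.permutation(aligned.labels)
            train = np.flatnonzero(aligned.labels == "AVER")[:5]
            train = np.concatenate([
                train, np.flatnonzero(aligned.labels == "CTRL")[:5]])
            test = np.setdiff1d(np.arange(20), train)
            out = build_and_apply_decoder(aligned, train, test, seed=seed)
            scores.append(out["reliability"])
        assert np.mean(scores) == pytest.approx(0.5, abs=0.12)

    def test_k_three_and_seven_agree_on_noiseless_data(self):
        aligned = make_separable_aligned(seed=1, snr=50.0)
        train = np.concatenate([np.arange(0, 5), np.arange(10, 15)])
        test = np.setdiff1d(np.arange(20), train)
        out3 = build_and_apply_decoder(aligned, train, test, k=3)
        out7 = build_and_apply_decoder(aligned, train, test, k=7)
        np.testing.assert_array_equal(out3["test_labels"], out7["test_labels"])

    def test_invalid_k_rejected(self):
        aligned = make_separable_aligned()
        train = np.concatenate([np.arange(0, 5), np.arange(10, 15)])
        with pytest.raises(ValueError, match="3..7"):
            build_and_apply_decoder(aligned, train, train, k=9)

    def test_single_class_training_split_rejected(self):
        aligned = make_separable_aligned()
        with pytest.raises(ValueError, match="both"):
            build_and_apply_decoder(aligned, np.arange(0, 5), np.arange(10, 15))


class TestClusterTrials:
    def test_separated_scores_split_perfectly(self):
        scores = np.array([0.1] * 5 + [1.0] * 5)
        out = cluster_trials(scores)
        assert list(out.cluster[:5]) == ["low_ramp"] * 5
        assert list(out.cluster[5:]) == ["high_ramp"] * 5

    def test_velocity_ramp_correlation_in_printed_range(self):
        """velocity = 0.9 * ramp + noise(0.1): r lands in [0.85, 0.99]."""
        inside = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ramp = rng.uniform(0, 1, 30)
            vel = 0.9 * ramp + 0.1 * rng.standard_normal(30)
            out = cluster_trials(ramp, velocity_summaries=vel, seed=seed)
            inside += 0.85 <= out.pearson_r <= 0.99
        assert inside >= 18

    def test_labels_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 1, 12)
        out1 = cluster_trials(scores, seed=0)
        out2 = cluster_trials(123.4 * scores, seed=0)
        np.testing.assert_array_equal(out1.cluster, out2.cluster)

    def test_identical_scores_flag_single_cluster(self):
        out = cluster_trials(np.full(8, 0.5))
        assert out.single_cluster

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match=">= 6"):
            cluster_trials(np.arange(4.0))


class TestLeadLag:
    def test_planted_lead_recovered_within_one_sample(self):
        """Velocity = population shifted 2.45 s later: lag = +2.45."""
        rate = 14.31
        t = np.arange(0, 60, 1 / rate)
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter1d
        pop = gaussian_filter1d(rng.standard_normal(t.size), 8)
        lead = 2.45
        shift = int(round(lead * rate))
        vel = np.roll(pop, shift)
        lag = lead_lag(pop[shift:-shift], vel[shift:-shift], rate, max_lag=5.0)
        assert abs(lag - lead) <= 1 / rate + 1e-9

    def test_identical_traces_have_zero_lag(self):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter1d
        x = gaussian_filter1d(rng.standard_normal(500), 5)
        assert lead_lag(x, x, 10.0, max_lag=3.0) == 0.0

    def test_running_leads_gives_negative_lag(self):
        rate = 14.31
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter1d
        vel = gaussian_filter1d(rng.standard_normal(1000), 8)
        shift = int(round(1.0 * rate))
        pop = np.roll(vel, shift)  # population is a delayed copy of running
        lag = lead_lag(pop[shift:-shift], vel[shift:-shift], rate, max_lag=3.0)
        assert lag < -0.5

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            lead_lag(np.zeros(100), np.ones(100), 10.0, 2.0)


class TestHubTiming:
    def test_earlier_hub_ramps_yield_onset_difference_over_one_second(self):
        """Hub ramps starting >= 1 s earlier show up as >= 1 s onset gap."""
        rate = 14.31
        n_t = int(8 * rate)
        time = np.arange(n_t) / rate
        hub = np.clip((time - 3.0) / 4.0, 0, None)       # onset at 3 s
        population = np.clip((time - 4.5) / 2.5, 0, None)  # onset at 4.5 s
        t_hub = onset_time(hub, rate)
        t_pop = onset_time(population, rate)
        assert t_pop - t_hub >= 1.0
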