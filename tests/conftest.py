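"""Shared fixtures: small synthetic sessions, populations and movies."""

import numpy as np
import pytest

from vr2p.synthetic_data import (
    SimConfig,
    generate_chessboard_movie,
    generate_session,
    generate_transients,
    sample_ground_truth,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A light-weight population: 12 neurons, 6 trials per zone."""
    return SimConfig(seed=11, n_neurons=12, grid_shape=(3, 4),
                     n_trials_per_zone=6, noise_sd=0.02,
                     mean_interteleport=8.0, p_immobility=0.0)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sample_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_transients(small_session, small_truth, small_config):
    return generate_transients(small_session, small_truth, small_config)


@pytest.fixture(scope="session")
def tiny_movie_setup():
    """A 2x2-grid movie short enough for registration tests."""
    cfg = SimConfig(seed=3, n_neurons=4, grid_shape=(2, 2),
                    n_trials_per_zone=1, noise_sd=0.0,
                    mean_interteleport=5.0, p_immobility=0.0)
    session = generate_session(cfg)
    truth = sample_ground_truth(cfg)
    traces = generate_transients(session, truth, cfg)
    movie, rois = generate_chessboard_movie(truth, traces, cfg)
    return cfg, session, truth, traces, movie, rois
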