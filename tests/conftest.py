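import numpy as np
import pytest

from readrhythm import RunConfig, SimulationConfig, simulate_session
from readrhythm.pipeline import prepare_eye, prep_eeg


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_participants=3, n_sentences=8, n_blocks=2, seed=11)


@pytest.fixture(scope="session")
def session(small_cfg):
    return simulate_session(small_cfg, 0)


@pytest.fixture(scope="session")
def run_cfg():
    cfg = RunConfig()
    cfg.simulation = SimulationConfig(n_participants=3, n_sentences=8, n_blocks=2, seed=11)
    cfg.highpass_order = 2000
    cfg.n_surrogates = 50
    cfg.n_cluster_perm = 256
    cfg.n_boundary_draws = 200
    cfg.ispc_lag_step = 10
    return cfg


@pytest.fixture(scope="session")
def eye_stage(session, run_cfg):
    return prepare_eye(session, run_cfg)


@pytest.fixture(scope="session")
def prepped(session, run_cfg):
    return prep_eeg(session, run_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
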