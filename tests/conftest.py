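"""Shared fixtures: one small simulated study reused across test modules."""

import numpy as np
import pytest

from insightrc import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(
        n_subjects=8,
        n_items=24,
        n_runs=2,
        trials_per_run=12,
        n_voxels_per_roi={"iLOC": 30, "pFusG": 30, "aITG": 30},
        rc_rois=("iLOC", "pFusG"),
        fc_rois=("iLOC_L", "iLOC_R", "pFusG_L", "pFusG_R", "Amy_L", "Amy_R",
                 "aHC_L", "aHC_R"),
        fc_subnetwork=("iLOC_L", "iLOC_R", "pFusG_L", "pFusG_R"),
    )


@pytest.fixture(scope="session")
def small_trials(small_config):
    return syn.simulate_trials(small_config, seed=11)


@pytest.fixture(scope="session")
def small_embeddings(small_config):
    return syn.simulate_embeddings(small_config, seed=11)


@pytest.fixture(scope="session")
def small_patterns(small_config, small_trials, small_embeddings):
    return syn.simulate_patterns(
        small_trials, small_embeddings[0], small_config, seed=11
    )


@pytest.fixture(scope="session")
def small_timeseries(small_config, small_trials):
    return syn.simulate_roi_timeseries(small_trials, small_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
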