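import numpy as np
import pytest

import mousebandit as mb
from mousebandit.dynamics import compute_features_table
from mousebandit.preprocess import preprocess_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Six simulated participants, 60 trials per block, exploitation-trial paths."""
    trials, tracking = mb.generate_dataset(
        n_participants=6,
        task_config=mb.TaskConfig(n_trials_per_block=60),
        seed=42,
        trajectories_for="exploitation",
    )
    return trials, tracking


@pytest.fixture(scope="session")
def aligned_small(small_dataset):
    _, tracking = small_dataset
    aligned, report = preprocess_dataset(tracking, mb.TrajectoryConfig())
    return aligned, report


@pytest.fixture(scope="session")
def features_small(aligned_small):
    aligned, _ = aligned_small
    return compute_features_table(aligned)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
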