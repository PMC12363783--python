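import numpy as np
import pytest

from infoconn.design import StudyDesign
from infoconn.synthetic import GenerativeModel, generate_atlas, generate_pattern_dataset


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """4 encoding runs x 6 trials, 2 retrieval runs x 6 trials, 2/group."""
    return StudyDesign(
        n_per_group=2,
        encoding_runs=4,
        retrieval_runs=2,
        trials_per_encoding_run=6,
        trials_per_retrieval_run=6,
    )


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas(n_rois=5, min_voxels=30, max_voxels=40, seed=7)


@pytest.fixture(scope="session")
def small_model(small_atlas):
    return GenerativeModel(n_rois=small_atlas.n_rois, seed=7)


@pytest.fixture(scope="session")
def small_pattern_set(small_design, small_atlas, small_model):
    return generate_pattern_dataset(
        small_design, small_atlas, small_model,
        participant="sub-test", group="navigation", session="pre",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
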