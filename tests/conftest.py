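import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from voxelsurvey import (RandomSurveySVM, assemble_feature_matrix,
                         build_voxel_pairs, compute_group_matrices,
                         generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """10+10 subjects, (6,7,6) maps, 20 planted voxels, strong effect."""
    return generate_cohort(n_disease=10, n_control=10, dims=(6, 7, 6),
                           n_informative=20, effect_size=0.3, noise_sd=0.05,
                           seed=7)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    M, N = compute_group_matrices(small_cohort)
    pairs = build_voxel_pairs(M, N)
    return assemble_feature_matrix(small_cohort, pairs), pairs


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return RandomSurveySVM.from_cohort(small_cohort, n_surveys=20)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
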