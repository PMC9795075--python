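import numpy as np
import pytest

from pitchlca import (
    ResponseKinematics,
    ResponseMatrix,
    generate_dataset,
    truth_to_matrix,
)
from pitchlca.simulate import default_profiles


@pytest.fixture(scope="session")
def small_cohort():
    """36-participant cohort, categorical path only (fast)."""
    _, truth = generate_dataset(36, seed=20, synthesize=False)
    return truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return truth_to_matrix(small_cohort)


@pytest.fixture(scope="session")
def noiseless_traces():
    """Small fully-synthesized cohort without measurement noise."""
    kin = ResponseKinematics(noise_sd=0.0)
    return generate_dataset(6, kinematics=kin, seed=7)


def random_small_matrix(rng, N=6, J=3, K=3):
    """Random categorical matrix guaranteed to expose >= 2 categories/column."""
    while True:
        Y = rng.integers(1, K + 1, size=(N, J))
        if all(len(np.unique(Y[:, j])) >= 2 for j in range(J)):
            return ResponseMatrix(Y)


@pytest.fixture
def default_profile_list():
    return default_profiles()
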