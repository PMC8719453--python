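import numpy as np
import pytest

from cerebparc import generate_geometry, generate_group_dataset


@pytest.fixture(scope="session")
def small_geometry():
    return generate_geometry((5, 5, 5), 2.0)


@pytest.fixture(scope="session")
def planted_dataset(small_geometry):
    """V=125, 4 compact regions, 6 subjects, moderate SNR, no unassigned."""
    series, truth = generate_group_dataset(
        small_geometry, K_true=4, n_subjects=6, T=100, snr=8.0,
        overlap_fraction=0.0, unassigned_fraction=0.0, seed=7,
    )
    return series, truth


@pytest.fixture(scope="session")
def noiseless_dataset(small_geometry):
    series, truth = generate_group_dataset(
        small_geometry, K_true=4, n_subjects=3, T=60, snr=np.inf,
        overlap_fraction=0.0, unassigned_fraction=0.0, seed=3,
        subject_jitter=0.0,
    )
    return series, truth
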