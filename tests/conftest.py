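import numpy as np
import pytest

from popemax import IIVSpec, PDParams, TrialDesign, simulate_binary_dataset


@pytest.fixture(scope="session")
def binary_dataset_gamma5():
    """40-subject binary trial, gamma=5, omega_C50=0.1 (the workhorse case)."""
    return simulate_binary_dataset(
        PDParams(c50=1.0, gamma=5.0), IIVSpec(omega_c50=0.1),
        TrialDesign(n_subjects=40), seed=42,
    )


@pytest.fixture(scope="session")
def binary_dataset_no_iiv():
    """200-subject binary trial without IIV, mild steepness (no separation)."""
    return simulate_binary_dataset(
        PDParams(c50=1.0, gamma=2.0), IIVSpec(),
        TrialDesign(n_subjects=200), seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
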