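"""Shared fixtures: small, fast model configurations and synthetic data."""

import numpy as np
import pytest

from mbeegcbam import AttentionConfig, BranchConfig, SyntheticSpec, generate_trialset

TINY_BANDS = ((8.0, (0,)), (12.0, (1,)), (20.0, (2,)), (26.0, (3,)))


@pytest.fixture
def tiny_configs():
    """Three small branches compatible with 64-sample trials."""
    return (
        BranchConfig(2, 8, 0.0, AttentionConfig(2, 2), pool1=4, pool2=4,
                     separable_kernel=4),
        BranchConfig(4, 12, 0.1, AttentionConfig(4, 3), pool1=4, pool2=4,
                     separable_kernel=4),
        BranchConfig(4, 16, 0.2, AttentionConfig(8, 2), pool1=4, pool2=4,
                     separable_kernel=4),
    )


@pytest.fixture
def tiny_shape():
    return (4, 64)


def make_tiny_trialset(seed: int = 3, snr_db: float = 10.0, n_per_class: int = 12):
    spec = SyntheticSpec(n_per_class=n_per_class, n_channels=4, n_samples=64,
                         rate=64.0, snr_db=snr_db, class_bands=TINY_BANDS, seed=seed)
    return generate_trialset(spec)


@pytest.fixture
def tiny_trainset():
    return make_tiny_trialset(seed=3)


@pytest.fixture
def tiny_testset():
    return make_tiny_trialset(seed=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
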