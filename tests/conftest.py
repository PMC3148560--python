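import numpy as np
import pytest

from wihs.haplodata import HaplotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260401)


def random_dataset(rng, n=12, s=40, cm_per_bp=1e-5, missing_frac=0.0):
    """Seeded random dataset; columns are iid Bernoulli(0.5)."""
    alleles = rng.integers(0, 2, size=(n, s)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(size=(n, s)) < missing_frac
        alleles[mask] = -1
    pos = (np.arange(s) + 1) * 1000
    return HaplotypeDataset(
        alleles=alleles,
        physical_positions=pos,
        genetic_positions=pos * cm_per_bp,
    )


@pytest.fixture
def make_dataset():
    return random_dataset


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, n=10, s=30)
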