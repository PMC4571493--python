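import numpy as np
import pytest

from traitpred.core import GenotypeMatrix, TraitVector


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dataset(rng, n, m, with_missing=False):
    """Small random genotype/trait pair for oracle comparisons."""
    codes = rng.integers(0, 3, size=(n, m)).astype(np.int16)
    if with_missing:
        from traitpred.core import MISSING
        mask = rng.random((n, m)) < 0.1
        codes[mask] = MISSING
    g = GenotypeMatrix(
        [f"S{i}" for i in range(n)], [f"M{j}" for j in range(m)], codes
    )
    t = TraitVector(g.sample_ids, rng.normal(size=n))
    return g, t


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, 20, 6)
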