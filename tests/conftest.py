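import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import kinlagoon as kl
from kinlagoon.io import MISSING, GenotypeMatrix


def make_gm(ids, loci, cells):
    """Build a GenotypeMatrix from a nested list of (a, b) tuples."""
    return GenotypeMatrix(ids, loci, np.array(cells, dtype=np.int64))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def panel_freqs():
    """21-locus frequency panel with mean expected heterozygosity ~0.67."""
    return kl.paper_like_frequencies(1)


@pytest.fixture
def random_gm(rng):
    """20 x 5 genotype matrix with planted missingness."""
    n, L = 20, 5
    alleles = 100 + 3 * rng.integers(0, 8, size=(n, L, 2))
    missing = rng.random((n, L)) < 0.15
    alleles[missing] = MISSING
    return GenotypeMatrix(
        [f"ind{i:02d}" for i in range(n)],
        [f"loc{j}" for j in range(L)],
        np.sort(alleles, axis=2),
    )
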