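import numpy as np
import pytest

from magicpanel import tables
from magicpanel.genotype import GenotypeMatrix, VariantSite
from magicpanel.synth import FounderSpec, simulate_founders


@pytest.fixture(scope="session")
def tiny_founders():
    """Small synthetic founder set on a 1/500-scale genome (400 sites)."""
    spec = FounderSpec(chromosomes=tables.chrom_lengths(1 / 500),
                       n_sites=400, seed=11)
    return simulate_founders(spec), spec


def random_matrix(rng, n_sites=50, n_samples=6, missing_rate=0.1,
                  chrom="c1") -> GenotypeMatrix:
    """A random genotype matrix with some missing calls, for oracle tests."""
    pos = np.sort(rng.choice(np.arange(1, 100 * n_sites), n_sites,
                             replace=False))
    sites = [VariantSite(chrom, int(p), f"{chrom}_{p}", "A", "G") for p in pos]
    calls = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    return GenotypeMatrix.from_calls(
        sites, [f"s{i}" for i in range(n_samples)], calls)
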