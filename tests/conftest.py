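import numpy as np
import pytest

from poem import GenotypeMatrix, TraitMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_genotypes(rng, n, m, ids=None, chrom=None, pos=None):
    """Random polymorphic +/-1 genotype panel for tests."""
    G = rng.choice((-1.0, 1.0), size=(n, m))
    while (np.abs(G.sum(axis=0)) == n).any():
        mono = np.flatnonzero(np.abs(G.sum(axis=0)) == n)
        G[:, mono] = rng.choice((-1.0, 1.0), size=(n, mono.size))
    return GenotypeMatrix(
        G,
        ids or [f"v{j}" for j in range(m)],
        [f"i{i}" for i in range(n)],
        variant_chrom=chrom,
        variant_pos_bp=pos,
    )


def make_traits(values, individual_ids, prefix="t"):
    values = np.asarray(values, dtype=float)
    return TraitMatrix(
        values,
        [f"{prefix}{j}" for j in range(values.shape[1])],
        list(individual_ids),
    )


@pytest.fixture
def genotype_factory():
    return make_genotypes


@pytest.fixture
def trait_factory():
    return make_traits
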