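import numpy as np
import pytest

from atpromoter import PromoterPairSpec, make_genome, make_promoter_pair


@pytest.fixture(scope="session")
def promoter_pair():
    """A divergence-free ortholog pair with its ground-truth manifest."""
    return make_promoter_pair(PromoterPairSpec(seed=7))


@pytest.fixture(scope="session")
def diverged_pair():
    """The same layout with 3% per-base divergence outside planted motifs."""
    return make_promoter_pair(PromoterPairSpec(seed=11, divergence=0.03))


@pytest.fixture(scope="session")
def small_genome():
    """A 200-kb annotated genome (fast enough for per-test reuse)."""
    return make_genome(chrom_length=200_000, n_genes=8, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
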