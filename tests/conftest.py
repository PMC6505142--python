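import itertools

import numpy as np
import pytest

from phantomld import HaplotypeDistribution, make_haplotype_distribution

#: the "generic" mutually-LD triple used throughout: QTL at locus 0,
#: markers at loci 1 and 2, all three loci in mutual but imperfect LD
GENERIC = dict(
    allele_freqs=(0.5, 0.4, 0.3),
    pairwise_D={(0, 1): 0.05, (0, 2): 0.04, (1, 2): 0.03},
    three_locus_D=0.01,
)


@pytest.fixture(scope="session")
def generic_dist() -> HaplotypeDistribution:
    return make_haplotype_distribution(**GENERIC)


@pytest.fixture(scope="session")
def le_dist() -> HaplotypeDistribution:
    """All three loci in complete linkage equilibrium."""
    return make_haplotype_distribution((0.5, 0.4, 0.3))


@pytest.fixture(scope="session")
def x2_indep_dist() -> HaplotypeDistribution:
    """x2 independent of the (z, x1) pair; z and x1 in LD."""
    return make_haplotype_distribution((0.5, 0.5, 0.3), {(0, 1): 0.1})


@pytest.fixture(scope="session")
def wei_dist() -> HaplotypeDistribution:
    """Markers pairwise independent of each other and of the QTL, yet the
    triple is jointly in LD (nonzero three-locus D only)."""
    return make_haplotype_distribution((0.3, 0.5, 0.5), None, 0.05)


@pytest.fixture(scope="session")
def perfect_ld_dist() -> HaplotypeDistribution:
    """QTL allele identical to the x1 allele on every haplotype."""
    pair = make_haplotype_distribution((0.5, 0.4), 0.1)
    freq = np.zeros(8)
    for k, (a1, a2) in enumerate(itertools.product((0, 1), repeat=2)):
        freq[(a1 << 2) | (a1 << 1) | a2] = pair.frequencies[(a1 << 1) | a2]
    return HaplotypeDistribution(freq, locus_labels=("z", "x1", "x2"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
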