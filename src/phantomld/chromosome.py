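"""Mock chromosome with distance-decaying LD.

Haplotypes are generated by a first-order Markov chain along the loci: the
haploid allele correlation between adjacent loci j and j+1 is
``exp(-(pos[j+1] - pos[j]) / decay_lambda)``, so the correlation between any
two loci is the product of the adjacent correlations and pairwise R**2 decays
exponentially with base-pair distance.  Diploids are formed by random union of
two independent haplotypes.  This emulates the qualitative shape of LD decay
along a real chromosome (R**2 falling to near zero over roughly a megabase
for the default ``decay_lambda``); it makes no claim about human LD maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .haplotypes import GenotypeMatrix, HaplotypeDistribution

__all__ = ["MarkovChromosome", "ChromosomeSample", "simulate_chromosome_haplotypes"]

#: default LD decay length (bp); R**2 = exp(-2 d / lambda) reaches ~0.001 near 1 Mb
DEFAULT_DECAY_LAMBDA = 3.0e5


@dataclass
class MarkovChromosome:
    """First-order Markov haplotype model along a mock chromosome.

    Parameters
    ----------
    positions
        Strictly increasing base-pair coordinates, one per locus.
    maf
        Per-locus frequency of the counted allele, in (0, 0.5].
    decay_lambda
        LD decay length in bp; adjacent haploid correlation is
        ``exp(-distance / decay_lambda)``.  A requested adjacent correlation
        infeasible for the flanking allele frequencies is clamped to the
        feasible maximum with a warning.
    """

    positions: np.ndarray
    maf: np.ndarray
    decay_lambda: float = DEFAULT_DECAY_LAMBDA
    adjacent_corr: np.ndarray = field(init=False)
    adjacent_D: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.positions.size != self.maf.size:
            raise ValueError("positions and maf must have one entry per locus")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("per-locus MAF must lie in (0, 0.5]")
        if self.decay_lambda < 0:
            raise ValueError("decay_lambda must be nonnegative")

        p, q = self.maf, 1.0 - self.maf
        gaps = np.diff(self.positions)
        with np.errstate(divide="ignore"):
            r = np.exp(-gaps / self.decay_lambda) if self.decay_lambda > 0 else np.zeros_like(gaps)
        # positive correlation between adjacent indicators is feasible only up
        # to D_max = min(p_j q_{j+1}, q_j p_{j+1})
        denom = np.sqrt(p[:-1] * q[:-1] * p[1:] * q[1:])
        r_max = np.minimum(p[:-1] * q[1:], q[:-1] * p[1:]) / denom
        if np.any(r > r_max):
            worst = int(np.argmax(r - r_max))
            warnings.warn(
                f"adjacent correlation {r[worst]:.4f} between loci {worst} and "
                f"{worst + 1} is infeasible for MAFs ({p[worst]:.3f}, {p[worst + 1]:.3f}); "
                f"clamped to {r_max[worst]:.4f}",
                stacklevel=2,
            )
            r = np.minimum(r, r_max)
        self.adjacent_corr = r
        self.adjacent_D = r * denom

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @property
    def locus_labels(self) -> tuple[str, ...]:
        return tuple(f"M{j + 1}" for j in range(self.n_loci))

    # -- analytic LD --------------------------------------------------------

    def haploid_correlation(self, i: int, j: int) -> float:
        """Allele-indicator correlation between loci i and j (chain product)."""
        if i == j:
            return 1.0
        lo, hi = sorted((i, j))
        return float(np.prod(self.adjacent_corr[lo:hi]))

    def expected_r2(self, i: int, j: int) -> float:
        """Expected genotypic R**2 between loci i and j.

        Under random mating the genotype correlation equals the haploid
        correlation, so R**2 is its square.
        """
        return self.haploid_correlation(i, j) ** 2

    def expected_r2_table(self, pairs: Sequence[tuple[int, int]] | None = None) -> pd.DataFrame:
        """Tidy per-pair table of distance and expected R**2 (for LD binning)."""
        if pairs is None:
            L = self.n_loci
            pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
        rows = [
            {
                "locus_i": i,
                "locus_j": j,
                "distance_bp": abs(self.positions[j] - self.positions[i]),
                "expected_r2": self.expected_r2(i, j),
            }
            for i, j in pairs
        ]
        return pd.DataFrame(rows)

    def _transition(self, j: int) -> np.ndarray:
        """2x2 transition P(A_{j+1} = b | A_j = a) preserving marginals and adjacent D."""
        p0, p1 = self.maf[j], self.maf[j + 1]
        D = self.adjacent_D[j]
        t1 = np.clip(p1 + D / p0, 0.0, 1.0)  # P(1 | 1)
        t0 = np.clip(p1 - D / (1 - p0), 0.0, 1.0)  # P(1 | 0)
        return np.array([[1 - t0, t0], [1 - t1, t1]])

    def marginal_distribution(self, loci: Sequence[int]) -> HaplotypeDistribution:
        """Exact joint haplotype law over a subset of loci.

        The marginal of a Markov chain on a subset is again Markov, with
        transition kernels given by products of the intermediate kernels;
        the joint table is built by enumerating the 2**k patterns.
        """
        loci = sorted(loci)
        kernels = []
        for a, b in zip(loci[:-1], loci[1:]):
            K = np.eye(2)
            for j in range(a, b):
                K = K @ self._transition(j)
            kernels.append(K)
        k = len(loci)
        freq = np.zeros((2,) * k)
        p_first = self.maf[loci[0]]
        for pattern in np.ndindex(*(2,) * k):
            pr = p_first if pattern[0] == 1 else 1 - p_first
            for step, K in enumerate(kernels):
                pr *= K[pattern[step], pattern[step + 1]]
            freq[pattern] = pr
        return HaplotypeDistribution(
            freq.ravel(),
            locus_labels=tuple(self.locus_labels[j] for j in loci),
            positions=self.positions[loci],
        )

    # -- sampling -----------------------------------------------------------

    def sample_haplotypes(self, n_hap: int, rng: np.random.Generator) -> np.ndarray:
        """(n_hap, L) array of allele indicators from the Markov chain."""
        L = self.n_loci
        H = np.empty((n_hap, L), dtype=np.int8)
        H[:, 0] = rng.random(n_hap) < self.maf[0]
        for j in range(L - 1):
            p1, D = self.maf[j + 1], self.adjacent_D[j]
            cond = np.where(
                H[:, j] == 1,
                np.clip(p1 + D / self.maf[j], 0.0, 1.0),
                np.clip(p1 - D / (1 - self.maf[j]), 0.0, 1.0),
            )
            H[:, j + 1] = rng.random(n_hap) < cond
        return H

    def sample_genotypes(
        self, n: int, seed: int | np.random.Generator | None = None
    ) -> GenotypeMatrix:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        codes = self.sample_haplotypes(int(n), rng) + self.sample_haplotypes(int(n), rng)
        return GenotypeMatrix(
            codes, locus_labels=self.locus_labels, positions=self.positions
        )


class ChromosomeSample(NamedTuple):
    genotypes: GenotypeMatrix
    expected_r2: pd.DataFrame
    model: MarkovChromosome


def simulate_chromosome_haplotypes(
    n_loci: int,
    positions: Sequence[float],
    maf: Sequence[float] | float,
    decay_lambda: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> ChromosomeSample:
    """Sample n random-mating diploids along a mock chromosome.

    Returns the genotype matrix together with the per-pair expected-R**2
    table (so experiments can bin replicates by LD) and the generating model.
    """
    maf_vec = np.full(n_loci, maf, dtype=float) if np.isscalar(maf) else np.asarray(maf, float)
    chrom = MarkovChromosome(np.asarray(positions, float), maf_vec, decay_lambda)
    if chrom.n_loci != n_loci:
        raise ValueError("n_loci inconsistent with positions/maf length")
    G = chrom.sample_genotypes(n, seed)
    return ChromosomeSample(G, chrom.expected_r2_table(), chrom)
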