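"""Exact multi-locus haplotype distributions and random-mating genotype sampling.

A :class:`HaplotypeDistribution` is the exact population law of an L-locus
biallelic haplotype, stored as a full table of 2**L frequencies.  All analytic
linkage-disequilibrium (LD) quantities used elsewhere in the package — pairwise
haploid D, three-locus D, and every genotypic moment — are derived from this
table by enumeration, so the distribution is the single source of truth.

Conventions
-----------
* Allele 1 is the counted (reference) allele; allele 0 the alternative.
* Haplotypes are indexed by bit pattern with locus 0 as the most significant
  bit, e.g. for L=3 the pattern ``"110"`` carries allele 1 at loci 0 and 1.
* Pairwise D is the haploid central second moment
  ``E[(A_j - p_j)(A_k - p_k)]`` and three-locus D the central third moment,
  i.e. the Bennett parametrization; both map one-to-one onto the genotypic
  moments under random mating (genotypic moment = 2 x haploid moment).
* Diploid genotypes are formed by the union of two independent haplotypes
  (random mating / Hardy-Weinberg).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HaplotypeDistribution",
    "GenotypeMatrix",
    "InfeasibleLDError",
    "UnsupportedConstructorError",
    "make_haplotype_distribution",
    "sample_genotypes",
]

_SUM_TOL = 1e-12


class InfeasibleLDError(ValueError):
    """Requested allele frequencies and D coefficients imply a negative haplotype frequency."""


class UnsupportedConstructorError(ValueError):
    """Closed-form constructor only covers 2 or 3 loci; supply frequencies directly otherwise."""


def _bit_patterns(n_loci: int) -> np.ndarray:
    """(2**L, L) array of allele indicators, locus 0 in column 0 (MSB order)."""
    return np.array(list(itertools.product((0, 1), repeat=n_loci)), dtype=np.int8)


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Exact law of an L-locus haplotype.

    Parameters
    ----------
    frequencies
        Vector of 2**L nonnegative reals summing to 1, indexed by haplotype
        bit pattern (locus 0 = most significant bit).
    locus_labels
        Optional identifiers, default ``L1..L{L}``.
    positions
        Optional strictly increasing base-pair coordinates.
    """

    frequencies: np.ndarray
    locus_labels: tuple[str, ...] = ()
    positions: np.ndarray | None = None
    n_loci: int = field(init=False)

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float).ravel()
        L = int(np.log2(freq.size))
        if 2**L != freq.size or L < 2:
            raise ValueError(f"frequency vector length {freq.size} is not 2**L for L >= 2")
        if np.any(freq < 0):
            raise ValueError("haplotype frequencies must be nonnegative")
        if abs(freq.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"haplotype frequencies sum to {freq.sum()!r}, not 1")
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "n_loci", L)
        labels = tuple(self.locus_labels) or tuple(f"L{j + 1}" for j in range(L))
        if len(labels) != L:
            raise ValueError("locus_labels length must equal the number of loci")
        object.__setattr__(self, "locus_labels", labels)
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.size != L or np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing, one per locus")
            object.__setattr__(self, "positions", pos)
        p = self.allele_frequencies()
        if np.any(p <= 0) or np.any(p >= 1):
            bad = [labels[j] for j in np.nonzero((p <= 0) | (p >= 1))[0]]
            raise ValueError(f"monomorphic locus (allele frequency 0 or 1): {bad}")

    # -- derived quantities -------------------------------------------------

    @property
    def patterns(self) -> np.ndarray:
        return _bit_patterns(self.n_loci)

    def allele_frequencies(self) -> np.ndarray:
        """Marginal frequency of allele 1 at each locus."""
        return self.frequencies @ _bit_patterns(self.n_loci).astype(float)

    def pairwise_D(self, i: int, j: int) -> float:
        """Haploid LD coefficient D_ij = E[(A_i - p_i)(A_j - p_j)]."""
        p = self.allele_frequencies()
        H = self.patterns.astype(float)
        return float(self.frequencies @ ((H[:, i] - p[i]) * (H[:, j] - p[j])))

    def three_locus_D(self, i: int, j: int, k: int) -> float:
        """Haploid three-locus LD: the central third moment of the allele indicators."""
        p = self.allele_frequencies()
        H = self.patterns.astype(float)
        c = (H[:, i] - p[i]) * (H[:, j] - p[j]) * (H[:, k] - p[k])
        return float(self.frequencies @ c)

    def haploid_correlation(self, i: int, j: int) -> float:
        p = self.allele_frequencies()
        return self.pairwise_D(i, j) / np.sqrt(p[i] * (1 - p[i]) * p[j] * (1 - p[j]))

    def marginal(self, loci: Sequence[int]) -> "HaplotypeDistribution":
        """Marginal distribution over a subset of loci, in the given order."""
        loci = list(loci)
        table = self.frequencies.reshape((2,) * self.n_loci)
        drop = tuple(ax for ax in range(self.n_loci) if ax not in loci)
        kept = table.sum(axis=drop) if drop else table
        # surviving axes come out in sorted(loci) order; axis t (locus
        # sorted(loci)[t]) must move to that locus's position in `loci`
        kept = np.moveaxis(kept, range(len(loci)), np.argsort(loci))
        pos = None
        if self.positions is not None and loci == sorted(loci):
            pos = self.positions[loci]
        return HaplotypeDistribution(
            kept.ravel(),
            locus_labels=tuple(self.locus_labels[j] for j in loci),
            positions=pos,
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "locus_labels": list(self.locus_labels),
            "positions": None if self.positions is None else list(self.positions),
            "frequencies": {
                "".join(map(str, pat)): f
                for pat, f in zip(self.patterns.tolist(), self.frequencies)
                if f != 0.0
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "HaplotypeDistribution":
        payload = json.loads(text)
        keys = list(payload["frequencies"])
        L = len(keys[0])
        freq = np.zeros(2**L)
        for k, v in payload["frequencies"].items():
            freq[int(k, 2)] = v
        return cls(
            freq,
            locus_labels=tuple(payload.get("locus_labels") or ()),
            positions=payload.get("positions"),
        )


def make_haplotype_distribution(
    allele_freqs: Sequence[float],
    pairwise_D: float | np.ndarray | Mapping[tuple[int, int], float] | None = None,
    three_locus_D: float = 0.0,
    locus_labels: Sequence[str] = (),
    positions: Sequence[float] | None = None,
) -> HaplotypeDistribution:
    """Closed-form 2- or 3-locus distribution from marginals and D coefficients.

    Each haplotype frequency is the product of its marginal allele
    probabilities plus signed D corrections (Bennett parametrization)::

        P(a1, a2)     = p1(a1) p2(a2) + s1 s2 D12
        P(a1, a2, a3) = p1(a1) p2(a2) p3(a3) + s1 s2 D12 p3(a3)
                        + s1 s3 D13 p2(a2) + s2 s3 D23 p1(a1) + s1 s2 s3 D123

    with ``s_j = +1`` for allele 1 and ``-1`` for allele 0.  The resulting
    marginals, pairwise central second moments, and (for L=3) the central
    third moment match the inputs exactly.

    Raises
    ------
    InfeasibleLDError
        If any implied haplotype frequency is negative (names the haplotype).
    UnsupportedConstructorError
        For more than three loci; build from explicit frequencies instead.
    """
    p = np.asarray(allele_freqs, dtype=float)
    L = p.size
    if L not in (2, 3):
        raise UnsupportedConstructorError(
            f"closed-form constructor supports L in {{2, 3}}, got L={L}; "
            "pass explicit frequencies to HaplotypeDistribution for larger L"
        )
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")

    D = np.zeros((L, L))
    if pairwise_D is not None:
        if np.isscalar(pairwise_D):
            if L != 2:
                raise ValueError("scalar pairwise_D only valid for two loci")
            D[0, 1] = D[1, 0] = float(pairwise_D)
        elif isinstance(pairwise_D, Mapping):
            for (i, j), v in pairwise_D.items():
                D[i, j] = D[j, i] = float(v)
        else:
            D = np.asarray(pairwise_D, dtype=float)
            if D.shape != (L, L) or not np.allclose(D, D.T):
                raise ValueError("pairwise_D must be a symmetric LxL matrix")

    H = _bit_patterns(L).astype(float)
    s = 2.0 * H - 1.0  # signs: allele 1 -> +1, allele 0 -> -1
    marg = np.where(H == 1, p, 1.0 - p)  # per-locus marginal probability of the carried allele
    freq = marg.prod(axis=1)
    if L == 2:
        freq = freq + s[:, 0] * s[:, 1] * D[0, 1]
    else:
        freq = (
            freq
            + s[:, 0] * s[:, 1] * D[0, 1] * marg[:, 2]
            + s[:, 0] * s[:, 2] * D[0, 2] * marg[:, 1]
            + s[:, 1] * s[:, 2] * D[1, 2] * marg[:, 0]
            + s[:, 0] * s[:, 1] * s[:, 2] * float(three_locus_D)
        )

    if np.any(freq < -1e-12):
        worst = int(np.argmin(freq))
        pat = "".join(map(str, _bit_patterns(L)[worst]))
        raise InfeasibleLDError(
            f"requested D coefficients are infeasible: haplotype {pat} "
            f"would have frequency {freq[worst]:.3e}"
        )
    freq = np.clip(freq, 0.0, None)
    return HaplotypeDistribution(
        freq, locus_labels=tuple(locus_labels), positions=positions
    )


# ---------------------------------------------------------------------------
# diploid genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """n x L diploid allele-count codes, raw (0/1/2) or mean-centered.

    ``sample_means`` records the vector subtracted when ``centered`` is true,
    so the raw codes can always be recovered and the centering convention
    (sample vs. population means) stays auditable.
    """

    codes: np.ndarray
    centered: bool = False
    sample_means: np.ndarray | None = None
    locus_labels: tuple[str, ...] = ()
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (n x L) array")
        if not self.centered:
            vals = np.unique(self.codes)
            if not np.isin(vals, (0, 1, 2)).all():
                raise ValueError(f"raw genotype codes must be in {{0,1,2}}, found {vals[:5]}")
        if not self.locus_labels:
            self.locus_labels = tuple(f"L{j + 1}" for j in range(self.codes.shape[1]))

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        if self.centered:
            raise ValueError("allele frequencies are defined on raw codes")
        return self.codes.mean(axis=0) / 2.0

    def center(self, means: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a centered copy.

        With ``means=None`` columns are sample-centered (the default for data
        paths); passing ``2 * p`` with population allele frequencies ``p``
        gives population centering (the convention of the analytic results).
        """
        if self.centered:
            raise ValueError("matrix is already centered")
        mu = self.codes.mean(axis=0) if means is None else np.asarray(means, dtype=float)
        return GenotypeMatrix(
            self.codes.astype(float) - mu,
            centered=True,
            sample_means=mu,
            locus_labels=self.locus_labels,
            positions=self.positions,
        )


def sample_genotypes(
    dist: HaplotypeDistribution,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw n random-mating diploids: each individual is the union of two
    independent haplotypes from ``dist``.  Reproducible under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(dist.frequencies.size, size=(int(n), 2), p=dist.frequencies)
    H = dist.patterns
    codes = H[idx[:, 0]] + H[idx[:, 1]]
    return GenotypeMatrix(
        codes.astype(np.int8),
        locus_labels=dist.locus_labels,
        positions=dist.positions,
    )
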