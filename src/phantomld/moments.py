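"""Genotypic moments of the three-locus system (QTL z, markers x1, x2).

The population regression coefficients of the marker-interaction model are
determined by a 3x3 matrix of genotypic moments of the centered marker codes,

    T = [ E(x1^2)     E(x1 x2)    E(x1^2 x2)                    ]
        [ E(x1 x2)    E(x2^2)     E(x1 x2^2)                    ]
        [ E(x1^2 x2)  E(x1 x2^2)  E(x1^2 x2^2) - E(x1 x2)^2     ]

together with the right-hand side (E(z x1), E(z x2), E(z x1 x2)) for an
additive QTL, or (E(z^2 x1), E(z^2 x2), E(z^2 x1 x2)) for the dominance part.
T is the covariance matrix of the regressors (x1, x2, x1*x2) once an
intercept absorbs the mean of the interaction product — which is why the
(3,3) entry carries the -E(x1 x2)^2 correction — so the exact solve and an
intercept-including OLS estimate the same population coefficients.

Exact moments are computed canonically by enumerating all 2^L x 2^L ordered
diplotypes of a :class:`HaplotypeDistribution` with population-centered
codes; empirical moments replace each expectation by a sample average over a
sample-centered :class:`GenotypeMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import json
import numpy as np

from .haplotypes import GenotypeMatrix, HaplotypeDistribution

__all__ = [
    "MomentSet",
    "LDSummary",
    "UncenteredError",
    "PhaseUnknownError",
    "exact_moments",
    "empirical_moments",
    "ld_summary",
]


class UncenteredError(ValueError):
    """Empirical moments require explicitly centered genotype columns."""


class PhaseUnknownError(ValueError):
    """Haploid LD quantities are unavailable from unphased genotype data."""


@dataclass
class MomentSet:
    """The moments entering the population coefficient system.

    Attributes
    ----------
    T : (3, 3) symmetric moment matrix (see module docstring).
    rhs_additive : (E(z x1), E(z x2), E(z x1 x2)) for unit QTL effect.
    rhs_dominance : (E(z^2 x1), E(z^2 x2), E(z^2 x1 x2)), z centered.
    var_z : E(z^2), needed to diagnose perfect LD (QTL R^2 on the markers).
    source : "exact" (diplotype enumeration) or "empirical" (sample averages).
    n : sample size when empirical.
    """

    T: np.ndarray
    rhs_additive: np.ndarray
    rhs_dominance: np.ndarray | None = None
    var_z: float = np.nan
    source: str = "exact"
    n: int | None = None
    raw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.rhs_additive = np.asarray(self.rhs_additive, dtype=float)
        if self.T.shape != (3, 3) or not np.allclose(self.T, self.T.T, atol=1e-10):
            raise ValueError("T must be a symmetric 3x3 matrix")
        if self.T[0, 0] <= 0 or self.T[1, 1] <= 0:
            raise ValueError("marker variances must be strictly positive (polymorphic loci)")
        if self.rhs_dominance is not None:
            self.rhs_dominance = np.asarray(self.rhs_dominance, dtype=float)

    def qtl_r2_joint(self) -> float:
        """Population R^2 of the regression of z on (x1, x2).

        Equals 1 exactly when z is almost surely a linear function of the two
        marker codes (perfect LD).  Uses a pseudo-inverse so collinear
        markers are handled.
        """
        S = self.T[:2, :2]
        v = self.rhs_additive[:2]
        if not np.isfinite(self.var_z) or self.var_z <= 0:
            raise ValueError("var_z not available")
        return float(v @ np.linalg.pinv(S) @ v / self.var_z)

    def to_json(self) -> str:
        return json.dumps(
            {
                "T": self.T.tolist(),
                "rhs_additive": self.rhs_additive.tolist(),
                "rhs_dominance": None if self.rhs_dominance is None else self.rhs_dominance.tolist(),
                "var_z": self.var_z,
                "source": self.source,
                "n": self.n,
            },
            indent=1,
        )


def _moments_from_columns(
    z: np.ndarray, x1: np.ndarray, x2: np.ndarray, w: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, dict[str, float]]:
    """Shared moment assembly given (weighted or sample) centered columns.

    ``w`` are probability weights for exact enumeration; ``None`` means the
    uniform sample average.
    """

    def E(a: np.ndarray) -> float:
        return float(a @ w) if w is not None else float(a.mean())

    m = {
        "E_x1_sq": E(x1**2),
        "E_x2_sq": E(x2**2),
        "E_x1x2": E(x1 * x2),
        "E_x1sq_x2": E(x1**2 * x2),
        "E_x1_x2sq": E(x1 * x2**2),
        "E_x1sq_x2sq": E(x1**2 * x2**2),
        "E_zx1": E(z * x1),
        "E_zx2": E(z * x2),
        "E_zx1x2": E(z * x1 * x2),
        "E_zsq_x1": E(z**2 * x1),
        "E_zsq_x2": E(z**2 * x2),
        "E_zsq_x1x2": E(z**2 * x1 * x2),
        "E_z_sq": E(z**2),
    }
    T = np.array(
        [
            [m["E_x1_sq"], m["E_x1x2"], m["E_x1sq_x2"]],
            [m["E_x1x2"], m["E_x2_sq"], m["E_x1_x2sq"]],
            [m["E_x1sq_x2"], m["E_x1_x2sq"], m["E_x1sq_x2sq"] - m["E_x1x2"] ** 2],
        ]
    )
    rhs_add = np.array([m["E_zx1"], m["E_zx2"], m["E_zx1x2"]])
    rhs_dom = np.array([m["E_zsq_x1"], m["E_zsq_x2"], m["E_zsq_x1x2"]])
    return T, rhs_add, rhs_dom, m["E_z_sq"], m


def _diplotype_columns(dist: HaplotypeDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Centered genotype codes over all ordered diplotypes, with probabilities.

    Returns ``(X, w)`` where X is (4**L, L) population-centered codes and w
    the diplotype probabilities (outer product of haplotype frequencies —
    random mating).
    """
    H = dist.patterns.astype(float)
    f = dist.frequencies
    codes = (H[:, None, :] + H[None, :, :]).reshape(-1, dist.n_loci)
    w = np.outer(f, f).ravel()
    return codes - 2.0 * dist.allele_frequencies(), w


def exact_moments(
    dist: HaplotypeDistribution,
    qtl_index: int = 0,
    marker_indices: tuple[int, int] = (1, 2),
) -> MomentSet:
    """Population moments by exact enumeration over all ordered diplotypes.

    Codes are population-centered (g - 2p); no sampling error.  The three
    indices must be distinct loci of ``dist``.
    """
    i1, i2 = marker_indices
    if len({qtl_index, i1, i2}) != 3:
        raise ValueError("qtl_index and marker_indices must be three distinct loci")
    X, w = _diplotype_columns(dist)
    T, rhs_add, rhs_dom, var_z, raw = _moments_from_columns(
        X[:, qtl_index], X[:, i1], X[:, i2], w
    )
    return MomentSet(T, rhs_add, rhs_dom, var_z=var_z, source="exact", raw=raw)


def empirical_moments(
    G: GenotypeMatrix, z_column: int, marker_columns: tuple[int, int]
) -> MomentSet:
    """Sample analogue: each expectation replaced by the sample average.

    Requires an explicitly sample-centered matrix — silent auto-centering is
    refused so the centering convention stays auditable.
    """
    if not G.centered:
        raise UncenteredError("empirical moments require a centered GenotypeMatrix (call .center())")
    if G.n < 10:
        raise ValueError("need at least 10 individuals")
    cols = (z_column, *marker_columns)
    if len(set(cols)) != 3:
        raise ValueError("z_column and marker_columns must be three distinct columns")
    # population-centered input is accepted too: columns then need not have
    # zero sample mean, but the means used are recorded on the matrix
    for c in cols:
        if np.var(G.codes[:, c]) == 0:
            raise ValueError(f"column {G.locus_labels[c]} is constant (monomorphic)")
    z, x1, x2 = (G.codes[:, c].astype(float) for c in cols)
    T, rhs_add, rhs_dom, var_z, raw = _moments_from_columns(z, x1, x2)
    return MomentSet(T, rhs_add, rhs_dom, var_z=var_z, source="empirical", n=G.n, raw=raw)


# ---------------------------------------------------------------------------
# LD summaries
# ---------------------------------------------------------------------------


@dataclass
class LDSummary:
    """Standard LD descriptors for a pair or triple of loci.

    ``qtl_r2_joint`` is the proportion of variance of the QTL genotype
    explained by (linear regression on) the two markers; for a pair only the
    pairwise entries are filled.
    """

    haploid_D: dict[tuple[int, int], float] | None
    three_locus_D: float | None
    genotypic_covariances: dict[tuple[int, int], float]
    r_squared: dict[tuple[int, int], float]
    qtl_r2_joint: float | None
    source: str

    def to_json(self) -> str:
        def keyed(d):
            return None if d is None else {f"{i},{j}": v for (i, j), v in d.items()}

        return json.dumps(
            {
                "haploid_D": keyed(self.haploid_D),
                "three_locus_D": self.three_locus_D,
                "genotypic_covariances": keyed(self.genotypic_covariances),
                "r_squared": keyed(self.r_squared),
                "qtl_r2_joint": self.qtl_r2_joint,
                "source": self.source,
            },
            indent=1,
        )


def ld_summary(
    dist_or_G: HaplotypeDistribution | GenotypeMatrix,
    loci: Sequence[int],
) -> LDSummary:
    """LD summary for 2 or 3 loci; with 3 loci the first is treated as the QTL.

    From an exact distribution, haploid D and (for 3 loci) the three-locus D
    are reported alongside genotypic covariances — equal to twice the haploid
    values under random mating — and pairwise genotypic R^2.  From genotype
    data only genotypic quantities are available (phase unknown).
    """
    loci = list(loci)
    if len(loci) not in (2, 3):
        raise ValueError("ld_summary takes two or three loci")

    if isinstance(dist_or_G, HaplotypeDistribution):
        dist = dist_or_G
        X, w = _diplotype_columns(dist)
        cov = {
            (i, j): float((X[:, i] * X[:, j]) @ w)
            for i, j in _pairs(loci)
        }
        var = {i: float((X[:, i] ** 2) @ w) for i in loci}
        r2 = {ij: cov[ij] ** 2 / (var[ij[0]] * var[ij[1]]) for ij in cov}
        hap = {ij: dist.pairwise_D(*ij) for ij in cov}
        d3 = dist.three_locus_D(*loci) if len(loci) == 3 else None
        qtl_r2 = None
        if len(loci) == 3:
            qtl_r2 = exact_moments(dist, loci[0], (loci[1], loci[2])).qtl_r2_joint()
        return LDSummary(hap, d3, cov, r2, qtl_r2, "exact")

    G = dist_or_G
    X = G.codes.astype(float)
    X = X - X.mean(axis=0)
    cov = {(i, j): float((X[:, i] * X[:, j]).mean()) for i, j in _pairs(loci)}
    var = {i: float((X[:, i] ** 2).mean()) for i in loci}
    if any(v == 0 for v in var.values()):
        raise ValueError("monomorphic column among requested loci")
    r2 = {ij: cov[ij] ** 2 / (var[ij[0]] * var[ij[1]]) for ij in cov}
    qtl_r2 = None
    if len(loci) == 3:
        z = X[:, loci[0]]
        M = X[:, [loci[1], loci[2]]]
        v = M.T @ z / G.n
        S = M.T @ M / G.n
        qtl_r2 = float(v @ np.linalg.pinv(S) @ v / var[loci[0]])
    return LDSummary(None, None, cov, r2, qtl_r2, "empirical")


def haploid_ld_from_genotypes(*_args, **_kwargs):
    raise PhaseUnknownError("haploid D cannot be computed from unphased genotypes")


def _pairs(loci: Sequence[int]):
    return [(loci[a], loci[b]) for a in range(len(loci)) for b in range(a + 1, len(loci))]
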