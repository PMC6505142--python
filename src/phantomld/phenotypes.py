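"""Quantitative-trait phenotype simulators.

All simulators act on *centered* genotype codes and target unit total
phenotypic variance (except the dominance simulator, whose error variance is
free).  The additive single-QTL model is

    y_i = z_i * b + delta_i,    delta_i ~ Normal(0, 1 - phi),

with the QTL effect scaled as ``b = sqrt(phi / Var(z))`` so the causal locus
explains a stated fraction ``phi`` of the phenotypic variance.  The dominance
model adds a term in the squared (centered) QTL code; the multi-locus model
sums per-QTL additive effects and an optional infinitesimal (polygenic)
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .haplotypes import GenotypeMatrix

__all__ = [
    "PhenotypeVector",
    "simulate_phenotype_additive",
    "simulate_phenotype_dominance",
    "simulate_phenotype_multilocus",
]


@dataclass
class PhenotypeVector:
    """Simulated phenotypes plus a record of the generating parameters."""

    values: np.ndarray
    model_tag: str
    true_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.values.size


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _as_centered_column(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float).ravel()
    if z.size < 2 or np.var(z) == 0:
        raise ValueError("QTL column must be non-constant")
    return z


def simulate_phenotype_additive(
    z: np.ndarray,
    qtl_variance_fraction: float,
    seed: int | np.random.Generator | None = None,
    var_z: float | None = None,
) -> PhenotypeVector:
    """Additive single-QTL trait with unit total variance.

    Parameters
    ----------
    z
        Centered QTL genotype column.
    qtl_variance_fraction
        phi in (0, 1): fraction of phenotypic variance explained by the QTL.
    var_z
        Population variance of the QTL code, used to scale the effect;
        defaults to the sample variance of ``z`` (flagged in ``true_params``).
    """
    phi = float(qtl_variance_fraction)
    if not 0.0 < phi < 1.0:
        raise ValueError(f"qtl_variance_fraction must lie in (0, 1), got {phi}")
    z = _as_centered_column(z)
    vz = float(np.var(z)) if var_z is None else float(var_z)
    if vz <= 0:
        raise ValueError("Var(z) must be positive")
    b = np.sqrt(phi / vz)
    rng = _rng(seed)
    y = z * b + rng.normal(0.0, np.sqrt(1.0 - phi), z.size)
    return PhenotypeVector(
        y,
        "additive",
        {"b": float(b), "phi": phi, "var_z": vz, "var_z_source": "population" if var_z is not None else "sample"},
    )


def simulate_phenotype_dominance(
    z: np.ndarray,
    a: float,
    d: float,
    error_variance: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> PhenotypeVector:
    """Single-QTL trait with additive value ``a`` and dominance value ``d``:
    ``y = a z + d z**2 + delta``, then mean-centered (the square of the
    centered code is not itself re-centered; centering y absorbs its mean)."""
    if error_variance <= 0:
        raise ValueError("error_variance must be positive")
    z = _as_centered_column(z)
    rng = _rng(seed)
    y = a * z + d * z**2 + rng.normal(0.0, np.sqrt(error_variance), z.size)
    y -= y.mean()
    return PhenotypeVector(y, "dominance", {"a": float(a), "d": float(d), "error_variance": float(error_variance)})


def simulate_phenotype_multilocus(
    Z: np.ndarray,
    variance_fractions: Sequence[float],
    polygenic_fraction: float = 0.0,
    polygenic_source: GenotypeMatrix | np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    var_z: Sequence[float] | None = None,
) -> PhenotypeVector:
    """Additive multi-QTL trait, optionally with an infinitesimal component.

    Each QTL column j gets effect ``b_j = sqrt(phi_j / Var(z_j))``.  The
    infinitesimal term is a scaled sum of equal standardized effects over the
    background loci in ``polygenic_source`` (scaled empirically to variance
    ``polygenic_fraction``); without a source it is an independent Normal
    deviate of that variance.  The residual tops total variance up to 1, so
    ``sum(phi_j) + polygenic_fraction`` must be < 1.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1 and len(variance_fractions) == 1:
        Z = Z.T
    phis = np.asarray(variance_fractions, dtype=float)
    if phis.size != Z.shape[1]:
        raise ValueError("one variance fraction per QTL column required")
    if np.any(phis <= 0):
        raise ValueError("variance fractions must be positive")
    poly = float(polygenic_fraction)
    if poly < 0:
        raise ValueError("polygenic_fraction must be nonnegative")
    budget = phis.sum() + poly
    if budget >= 1.0:
        raise ValueError(f"variance budget {budget:.4f} must be < 1")

    if var_z is None:
        vz = Z.var(axis=0)
    else:
        vz = np.asarray(var_z, dtype=float)
    if np.any(vz <= 0):
        raise ValueError("every QTL column must have positive variance")
    b = np.sqrt(phis / vz)
    rng = _rng(seed)
    y = Z @ b

    if poly > 0:
        if polygenic_source is not None:
            B = polygenic_source.codes if isinstance(polygenic_source, GenotypeMatrix) else np.asarray(polygenic_source, float)
            B = B - B.mean(axis=0)
            sd = B.std(axis=0)
            ok = sd > 0
            if not ok.any():
                raise ValueError("polygenic_source has no polymorphic loci")
            u = (B[:, ok] / sd[ok]).sum(axis=1)  # equal effects on the standardized scale
            su = u.std()
            if su == 0:
                raise ValueError("polygenic score is constant in this sample")
            y = y + u * (np.sqrt(poly) / su)
        else:
            y = y + rng.normal(0.0, np.sqrt(poly), Z.shape[0])

    y = y + rng.normal(0.0, np.sqrt(1.0 - budget), Z.shape[0])
    tag = "multilocus+infinitesimal" if poly > 0 else "multilocus"
    return PhenotypeVector(
        y,
        tag,
        {"b": b, "phi": phis, "polygenic_fraction": poly, "var_z": vz},
    )
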