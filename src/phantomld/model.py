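"""Population coefficients of the marker-interaction model and the
necessary conditions for phantom epistasis.

For an additive QTL with effect b, the population coefficients of the
instrumental regression ``y = x1 b1 + x2 b2 + x1 x2 b12 + e`` solve

    T (beta1, beta2, beta12)' = (E(z x1), E(z x2), E(z x1 x2))' b,

with T the genotypic moment matrix of :mod:`phantomld.moments`.  The
interaction coefficient admits the explicit form

    beta12 = [t31 E(z x1) + t32 E(z x2) + t33 E(z x1 x2)] b,

where (t31, t32, t33) is the third row of T^{-1}; both routes are computed
and checked against each other.  With dominance the right-hand side becomes
``a * rhs_additive + d * rhs_dominance``; with multiple QTLs it is the sum of
per-QTL right-hand sides weighted by the effects.

A nonzero beta12 under a purely additive (or dominant) causal model is
*phantom epistasis*.  It requires the QTL and the two markers to be in
mutual but imperfect LD: (1) the QTL in LD with at least one marker, (2) the
QTL not a linear function of the marker pair, and (3) no variable
independent of the other two (joint three-locus LD).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .haplotypes import HaplotypeDistribution
from .moments import MomentSet, exact_moments

__all__ = [
    "CoefficientSolution",
    "ConditionReport",
    "DegenerateSystemError",
    "solve_population_coefficients",
    "solve_population_coefficients_dominance",
    "interaction_coefficient_multilocus",
    "check_necessary_conditions",
]

_RANK_RTOL = 1e-10
_AGREE_TOL = 1e-10


class DegenerateSystemError(RuntimeError):
    """Raised internally when the two beta12 routes disagree (numerical fault)."""


@dataclass
class CoefficientSolution:
    """Population (beta1, beta2, beta12) with degeneracy diagnostics.

    When ``degenerate`` is true the moment matrix T was numerically singular:
    if the QTL is in perfect LD with the marker pair the interaction
    coefficient is identically zero and is reported as such; otherwise the
    coefficients are not identified and are withheld (NaN).
    """

    beta1: float
    beta2: float
    beta12: float
    t_row3: np.ndarray | None
    degenerate: bool
    qtl_effect_scale: dict[str, float] = field(default_factory=dict)
    qtl_r2_joint: float | None = None

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta1, self.beta2, self.beta12])

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta1": self.beta1,
                "beta2": self.beta2,
                "beta12": self.beta12,
                "t_row3": None if self.t_row3 is None else self.t_row3.tolist(),
                "degenerate": self.degenerate,
                "qtl_effect_scale": self.qtl_effect_scale,
                "qtl_r2_joint": self.qtl_r2_joint,
            },
            indent=1,
        )


def _solve(T: np.ndarray, rhs: np.ndarray, var_z: float, scale: dict[str, float]) -> CoefficientSolution:
    s = np.linalg.svd(T, compute_uv=False)
    rank = int(np.sum(s > s[0] * _RANK_RTOL))
    r2 = None
    if rank == 3:
        beta = np.linalg.solve(T, rhs)
        t_row3 = np.linalg.inv(T)[2]
        beta12_explicit = float(t_row3 @ rhs)
        if abs(beta12_explicit - beta[2]) > _AGREE_TOL * max(1.0, abs(beta[2])):
            raise DegenerateSystemError(
                f"linear-solve and t-row beta12 disagree: {beta[2]!r} vs {beta12_explicit!r}"
            )
        return CoefficientSolution(
            float(beta[0]), float(beta[1]), float(beta[2]), t_row3, False, scale
        )

    # singular T: identified only under perfect LD (QTL linear in the markers),
    # in which case the interaction coefficient is exactly zero
    perfect = False
    if np.isfinite(var_z) and var_z > 0:
        S = T[:2, :2]
        v = rhs[:2]
        r2 = float(v @ np.linalg.pinv(S) @ v / var_z)
        perfect = r2 >= 1.0 - 1e-8
    if perfect:
        b12 = 0.0
        b_main, *_ = np.linalg.lstsq(T[:2, :2], rhs[:2], rcond=None)
        return CoefficientSolution(
            float(b_main[0]), float(b_main[1]), b12, None, True, scale, qtl_r2_joint=r2
        )
    return CoefficientSolution(np.nan, np.nan, np.nan, None, True, scale, qtl_r2_joint=r2)


def solve_population_coefficients(moments: MomentSet, b: float = 1.0) -> CoefficientSolution:
    """Solve the population system for an additive QTL with effect ``b``.

    All three coefficients are exactly linear in b.  On a singular moment
    matrix the perfect-LD rule applies (see :class:`CoefficientSolution`).
    """
    rhs = moments.rhs_additive * float(b)
    var_z = moments.var_z * b * b if np.isfinite(moments.var_z) else np.nan
    sol = _solve(moments.T, rhs, var_z, {"b": float(b)})
    if sol.qtl_r2_joint is None and np.isfinite(moments.var_z) and moments.var_z > 0:
        sol.qtl_r2_joint = moments.qtl_r2_joint()
    return sol


def solve_population_coefficients_dominance(
    moments: MomentSet, a: float, d: float
) -> CoefficientSolution:
    """Solve with a dominant QTL: right-hand side ``a*rhs_additive + d*rhs_dominance``."""
    if moments.rhs_dominance is None:
        raise ValueError("MomentSet lacks the dominance right-hand side")
    rhs = float(a) * moments.rhs_additive + float(d) * moments.rhs_dominance
    # perfect-LD diagnosis still refers to the additive QTL signal; a singular
    # T with an unexplained dominance signal is left unidentified
    var_sig = moments.var_z if np.isfinite(moments.var_z) else np.nan
    sol = _solve(moments.T, rhs, np.nan if d != 0 else var_sig, {"a": float(a), "d": float(d)})
    return sol


def interaction_coefficient_multilocus(
    per_qtl_moments: Sequence[MomentSet | np.ndarray],
    effects: Sequence[float],
    T: np.ndarray | None = None,
) -> float:
    """beta12 of the combined additive multi-QTL model.

    Each QTL j contributes ``b_j * (E(x1 z_j), E(x2 z_j), E(x1 x2 z_j))`` to
    the right-hand side against a *shared* marker pair; beta12 is the third
    component of ``T^{-1} sum_j b_j rhs_j`` and is exactly linear in each
    effect.  MomentSets must all refer to the same marker pair (their T
    matrices must agree); alternatively pass raw rhs vectors plus T.
    """
    effects = np.asarray(effects, dtype=float)
    if len(per_qtl_moments) != effects.size:
        raise ValueError("one effect per QTL right-hand side required")
    rhs_list = []
    for m in per_qtl_moments:
        if isinstance(m, MomentSet):
            if T is None:
                T = m.T
            elif not np.allclose(T, m.T, atol=1e-9):
                raise ValueError("moment sets refer to different marker pairs (T matrices differ)")
            rhs_list.append(m.rhs_additive)
        else:
            rhs_list.append(np.asarray(m, dtype=float))
    if T is None:
        raise ValueError("marker moment matrix T required with raw rhs vectors")
    rhs = np.einsum("j,jk->k", effects, np.vstack(rhs_list))
    sol = _solve(np.asarray(T, float), rhs, np.nan, {"b": effects.tolist()})
    if sol.degenerate:
        raise np.linalg.LinAlgError("marker moment matrix is singular")
    return sol.beta12


# ---------------------------------------------------------------------------
# necessary conditions
# ---------------------------------------------------------------------------


@dataclass
class ConditionReport:
    """Audit of the three necessary conditions for phantom epistasis.

    ``qtl_marker_LD`` flags which QTL-involving moments are nonzero at the
    tolerance; ``perfect_LD`` is true when the QTL genotype is a linear
    function of the marker pair; ``mutual_three_locus_LD`` is true when the
    haploid law does not factorize over any bipartition of the three loci.
    ``phantom_possible`` is the conjunction of the three conditions.
    """

    qtl_marker_LD: dict[str, bool]
    perfect_LD: bool
    mutual_three_locus_LD: bool
    phantom_possible: bool
    moments: dict[str, float] = field(default_factory=dict)
    tol: float = 1e-10

    def to_json(self) -> str:
        return json.dumps(
            {
                "qtl_marker_LD": self.qtl_marker_LD,
                "perfect_LD": self.perfect_LD,
                "mutual_three_locus_LD": self.mutual_three_locus_LD,
                "phantom_possible": self.phantom_possible,
                "moments": self.moments,
                "tol": self.tol,
            },
            indent=1,
        )


def _factorizes(dist: HaplotypeDistribution, part_a: list[int], part_b: list[int], tol: float) -> bool:
    ka, kb = len(part_a), len(part_b)
    joint = dist.marginal(part_a + part_b).frequencies.reshape((2,) * (ka + kb))
    fa = joint.sum(axis=tuple(range(ka, ka + kb)))
    fb = joint.sum(axis=tuple(range(ka)))
    prod = np.multiply.outer(fa, fb)
    return bool(np.max(np.abs(joint - prod)) <= tol)


def check_necessary_conditions(
    dist: HaplotypeDistribution,
    qtl_index: int = 0,
    marker_indices: tuple[int, int] = (1, 2),
    tol: float = 1e-10,
) -> ConditionReport:
    """Evaluate, from exact moments, whether phantom epistasis can emerge.

    1. The QTL must be in LD with at least one marker (some QTL-involving
       moment nonzero).
    2. The LD must be imperfect: the QTL genotype is not fully explained by
       linear regression on the marker pair.
    3. The three loci must be jointly in LD: the haploid distribution does
       not factorize as p(z,x1)p(x2), p(z,x2)p(x1) or p(z)p(x1,x2).
    """
    i1, i2 = marker_indices
    m = exact_moments(dist, qtl_index, marker_indices)
    lead = {
        "E_zx1": bool(abs(m.rhs_additive[0]) > tol),
        "E_zx2": bool(abs(m.rhs_additive[1]) > tol),
        "E_zx1x2": bool(abs(m.rhs_additive[2]) > tol),
    }
    cond1 = any(lead.values())
    r2 = m.qtl_r2_joint()
    perfect = r2 >= 1.0 - max(tol, 1e-12)
    cond3 = not (
        _factorizes(dist, [qtl_index], [i1, i2], tol)
        or _factorizes(dist, [i1], [qtl_index, i2], tol)
        or _factorizes(dist, [i2], [qtl_index, i1], tol)
    )
    return ConditionReport(
        qtl_marker_LD=lead,
        perfect_LD=perfect,
        mutual_three_locus_LD=cond3,
        phantom_possible=cond1 and not perfect and cond3,
        moments={
            "E_zx1": float(m.rhs_additive[0]),
            "E_zx2": float(m.rhs_additive[1]),
            "E_zx1x2": float(m.rhs_additive[2]),
            "qtl_r2_joint": float(r2),
        },
        tol=tol,
    )
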