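"""Monte Carlo rejection-rate studies.

Each scenario repeatedly (i) draws random-mating diploid genotypes from an
exact haplotype distribution or from the Markov chromosome emulator,
(ii) simulates an additive, dominant, or multi-locus phenotype, (iii) fits
the marker-interaction model by OLS and tests H0: beta12 = 0 at level alpha.
The empirical rejection fraction, with its binomial Monte Carlo standard
error sqrt(r(1-r)/replicates), is the quantity of interest: values above
alpha under a non-epistatic generating model indicate phantom epistasis.

Every experiment is a pure function of its scenario, master seed included:
per-replicate random streams are spawned from the master seed with
``numpy.random.SeedSequence``, so reruns are byte-identical and scenario
cells are independent.  Replicates whose design matrix is degenerate
(collinear markers) are excluded and counted, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chromosome import MarkovChromosome
from .gwas import CollinearityError, fit_interaction_model, wald_interaction_test
from .haplotypes import HaplotypeDistribution, make_haplotype_distribution, sample_genotypes
from .phenotypes import (
    simulate_phenotype_additive,
    simulate_phenotype_dominance,
    simulate_phenotype_multilocus,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "run_scenario",
    "bin_results",
    "distance_profile_experiment",
    "cross_chromosome_null_experiment",
    "infinitesimal_experiment",
    "three_pair_experiment",
]

SUMMARY_COLUMNS = [
    "scenario_id",
    "model",
    "n",
    "phi",
    "alpha",
    "replicates",
    "rejection_rate",
    "mc_standard_error",
    "n_degenerate",
    "mean_marker_r2",
    "mean_maf",
]


@dataclass
class Scenario:
    """One Monte Carlo scenario cell.

    Genotypes come from exactly one of ``dist`` (an exact haplotype law) or
    ``chromosome`` (the Markov LD emulator).  ``qtl_index`` and
    ``marker_indices`` name the causal locus and the tested marker pair
    within that source; multi-locus models name their QTLs via
    ``qtl_indices``.
    """

    scenario_id: str
    n: int
    model: str = "additive"
    qtl_variance_fraction: float = 0.01
    alpha: float = 0.05
    replicates: int = 1000
    master_seed: int = 0
    dist: HaplotypeDistribution | None = None
    chromosome: MarkovChromosome | None = None
    qtl_index: int = 0
    marker_indices: tuple[int, int] = (1, 2)
    # dominance model
    a: float = 1.0
    d: float = 0.0
    error_variance: float = 1.0
    # multi-locus model
    qtl_indices: tuple[int, ...] | None = None
    variance_fractions: tuple[float, ...] | None = None
    polygenic_fraction: float = 0.0
    background_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if (self.dist is None) == (self.chromosome is None):
            raise ValueError("exactly one of dist or chromosome must be given")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.model not in {"additive", "dominance", "multilocus", "multilocus+infinitesimal"}:
            raise ValueError(f"unknown model {self.model!r}")
        L = self.dist.n_loci if self.dist is not None else self.chromosome.n_loci
        referenced = {self.qtl_index, *self.marker_indices, *(self.qtl_indices or ())}
        if self.background_indices:
            referenced |= set(self.background_indices)
        if any(j < 0 or j >= L for j in referenced):
            raise ValueError("scenario references loci outside the genotype source")


@dataclass
class ScenarioResult:
    """Aggregate rejection rate plus the per-replicate audit table."""

    summary: dict
    replicates: pd.DataFrame

    @property
    def rejection_rate(self) -> float:
        return self.summary["rejection_rate"]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.summary], columns=SUMMARY_COLUMNS)


def _simulate_phenotype(s: Scenario, Gc, rng: np.random.Generator):
    z = Gc.codes[:, s.qtl_index]
    if s.model == "additive":
        return simulate_phenotype_additive(z, s.qtl_variance_fraction, rng)
    if s.model == "dominance":
        return simulate_phenotype_dominance(z, s.a, s.d, s.error_variance, rng)
    qtls = s.qtl_indices if s.qtl_indices is not None else (s.qtl_index,)
    phis = (
        s.variance_fractions
        if s.variance_fractions is not None
        else tuple(s.qtl_variance_fraction / len(qtls) for _ in qtls)
    )
    source = Gc.codes[:, list(s.background_indices)] if s.background_indices else None
    return simulate_phenotype_multilocus(
        Gc.codes[:, list(qtls)],
        phis,
        polygenic_fraction=s.polygenic_fraction,
        polygenic_source=source,
        seed=rng,
    )


def run_scenario(s: Scenario) -> ScenarioResult:
    """Run all replicates of one scenario and aggregate the rejection rate."""
    streams = np.random.SeedSequence(s.master_seed).spawn(s.replicates)
    i1, i2 = s.marker_indices
    rows = []
    n_degenerate = 0
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if s.dist is not None:
            G = sample_genotypes(s.dist, s.n, rng)
        else:
            G = s.chromosome.sample_genotypes(s.n, rng)
        p_hat = G.allele_frequencies()
        Gc = G.center()
        y = _simulate_phenotype(s, Gc, rng)
        x1, x2 = Gc.codes[:, i1], Gc.codes[:, i2]
        try:
            fit = fit_interaction_model(y, x1, x2)
        except CollinearityError:
            n_degenerate += 1
            continue
        test = wald_interaction_test(fit, s.alpha)
        v1, v2 = x1.var(), x2.var()
        r2 = float(np.cov(x1, x2)[0, 1] ** 2 / (v1 * v2)) if v1 > 0 and v2 > 0 else np.nan
        rows.append(
            {
                "scenario_id": s.scenario_id,
                "replicate": rep,
                "reject": test.reject,
                "p_value": test.p_value,
                "beta12_hat": test.estimate,
                "marker_r2": r2,
                "mean_maf": float(np.mean([min(p_hat[i1], 1 - p_hat[i1]), min(p_hat[i2], 1 - p_hat[i2])])),
            }
        )
    reps = pd.DataFrame(rows)
    m = len(rows)
    rate = float(reps["reject"].mean()) if m else np.nan
    summary = {
        "scenario_id": s.scenario_id,
        "model": s.model,
        "n": s.n,
        "phi": s.qtl_variance_fraction,
        "alpha": s.alpha,
        "replicates": m,
        "rejection_rate": rate,
        "mc_standard_error": float(np.sqrt(rate * (1 - rate) / m)) if m else np.nan,
        "n_degenerate": n_degenerate,
        "mean_marker_r2": float(reps["marker_r2"].mean()) if m else np.nan,
        "mean_maf": float(reps["mean_maf"].mean()) if m else np.nan,
    }
    return ScenarioResult(summary, reps)


def bin_results(
    replicate_table: pd.DataFrame,
    by: str = "marker_r2",
    edges: Sequence[float] = (0, 0.01, 0.1, 0.2, 0.5, 0.9, 1.0),
    maf_edges: Sequence[float] = (0, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Bin per-replicate results by marker R^2 (or MAF x R^2) and aggregate.

    Rates are weighted by replicate count within each bin; empty bins appear
    with NaN rate (missing, not zero).  ``by='maf_x_r2'`` crosses R^2 bins
    with bins of the mean marker MAF, the layout of the MAF-by-LD heatmaps.
    """
    if by not in {"marker_r2", "maf_x_r2"}:
        raise ValueError("by must be 'marker_r2' or 'maf_x_r2'")
    df = replicate_table.copy()
    df["r2_bin"] = pd.cut(df["marker_r2"], bins=list(edges), include_lowest=True)
    keys = ["r2_bin"]
    if by == "maf_x_r2":
        df["maf_bin"] = pd.cut(df["mean_maf"], bins=list(maf_edges), include_lowest=True)
        keys = ["maf_bin", "r2_bin"]
    grouped = df.groupby(keys, observed=False)["reject"]
    out = grouped.agg(rejection_rate="mean", replicates="count").reset_index()
    out["rejection_rate"] = out["rejection_rate"].astype(float)
    out.loc[out["replicates"] == 0, "rejection_rate"] = np.nan
    out["mc_standard_error"] = np.sqrt(
        out["rejection_rate"] * (1 - out["rejection_rate"]) / out["replicates"].clip(lower=1)
    )
    out.loc[out["replicates"] == 0, "mc_standard_error"] = np.nan
    return out


# ---------------------------------------------------------------------------
# named experiment drivers
# ---------------------------------------------------------------------------


def _spawn_seeds(master_seed: int, k: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master_seed).spawn(k)]


def distance_profile_experiment(
    lags_bp: Sequence[float],
    n_grid: Sequence[int],
    phi_grid: Sequence[float],
    maf: float = 0.3,
    decay_lambda: float = 3.0e5,
    proximal_gap_bp: float = 1.0e3,
    alpha: float = 0.05,
    replicates: int = 500,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Rejection rate vs distance between the QTL and the distal marker.

    The proximal marker x1 sits ``proximal_gap_bp`` to the left of the QTL;
    the distal marker x2 is placed at each lag to the right.  Genotypes are
    drawn from the exact three-locus marginal of the Markov chromosome, so
    each row also reports the expected R^2 between the markers.
    """
    cells = [(lag, n, phi) for lag in lags_bp for n in n_grid for phi in phi_grid]
    seeds = _spawn_seeds(master_seed, len(cells))
    rows = []
    for (lag, n, phi), seed in zip(cells, seeds):
        chrom = MarkovChromosome(
            positions=np.array([0.0, proximal_gap_bp, proximal_gap_bp + lag]),
            maf=np.full(3, maf),
            decay_lambda=decay_lambda,
        )
        dist = chrom.marginal_distribution([0, 1, 2])
        s = Scenario(
            scenario_id=f"distance_lag{lag:g}_n{n}_phi{phi:g}",
            n=n,
            qtl_variance_fraction=phi,
            alpha=alpha,
            replicates=replicates,
            master_seed=seed,
            dist=dist,
            qtl_index=1,
            marker_indices=(0, 2),
        )
        row = run_scenario(s).summary
        row.update(lag_bp=lag, expected_marker_r2=chrom.expected_r2(0, 2))
        rows.append(row)
    return pd.DataFrame(rows)


def cross_chromosome_null_experiment(
    n_grid: Sequence[int] = (10_000, 250_000),
    phi: float = 0.01,
    qtl_marker_D: float = 0.08,
    allele_freqs: tuple[float, float, float] = (0.5, 0.5, 0.4),
    alpha: float = 0.05,
    replicates: int = 2000,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Null analogue of markers on different chromosomes.

    The QTL-proximal pair (z, x1) is kept in LD while the distal marker x2 is
    simulated independently of both, so beta12 = 0 in the population and the
    rejection rate should sit at alpha.
    """
    dist = make_haplotype_distribution(
        allele_freqs, pairwise_D={(0, 1): qtl_marker_D}, locus_labels=("z", "x1", "x2")
    )
    seeds = _spawn_seeds(master_seed, len(list(n_grid)))
    rows = []
    for n, seed in zip(n_grid, seeds):
        s = Scenario(
            scenario_id=f"cross_chrom_n{n}",
            n=n,
            qtl_variance_fraction=phi,
            alpha=alpha,
            replicates=replicates,
            master_seed=seed,
            dist=dist,
        )
        rows.append(run_scenario(s).summary)
    return pd.DataFrame(rows)


def infinitesimal_experiment(
    lags_bp: Sequence[float],
    n: int = 50_000,
    main_qtl_fraction: float = 0.01,
    polygenic_fraction: float = 0.49,
    n_background: int = 50,
    background_offset_bp: float = 5.0e6,
    background_spacing_bp: float = 1.0e5,
    maf: float = 0.3,
    decay_lambda: float = 3.0e5,
    alpha: float = 0.05,
    replicates: int = 300,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Major QTL plus a strictly additive infinitesimal component.

    Trait heritability defaults to 0.5: the main QTL explains 1% of the
    phenotypic variance and the infinitesimal term — equal standardized
    effects over ``n_background`` loci placed well away from the tested
    triad — the remaining 49%.
    """
    rows = []
    seeds = _spawn_seeds(master_seed, len(list(lags_bp)))
    for lag, seed in zip(lags_bp, seeds):
        triad_pos = [0.0, 1.0e3, 1.0e3 + lag]
        bg_pos = [
            background_offset_bp + k * background_spacing_bp for k in range(n_background)
        ]
        chrom = MarkovChromosome(
            positions=np.array(triad_pos + bg_pos),
            maf=np.full(3 + n_background, maf),
            decay_lambda=decay_lambda,
        )
        s = Scenario(
            scenario_id=f"infinitesimal_lag{lag:g}_n{n}",
            n=n,
            model="multilocus+infinitesimal",
            qtl_variance_fraction=main_qtl_fraction,
            alpha=alpha,
            replicates=replicates,
            master_seed=seed,
            chromosome=chrom,
            qtl_index=1,
            marker_indices=(0, 2),
            qtl_indices=(1,),
            variance_fractions=(main_qtl_fraction,),
            polygenic_fraction=polygenic_fraction,
            background_indices=tuple(range(3, 3 + n_background)),
        )
        row = run_scenario(s).summary
        row.update(lag_bp=lag, expected_marker_r2=chrom.expected_r2(0, 2))
        rows.append(row)
    return pd.DataFrame(rows)


def three_pair_experiment(
    pair13_distances_bp: Sequence[float],
    n: int = 50_000,
    total_genetic_fraction: float = 0.01,
    intra_pair_gap_bp: float = 5.0e4,
    maf: float = 0.3,
    decay_lambda: float = 3.0e5,
    alpha: float = 0.05,
    replicates: int = 300,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Three marker-QTL pairs; the x1-x3 interaction is tested.

    Pairs 1 and 3 are moved apart with pair 2 held at the midpoint; within a
    pair the marker is immediately adjacent to its QTL.  The trait is
    strictly additive with the three QTLs jointly explaining
    ``total_genetic_fraction`` of the phenotypic variance (one third each).
    The analytic interaction coefficient of the combined model, driven by
    the unaccounted middle QTL, is reported next to the empirical rate.
    """
    from .model import interaction_coefficient_multilocus
    from .moments import exact_moments

    rows = []
    seeds = _spawn_seeds(master_seed, len(list(pair13_distances_bp)))
    for dist13, seed in zip(pair13_distances_bp, seeds):
        mid = dist13 / 2.0
        # locus order: x1, z1, x2, z2, x3, z3 (marker adjacent, QTL to its right)
        positions = np.array(
            [
                0.0,
                intra_pair_gap_bp,
                mid,
                mid + intra_pair_gap_bp,
                dist13,
                dist13 + intra_pair_gap_bp,
            ]
        )
        chrom = MarkovChromosome(positions, np.full(6, maf), decay_lambda)
        dist = chrom.marginal_distribution(range(6))
        markers = (0, 4)  # x1, x3
        qtls = (1, 3, 5)
        phis = tuple(total_genetic_fraction / 3 for _ in qtls)
        s = Scenario(
            scenario_id=f"three_pair_d{dist13:g}_n{n}",
            n=n,
            model="multilocus",
            qtl_variance_fraction=total_genetic_fraction,
            alpha=alpha,
            replicates=replicates,
            master_seed=seed,
            dist=dist,
            qtl_index=qtls[0],
            marker_indices=markers,
            qtl_indices=qtls,
            variance_fractions=phis,
        )
        # analytic beta12 of the combined model on the exact distribution
        msets = [exact_moments(dist, q, markers) for q in qtls]
        var_z = np.array([m.var_z for m in msets])
        effects = np.sqrt(np.asarray(phis) / var_z)
        beta12 = interaction_coefficient_multilocus(msets, effects)
        row = run_scenario(s).summary
        row.update(
            pair13_distance_bp=dist13,
            analytic_beta12=beta12,
            expected_marker_r2=chrom.expected_r2(*markers),
        )
        rows.append(row)
    return pd.DataFrame(rows)
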