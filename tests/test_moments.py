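"""Genotypic moments: exact enumeration, empirical estimates, LD summaries."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from phantomld import (
    GenotypeMatrix,
    InfeasibleLDError,
    empirical_moments,
    exact_moments,
    ld_summary,
    make_haplotype_distribution,
    sample_genotypes,
)
from phantomld.moments import PhaseUnknownError, UncenteredError, haploid_ld_from_genotypes


class TestExactMoments:
    def test_le_triple_has_zero_rhs_and_diagonal_T(self, le_dist):
        m = exact_moments(le_dist)
        np.testing.assert_allclose(m.rhs_additive, 0.0, atol=1e-12)
        np.testing.assert_allclose(m.T, np.diag(np.diag(m.T)), atol=1e-12)

    def test_independent_x2_gives_diagonal_T_and_zero_interaction_moment(self, x2_indep_dist):
        m = exact_moments(x2_indep_dist)
        np.testing.assert_allclose(m.T, np.diag(np.diag(m.T)), atol=1e-12)
        assert m.rhs_additive[2] == pytest.approx(0.0, abs=1e-12)
        assert m.rhs_additive[0] != 0.0

    def test_marker_variances_are_twice_binomial_variance(self, generic_dist):
        # Var(genotype) = 2 p (1-p) under random mating
        m = exact_moments(generic_dist)
        p = generic_dist.allele_frequencies()
        assert m.T[0, 0] == pytest.approx(2 * p[1] * (1 - p[1]), abs=1e-12)
        assert m.T[1, 1] == pytest.approx(2 * p[2] * (1 - p[2]), abs=1e-12)

    def test_duplicate_locus_indices_rejected(self, generic_dist):
        with pytest.raises(ValueError):
            exact_moments(generic_dist, 0, (0, 2))

    def test_monte_carlo_agreement_at_large_n(self, generic_dist):
        n = 1_000_000
        G = sample_genotypes(generic_dist, n, seed=13).center()
        emp = empirical_moments(G, 0, (1, 2))
        exact = exact_moments(generic_dist)
        # every additive-path moment converges at the 1/sqrt(n) rate; bound by
        # 5 SEs with a conservative per-moment variance proxy of 16
        tol = 5 * np.sqrt(16 / n)
        np.testing.assert_allclose(emp.T, exact.T, atol=tol)
        np.testing.assert_allclose(emp.rhs_additive, exact.rhs_additive, atol=tol)
        np.testing.assert_allclose(emp.rhs_dominance, exact.rhs_dominance, atol=tol)

    def test_convergence_rate_shrinks_with_n(self, generic_dist):
        exact = exact_moments(generic_dist).rhs_additive
        errs = []
        for n in (10_000, 1_000_000):
            G = sample_genotypes(generic_dist, n, seed=17).center()
            errs.append(np.abs(empirical_moments(G, 0, (1, 2)).rhs_additive - exact).max())
        assert errs[1] < errs[0]


class TestEmpiricalMoments:
    def test_uncentered_input_refused(self, generic_dist):
        G = sample_genotypes(generic_dist, 100, seed=1)
        with pytest.raises(UncenteredError):
            empirical_moments(G, 0, (1, 2))

    def test_constant_column_rejected(self):
        codes = np.column_stack(
            [np.ones(50, dtype=np.int8), np.tile([0, 1], 25), np.tile([0, 2], 25)]
        )
        G = GenotypeMatrix(codes).center()
        with pytest.raises(ValueError, match="monomorphic"):
            empirical_moments(G, 0, (1, 2))

    def test_duplicated_marker_yields_singular_T(self, generic_dist):
        from phantomld import solve_population_coefficients

        G = sample_genotypes(generic_dist, 5000, seed=2)
        codes = np.column_stack([G.codes[:, 0], G.codes[:, 1], G.codes[:, 1]])
        dup = GenotypeMatrix(codes).center()
        m = empirical_moments(dup, 0, (1, 2))
        sol = solve_population_coefficients(m)
        assert sol.degenerate


class TestFactorTwoLaw:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        p=st.tuples(*[st.floats(0.15, 0.85)] * 3),
        d=st.tuples(*[st.floats(-0.03, 0.03)] * 3),
        d3=st.floats(-0.01, 0.01),
    )
    def test_genotypic_moments_double_haploid_moments(self, p, d, d3):
        """Random mating: genotypic second and third central moments equal
        exactly twice the haploid D coefficients, via 64-diplotype enumeration."""
        try:
            dist = make_haplotype_distribution(
                p, {(0, 1): d[0], (0, 2): d[1], (1, 2): d[2]}, d3
            )
        except (InfeasibleLDError, ValueError):
            assume(False)
        m = exact_moments(dist)
        assert m.rhs_additive[0] == pytest.approx(2 * dist.pairwise_D(0, 1), abs=1e-12)
        assert m.rhs_additive[1] == pytest.approx(2 * dist.pairwise_D(0, 2), abs=1e-12)
        assert m.T[0, 1] == pytest.approx(2 * dist.pairwise_D(1, 2), abs=1e-12)
        assert m.rhs_additive[2] == pytest.approx(2 * dist.three_locus_D(0, 1, 2), abs=1e-12)


class TestLDSummary:
    def test_perfect_pair_r2_is_one(self):
        dist = make_haplotype_distribution((0.5, 0.5), 0.25)
        s = ld_summary(dist, [0, 1])
        assert s.r_squared[(0, 1)] == pytest.approx(1.0)

    def test_genotypic_covariance_is_twice_haploid_D(self, generic_dist):
        s = ld_summary(generic_dist, [0, 1, 2])
        for pair, cov in s.genotypic_covariances.items():
            assert cov == pytest.approx(2 * s.haploid_D[pair], abs=1e-12)

    def test_genotypic_r2_equals_squared_haploid_correlation(self):
        # MAF 0.5 pair with haploid correlation rho = 4 D
        dist = make_haplotype_distribution((0.5, 0.5), 0.1)
        rho = dist.haploid_correlation(0, 1)
        s = ld_summary(dist, [0, 1])
        assert s.r_squared[(0, 1)] == pytest.approx(rho**2, abs=1e-12)

    def test_qtl_r2_joint_is_one_iff_perfect_ld(self, perfect_ld_dist, generic_dist):
        assert ld_summary(perfect_ld_dist, [0, 1, 2]).qtl_r2_joint == pytest.approx(1.0)
        assert ld_summary(generic_dist, [0, 1, 2]).qtl_r2_joint < 0.999

    def test_empirical_summary_has_no_haploid_quantities(self, generic_dist):
        G = sample_genotypes(generic_dist, 2000, seed=3)
        s = ld_summary(G, [0, 1, 2])
        assert s.haploid_D is None and s.three_locus_D is None
        assert 0 <= s.qtl_r2_joint <= 1
        with pytest.raises(PhaseUnknownError):
            haploid_ld_from_genotypes(G)

    def test_json_serialization(self, generic_dist):
        import json

        payload = json.loads(ld_summary(generic_dist, [0, 1, 2]).to_json())
        assert payload["source"] == "exact"
        assert "0,1" in payload["r_squared"]
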