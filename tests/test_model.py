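"""Population coefficient solver and the necessary conditions for phantom epistasis."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from phantomld import (
    InfeasibleLDError,
    check_necessary_conditions,
    exact_moments,
    interaction_coefficient_multilocus,
    make_haplotype_distribution,
    solve_population_coefficients,
    solve_population_coefficients_dominance,
)

# regression pin: exact solver output for the generic mutually-LD triple
# (freqs .5/.4/.3, D = .05/.04/.03, D123 = .01) at unit QTL effect,
# independently corroborated by large-n OLS in test_consistency below
GENERIC_BETAS = (0.18665246716364925, 0.1599574014909479, 0.06744763933262331)


class TestAdditiveSolver:
    def test_linkage_equilibrium_gives_all_zero_coefficients(self, le_dist):
        sol = solve_population_coefficients(exact_moments(le_dist), b=1.0)
        np.testing.assert_allclose(sol.betas, 0.0, atol=1e-12)
        assert not sol.degenerate

    def test_perfect_d_zeroes_interaction(self, perfect_ld_dist):
        sol = solve_population_coefficients(exact_moments(perfect_ld_dist), b=1.0)
        assert sol.beta12 == pytest.approx(0.0, abs=1e-10)
        # z == x1 exactly, so the main effect loads entirely on x1
        assert sol.beta1 == pytest.approx(1.0, abs=1e-10)

    def test_independent_marker_zeroes_interaction(self, x2_indep_dist):
        m = exact_moments(x2_indep_dist)
        sol = solve_population_coefficients(m, b=1.0)
        assert sol.beta12 == pytest.approx(0.0, abs=1e-10)
        assert sol.beta2 == pytest.approx(0.0, abs=1e-10)
        assert sol.beta1 == pytest.approx(m.rhs_additive[0] / m.T[0, 0], abs=1e-12)
        assert sol.beta1 != 0.0

    def test_generic_triple_pinned_regression(self, generic_dist):
        sol = solve_population_coefficients(exact_moments(generic_dist), b=1.0)
        np.testing.assert_allclose(sol.betas, GENERIC_BETAS, atol=1e-12)
        assert sol.t_row3 is not None and not sol.degenerate

    def test_scale_equivariance_in_qtl_effect(self, generic_dist):
        m = exact_moments(generic_dist)
        one = solve_population_coefficients(m, b=1.0)
        two = solve_population_coefficients(m, b=2.0)
        np.testing.assert_allclose(two.betas, 2 * one.betas, atol=1e-12)

    def test_singular_without_perfect_ld_withholds_betas(self, generic_dist):
        # duplicated marker: singular T, QTL not linear in the markers
        m = exact_moments(generic_dist)
        T = m.T.copy()
        T[1] = T[0]
        T[:, 1] = T[:, 0]
        m.T = T
        sol = solve_population_coefficients(m, b=1.0)
        assert sol.degenerate and np.isnan(sol.beta12)


class TestDominanceSolver:
    def test_zero_dominance_matches_additive_solver(self, generic_dist):
        m = exact_moments(generic_dist)
        add = solve_population_coefficients(m, b=0.7)
        dom = solve_population_coefficients_dominance(m, a=0.7, d=0.0)
        np.testing.assert_allclose(dom.betas, add.betas, atol=1e-12)

    @pytest.mark.parametrize("a,d", [(1, 0), (0, 1), (1, 1), (0.3, -0.7)])
    def test_independent_marker_zeroes_interaction_for_all_effects(self, x2_indep_dist, a, d):
        m = exact_moments(x2_indep_dist)
        sol = solve_population_coefficients_dominance(m, a, d)
        assert sol.beta12 == pytest.approx(0.0, abs=1e-10)

    def test_wei_construction_generates_dominance_phantom(self, wei_dist):
        # markers pairwise independent yet jointly in LD with the QTL:
        # pure dominance (a=0) still produces a nonzero interaction coefficient
        m = exact_moments(wei_dist)
        assert abs(m.T[0, 1]) < 1e-12  # markers in LE
        sol = solve_population_coefficients_dominance(m, a=0.0, d=1.0)
        assert sol.beta12 == pytest.approx(0.16, abs=1e-12)

    def test_missing_dominance_rhs_rejected(self, generic_dist):
        m = exact_moments(generic_dist)
        m.rhs_dominance = None
        with pytest.raises(ValueError):
            solve_population_coefficients_dominance(m, 1.0, 1.0)


class TestMultilocus:
    def test_all_qtls_in_le_give_zero(self, le_dist):
        m = exact_moments(le_dist)
        assert interaction_coefficient_multilocus([m, m], [0.5, 0.5]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_qtl_reduces_to_plain_solver(self, generic_dist):
        m = exact_moments(generic_dist)
        single = solve_population_coefficients(m, b=0.3).beta12
        assert interaction_coefficient_multilocus([m], [0.3]) == pytest.approx(single, abs=1e-14)

    def test_linearity_in_each_effect(self, generic_dist, x2_indep_dist):
        # both moment sets must share the marker pair; build a second QTL by
        # reusing the generic distribution with the roles of z left intact
        m = exact_moments(generic_dist)
        b_base = interaction_coefficient_multilocus([m, m], [1.0, 0.0])
        b_scaled = interaction_coefficient_multilocus([m, m], [2.0, 0.0])
        b_sum = interaction_coefficient_multilocus([m, m], [1.0, 1.0])
        assert b_scaled == pytest.approx(2 * b_base, abs=1e-14)
        assert b_sum == pytest.approx(2 * b_base, abs=1e-14)

    def test_mismatched_marker_pairs_rejected(self, generic_dist, wei_dist):
        with pytest.raises(ValueError, match="marker pair"):
            interaction_coefficient_multilocus(
                [exact_moments(generic_dist), exact_moments(wei_dist)], [1.0, 1.0]
            )

    def test_three_pair_block_geometry_nonzero_beta12(self):
        # six loci in three blocks; the middle, unaccounted QTL is in LD with
        # the two tested flanking markers and drives the interaction
        from phantomld import MarkovChromosome

        chrom = MarkovChromosome(
            np.array([0.0, 5e4, 2e5, 2.5e5, 4e5, 4.5e5]), np.full(6, 0.3), 3e5
        )
        dist = chrom.marginal_distribution(range(6))
        markers = (0, 4)
        msets = [exact_moments(dist, q, markers) for q in (1, 3, 5)]
        effects = np.sqrt((0.01 / 3) / np.array([m.var_z for m in msets]))
        combined = interaction_coefficient_multilocus(msets, effects)
        assert combined != pytest.approx(0.0, abs=1e-6)
        # dominated by the middle QTL's contribution b2 * E(x1 x3 z2)
        middle_only = interaction_coefficient_multilocus(msets, [0, effects[1], 0])
        assert abs(middle_only) > 0.5 * abs(combined)


class TestNecessaryConditions:
    def test_le_triple_fails_first_condition(self, le_dist):
        rep = check_necessary_conditions(le_dist)
        assert not any(rep.qtl_marker_LD.values())
        assert not rep.phantom_possible

    def test_perfect_ld_fails_second_condition(self, perfect_ld_dist):
        rep = check_necessary_conditions(perfect_ld_dist)
        assert rep.perfect_LD and not rep.phantom_possible

    def test_factorizable_triple_fails_third_condition(self, x2_indep_dist):
        rep = check_necessary_conditions(x2_indep_dist)
        assert not rep.mutual_three_locus_LD and not rep.phantom_possible

    def test_mutual_imperfect_ld_enables_phantom(self, generic_dist):
        rep = check_necessary_conditions(generic_dist)
        assert rep.phantom_possible
        sol = solve_population_coefficients(exact_moments(generic_dist))
        assert sol.beta12 != 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.tuples(*[st.floats(0.15, 0.85)] * 3),
        d=st.tuples(*[st.floats(-0.03, 0.03)] * 3),
        d3=st.floats(-0.01, 0.01),
    )
    def test_nonzero_beta12_implies_conditions_met(self, p, d, d3):
        """Necessity sweep: beta12 != 0 can only occur when all three
        conditions hold (contrapositive of the analytic argument)."""
        try:
            dist = make_haplotype_distribution(
                p, {(0, 1): d[0], (0, 2): d[1], (1, 2): d[2]}, d3
            )
        except (InfeasibleLDError, ValueError):
            assume(False)
        sol = solve_population_coefficients(exact_moments(dist))
        if not sol.degenerate and abs(sol.beta12) > 1e-8:
            assert check_necessary_conditions(dist, tol=1e-10).phantom_possible


class TestConsistencyWithOLS:
    def test_exact_solution_matches_large_n_ols(self, generic_dist):
        """Independent route: empirical OLS on a million simulated diploids
        reproduces the exact-solver coefficients within sampling error."""
        from phantomld import (
            fit_interaction_model,
            sample_genotypes,
            simulate_phenotype_additive,
        )

        n = 1_000_000
        m = exact_moments(generic_dist)
        phi = 0.01
        b = np.sqrt(phi / m.var_z)
        expected = solve_population_coefficients(m, b=b)

        rng = np.random.default_rng(20)
        G = sample_genotypes(generic_dist, n, rng).center()
        y = simulate_phenotype_additive(G.codes[:, 0], phi, rng, var_z=m.var_z)
        fit = fit_interaction_model(y, G.codes[:, 1], G.codes[:, 2])
        for term, target in zip(("x1", "x2", "x1:x2"), expected.betas):
            assert abs(fit[term] - target) < 5 * fit.se(term)
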