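"""Deterministic tier: transition operators, clinical likelihood, equilibrium."""

import math

import numpy as np
import pytest
from scipy.stats import binom, hypergeom, nchypergeom_fisher, nchypergeom_wallenius

import mitogerm as mg
from mitogerm.germline import (
    _hypergeom_transition,
    _replication_transition,
)


def _random_dist(M, rng):
    p = rng.dirichlet(np.ones(M + 1))
    return mg.LoadDistribution(p, M)


class TestSegregationOperator:
    def test_point_masses(self):
        out = mg.segregation_operator(mg.LoadDistribution.point(0, 8))
        assert out.M == 4 and out.probs[0] == pytest.approx(1.0)
        out = mg.segregation_operator(mg.LoadDistribution.point(2, 4))
        assert np.allclose(out.probs, [1 / 6, 4 / 6, 1 / 6])

    def test_mean_count_halves_exactly(self, rng):
        d = _random_dist(64, rng)
        out = mg.segregation_operator(d)
        assert out.mean_count == pytest.approx(d.mean_count / 2, abs=1e-10)
        assert out.mean_load == pytest.approx(d.mean_load, abs=1e-10)

    def test_odd_m_rejected(self):
        with pytest.raises(ValueError):
            mg.segregation_operator(mg.LoadDistribution.point(1, 5))

    def test_cleavage_chain_collapses_to_single_subsample(self, rng):
        # repeated halving == one uniform subsample of the final size
        d = _random_dist(64, rng)
        step = d
        for _ in range(3):
            step = mg.segregation_operator(step)
        direct = mg.germline._apply(_hypergeom_transition(64, 8), d, 8)
        assert np.allclose(step.probs, direct.probs, atol=1e-12)


class TestMaturationOperator:
    def test_doubling_without_mutation(self):
        out = mg.maturation_operator(mg.LoadDistribution.point(3, 8), 0.0)
        assert out.M == 16
        assert out.probs[6] == pytest.approx(1.0)

    def test_binomial_new_mutations(self):
        # from a clean cell with M=2: new mutants ~ Binomial(2, 1/2)
        out = mg.maturation_operator(mg.LoadDistribution.point(0, 2), 0.5)
        assert np.allclose(out.probs[:3], [0.25, 0.5, 0.25])
        assert np.allclose(out.probs[3:], 0.0)

    def test_restores_zygote_ploidy_schedule(self):
        d = mg.LoadDistribution.point(0, 128)
        for _ in range(12):
            d = mg.maturation_operator(d, 0.0)
        assert d.M == 2**19


class TestProliferationOperator:
    def test_clean_state_fixed_without_mutation(self):
        out = mg.proliferation_operator(mg.LoadDistribution.point(0, 8), 0.0)
        assert out.M == 8 and out.probs[0] == pytest.approx(1.0)

    def test_kernel_columns_are_stochastic(self):
        for T in (_hypergeom_transition(32, 16), _replication_transition(32, 0.1)):
            colsums = np.asarray(T.sum(axis=0)).ravel()
            assert np.allclose(colsums, 1.0, atol=1e-10)

    def test_mean_load_increase_first_order_in_U(self):
        U = 1e-4
        d = mg.LoadDistribution.point(10, 100)
        out = mg.proliferation_operator(d, U)
        expected = d.mean_load + U * (1 - d.mean_load) / 2
        assert out.mean_load == pytest.approx(expected, abs=1e-8)

    def test_matches_monte_carlo_replicate_segregate(self, rng):
        M, m, U, reps = 4, 1, 0.1, 400_000
        out = mg.proliferation_operator(mg.LoadDistribution.point(m, M), U)
        wt2, mut2 = mg.replicate_and_mutate_counts(
            np.full(reps, M - m), np.full(reps, m), U, rng
        )
        daughters = rng.hypergeometric(mut2, wt2, M)
        emp = np.bincount(daughters, minlength=M + 1) / reps
        se = np.sqrt(out.probs * (1 - out.probs) / reps)
        assert np.all(np.abs(emp - out.probs) < 3 * se + 1e-9)


class TestSelectionUpdate:
    def test_uniform_weights_identity(self, rng):
        d = _random_dist(16, rng)
        out = mg.selection_update(d, np.ones(17))
        assert np.allclose(out.probs, d.probs)

    def test_lethal_class_removed(self):
        M = 8
        p = np.zeros(M + 1)
        p[0] = p[M] = 0.5
        w = np.ones(M + 1)
        w[M] = 0.0
        out = mg.selection_update(mg.LoadDistribution(p, M), w)
        assert out.probs[0] == pytest.approx(1.0)

    def test_hand_normalized_linear_selection(self):
        d = mg.LoadDistribution(np.full(5, 0.2), 4)
        w = 1 - np.arange(5) / 4.0
        out = mg.selection_update(d, w)
        assert np.allclose(out.probs, np.array([1, 0.75, 0.5, 0.25, 0.0]) / 2.5)

    def test_zero_total_weight_rejected(self):
        d = mg.LoadDistribution.point(4, 4)
        with pytest.raises(ValueError):
            mg.selection_update(d, np.array([1, 1, 1, 1, 0.0]))

    def test_nonincreasing_weights_never_increase_mean_load(self, rng):
        for _ in range(20):
            d = _random_dist(24, rng)
            w = np.sort(rng.random(25))[::-1]
            out = mg.selection_update(d, w)
            assert out.mean_load <= d.mean_load + 1e-12


class TestTransferKernel:
    @pytest.mark.parametrize("M,pwt,pmut", [(8, 0.75, 0.25), (12, 0.67, 0.33), (6, 0.5, 0.5)])
    def test_fisher_matches_reference(self, M, pwt, pmut):
        C = mg.transfer_contribution_kernel(M, pwt, pmut, f=0.5)
        odds = pmut / pwt
        for m in range(M + 1):
            ref = nchypergeom_fisher.pmf(np.arange(M // 2 + 1), M, m, M // 2, odds)
            assert np.allclose(C[:, m], ref, atol=1e-10)

    def test_neutral_weights_reduce_to_hypergeometric(self):
        C = mg.transfer_contribution_kernel(8, 0.4, 0.4, f=0.5)
        for m in range(9):
            assert np.allclose(C[:, m], hypergeom.pmf(np.arange(5), 8, m, 4), atol=1e-12)

    def test_wallenius_mode_matches_reference(self):
        C = mg.transfer_contribution_kernel(8, 0.75, 0.25, f=0.5, mode="wallenius")
        for m in range(9):
            ref = nchypergeom_wallenius.pmf(np.arange(5), 8, m, 4, 1 / 3)
            assert np.allclose(C[:, m], ref, atol=1e-10)

    def test_operator_copy_number_and_clean_point(self):
        d = mg.LoadDistribution.point(0, 8)
        out = mg.transfer_operator(d, 0.5, 0.5, U=0.0, cyst_size=8, f=0.5)
        # cyst content 8 * 8 = 64 copies; half are pooled -> 32 = cyst_size * f * M
        assert out.M == 32
        assert out.probs[0] == pytest.approx(1.0)

    def test_empty_support_detected(self):
        d = mg.LoadDistribution.point(8, 8)  # fully mutant cell
        with pytest.raises(ValueError):
            mg.transfer_operator(d, 0.75, 0.0, U=0.0, cyst_size=2, f=0.5)


class TestClinicalFractions:
    def test_point_mass_at_zero(self):
        assert mg.clinical_fractions(mg.LoadDistribution.point(0, 100)) == (0.0, 0.0)

    def test_interval_masses_on_uniform_grid(self):
        M = 1000
        d = mg.LoadDistribution(np.full(M + 1, 1 / (M + 1)), M)
        a1, a2 = mg.clinical_fractions(d)
        assert a1 == pytest.approx(580 / 1001)  # loads 0.020 .. 0.599
        assert a2 == pytest.approx(401 / 1001)  # loads 0.600 .. 1.000

    def test_three_fractions_sum_to_one(self):
        M = 50
        rng = np.random.default_rng(3)
        d = mg.LoadDistribution(rng.dirichlet(np.ones(M + 1)), M)
        a1, a2 = mg.clinical_fractions(d)
        free = d.probs[d.loads < 0.02].sum()
        assert free + a1 + a2 == pytest.approx(1.0)

    def test_observed_prevalences_leave_expected_mutation_free_fraction(self):
        assert 1 - 1 / 200 - 1 / 5000 == pytest.approx(0.9948)


class TestLogLikelihood:
    def test_matches_independent_binomial_pmf(self):
        clin = mg.ClinicalModel(X1=50, N1=10_000, X2=2, N2=10_000)
        a1, a2 = 1 / 200, 1 / 5000
        ours = mg.log_likelihood(a1, a2, clin)
        ref = binom.logpmf(50, 10_000, a1) + binom.logpmf(2, 10_000, a2)
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_maximal_at_observed_frequencies(self):
        clin = mg.ClinicalModel()
        a1_hat, a2_hat = clin.X1 / clin.N1, clin.X2 / clin.N2
        best = mg.log_likelihood(a1_hat, a2_hat, clin)
        for da in (-0.3, -0.1, 0.1, 0.3):
            assert mg.log_likelihood(a1_hat * (1 + da), a2_hat, clin) < best
            assert mg.log_likelihood(a1_hat, a2_hat * (1 + da), clin) < best

    def test_alpha_terms_scale_with_sample_size(self):
        a1, a2 = 0.004, 0.0003
        c1 = mg.ClinicalModel(X1=40, N1=8000, X2=3, N2=6000)
        c2 = mg.ClinicalModel(X1=80, N1=16000, X2=6, N2=12000)
        lc1 = mg.log_likelihood(a1, a2, c1) - mg.log_likelihood(c1.X1 / c1.N1, c1.X2 / c1.N2, c1)

        # the alpha-dependent part of the log-likelihood is linear in (N, X)
        def alpha_part(c):
            from scipy.special import gammaln

            coef = sum(
                gammaln(N + 1) - gammaln(X + 1) - gammaln(N - X + 1)
                for X, N in ((c.X1, c.N1), (c.X2, c.N2))
            )
            return mg.log_likelihood(a1, a2, c) - coef

        assert alpha_part(c2) == pytest.approx(2 * alpha_part(c1), rel=1e-12)

    def test_degenerate_alphas(self):
        clin = mg.ClinicalModel(X1=1, N1=100, X2=0, N2=100)
        assert mg.log_likelihood(0.0, 0.5, clin) == -math.inf  # X1 > 0 but alpha1 = 0
        assert np.isfinite(mg.log_likelihood(0.01, 0.0, clin))  # X2 = 0 is consistent


class TestBandedAgainstExactKernels:
    """The banded truncation must agree with the exact small-M path to 1e-8."""

    def test_hypergeometric_kernel(self):
        exact = _hypergeom_transition(400, 100, exact=True).toarray()
        banded = _hypergeom_transition(400, 100, exact=False).toarray()
        assert np.abs(exact - banded).max() < 1e-8

    def test_replication_kernel(self):
        U = 1.6569e-4
        exact = _replication_transition(400, U, exact=True).toarray()
        banded = _replication_transition(400, U, exact=False).toarray()
        assert np.abs(exact - banded).max() < 1e-8


class TestGenerationOperator:
    def _tiny(self, regime="individual", **kw):
        params = mg.GermlineParams(M0=64, mu=1e-6, n_cleavage=3, n_prolif=4, n_pgc=2)
        spec = mg.SelectionSpec(regime=regime, **kw)
        return params, spec

    def test_step_matches_public_operator_composition(self):
        params, spec = self._tiny()
        op = mg.GenerationOperator(params, spec)
        rng = np.random.default_rng(0)
        p0 = rng.dirichlet(np.ones(params.M0 + 1))
        # manual pipeline from the public operators
        d = mg.LoadDistribution(p0.copy(), params.M0)
        for _ in range(params.n_cleavage):
            d = mg.segregation_operator(d)
        for _ in range(params.n_prolif):
            d = mg.proliferation_operator(d, params.U)
        for _ in range(params.n_cleavage):
            d = mg.maturation_operator(d, params.U)
        d = mg.selection_update(d, mg.individual_fitness(np.arange(params.M0 + 1), params.M0, 5))
        assert np.allclose(op.step(p0), d.probs, atol=1e-9)

    def test_transfer_step_matches_transfer_operator(self):
        params, spec = self._tiny(regime="transfer", p_wt=0.75, p_mut=0.25)
        op = mg.GenerationOperator(params, spec)
        rng = np.random.default_rng(1)
        p0 = rng.dirichlet(np.ones(params.M0 + 1))
        d = mg.LoadDistribution(p0.copy(), params.M0)
        for _ in range(params.n_cleavage):
            d = mg.segregation_operator(d)
        for _ in range(params.n_prolif - 3):
            d = mg.proliferation_operator(d, params.U)
        d = mg.transfer_operator(d, 0.75, 0.25, U=params.U)
        while d.M < params.M0:
            d = mg.maturation_operator(d, params.U)
        assert np.allclose(op.step(p0), d.probs, atol=1e-9)

    def test_neutral_operators_conserve_mean_load(self):
        params = mg.GermlineParams(M0=256, mu=0.0, n_cleavage=4, n_prolif=4, n_pgc=2)
        op = mg.GenerationOperator(params, mg.SelectionSpec(regime="none"))
        rng = np.random.default_rng(2)
        p0 = rng.dirichlet(np.ones(params.M0 + 1))
        before = p0 @ np.arange(params.M0 + 1)
        after = op.step(p0) @ np.arange(params.M0 + 1)
        assert after == pytest.approx(before, abs=1e-8)
        assert op.step(p0).sum() == pytest.approx(1.0, abs=1e-10)


class TestEquilibrium:
    def test_mutation_free_absorbing_state_is_fixed_point(self):
        params = mg.GermlineParams(M0=128, mu=0.0, n_cleavage=4, n_prolif=4, n_pgc=2)
        res = mg.iterate_to_equilibrium(params, mg.SelectionSpec(regime="none"), max_gen=10)
        assert res.generations == 1
        assert res.dist.probs[0] == pytest.approx(1.0)

    def test_stationarity_one_more_generation(self):
        params = mg.GermlineParams(M0=8 << 6, mu=1e-8, n_cleavage=6, n_prolif=8)
        res = mg.iterate_to_equilibrium(params, mg.SelectionSpec(regime="individual"))
        op = mg.GenerationOperator(params, mg.SelectionSpec(regime="individual"))
        again = op.step(res.dist.probs)
        assert mg.germline._kl_divergence(again, res.dist.probs) < 1e-9

    def test_nonconvergence_raises(self):
        params = mg.GermlineParams(M0=16 << 4, mu=1e-7, n_cleavage=4, n_prolif=6)
        with pytest.raises(mg.ConvergenceError):
            mg.iterate_to_equilibrium(params, mg.SelectionSpec(regime="individual"), max_gen=1)

    def test_equilibrium_mean_load_nondecreasing_in_mu(self):
        means = []
        for mu in (1e-9, 1e-8, 1e-7):
            params = mg.GermlineParams(M0=8 << 5, mu=mu, n_cleavage=5, n_prolif=8)
            res = mg.iterate_to_equilibrium(params, mg.SelectionSpec(regime="individual"))
            means.append(res.dist.mean_load)
        assert means[0] < means[1] < means[2]


class TestScanGrid:
    def test_single_cell_grid_matches_direct_call(self):
        clin = mg.ClinicalModel()
        spec = mg.SelectionSpec(regime="individual")
        surf = mg.scan_grid([1e-8], [8], spec, clin, n_cleavage=5, n_prolif=8)
        params = mg.GermlineParams(M0=8 << 5, mu=1e-8, n_cleavage=5, n_prolif=8)
        res = mg.iterate_to_equilibrium(params, spec)
        a1, a2 = mg.clinical_fractions(res.dist, clin)
        assert surf.loglik[0, 0] == pytest.approx(mg.log_likelihood(a1, a2, clin))
        assert surf.to_frame().shape[0] == 1

    def test_surface_shape_and_frame_rows(self):
        spec = mg.SelectionSpec(regime="individual")
        surf = mg.scan_grid([1e-9, 1e-8], [4, 8], spec, n_cleavage=4, n_prolif=6)
        assert surf.loglik.shape == (2, 2)
        assert len(surf.to_frame()) == 4
        assert np.all(np.isfinite(surf.loglik))
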