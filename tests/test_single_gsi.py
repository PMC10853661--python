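"""Single-baseline sampler primitives and the one-baseline Gibbs fit."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import dirichlet_multinomial

from msgsi import (
    AlleleFreqState,
    McmcConfig,
    PriorSpec,
    UnassignableFishError,
    cdm_logpmf,
    log_genotype_likelihood,
    run_single_gsi,
    sample_allele_freqs,
    sample_memberships,
    sample_proportions,
)
from msgsi.diagnostics import effective_size
from _oracles import single_stage_posterior_mean
from conftest import make_baseline, make_mixture


class TestCdmLogpmf:
    def test_uniform_over_diploid_genotypes_at_unit_weights(self):
        """Integrating a flat Dirichlet against the multinomial makes all
        three diploid genotypes equally likely."""
        for x in ([2, 0], [1, 1], [0, 2]):
            assert np.exp(cdm_logpmf(x, [1.0, 1.0])) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("v", [[0.5, 0.5], [1.0, 2.0], [0.3, 1.7, 2.0]])
    def test_pmf_sums_to_one_over_genotypes(self, v):
        J = len(v)
        total = sum(
            np.exp(cdm_logpmf(x, v))
            for x in itertools.product(range(3), repeat=J)
            if sum(x) == 2
        )
        assert total == pytest.approx(1.0)

    def test_matches_scipy_dirichlet_multinomial(self):
        x, v = np.array([1, 1, 0]), np.array([0.4, 1.2, 2.0])
        assert np.exp(cdm_logpmf(x, v)) == pytest.approx(
            dirichlet_multinomial.pmf(x, v, 2)
        )


class TestGenotypeLikelihood:
    def test_fixed_frequency_certain_genotype(self):
        base = make_baseline(np.array([[[4, 0]]]), alleles=("A", "T"))
        state = AlleleFreqState(model="fully_bayesian", freqs=np.array([[[1.0, 0.0]]]))
        mix = make_mixture(np.array([[[2, 0]]]), base.loci)
        L = log_genotype_likelihood(mix, state)
        assert L[0, 0] == pytest.approx(0.0)

    def test_even_frequencies_heterozygote(self):
        base = make_baseline(np.array([[[2, 2]]]), alleles=("A", "T"))
        state = AlleleFreqState(model="fully_bayesian", freqs=np.array([[[0.5, 0.5]]]))
        mix = make_mixture(np.array([[[1, 1]]]), base.loci)
        assert log_genotype_likelihood(mix, state)[0, 0] == pytest.approx(np.log(0.25))

    def test_zero_frequency_positive_count_is_effectively_minus_inf(self):
        base = make_baseline(np.array([[[4, 0]]]), alleles=("A", "T"))
        state = AlleleFreqState(model="fully_bayesian", freqs=np.array([[[1.0, 0.0]]]))
        mix = make_mixture(np.array([[[0, 2]]]), base.loci)
        assert log_genotype_likelihood(mix, state)[0, 0] < -1e20

    def test_unobserved_locus_contributes_zero(self):
        base = make_baseline(
            np.stack([np.array([[3, 1], [2, 2]])], axis=0), alleles=("A", "T")
        )
        state = AlleleFreqState.conditional(base, PriorSpec().beta_for(base.loci))
        counts = np.zeros((1, 2, 2), np.int64)
        counts[0, 0] = (1, 1)
        mix = make_mixture(counts, base.loci, observed=np.array([[True, False]]))
        L1 = log_genotype_likelihood(mix, state)
        # dropping the missing locus entirely gives the same value
        base1 = make_baseline(base.counts[:, :1], alleles=("A", "T"))
        mix1 = make_mixture(counts[:, :1], base1.loci)
        state1 = AlleleFreqState.conditional(base1, PriorSpec().beta_for(base1.loci))
        np.testing.assert_allclose(L1, log_genotype_likelihood(mix1, state1))

    def test_conditional_matches_cdm_up_to_constant(self):
        base = make_baseline(np.array([[[5, 3]], [[1, 7]]]), alleles=("A", "T"))
        beta = PriorSpec().beta_for(base.loci)
        state = AlleleFreqState.conditional(base, beta)
        mix = make_mixture(np.array([[[2, 0]], [[1, 1]]]), base.loci)
        L = log_genotype_likelihood(mix, state)
        for m, k in itertools.product(range(2), range(2)):
            expect = cdm_logpmf(
                mix.counts[m, 0], base.counts[k, 0] + beta[0], include_coeff=False
            )
            assert L[m, k] == pytest.approx(expect)


class TestSampleMemberships:
    def test_diagnostic_alleles_deterministic(self, rng):
        logw = np.array([[0.0, -1e30], [-1e30, 0.0]])
        z = sample_memberships(logw, np.array([0.5, 0.5]), rng)
        assert z.tolist() == [0, 1]

    def test_identical_likelihoods_follow_proportions(self, rng):
        logw = np.zeros((4000, 2))
        p = np.array([0.8, 0.2])
        z = sample_memberships(logw, p, rng)
        assert np.abs((z == 0).mean() - 0.8) < 0.03

    def test_one_hot_proportions_assign_everyone(self, rng):
        logw = np.zeros((10, 3))
        z = sample_memberships(logw, np.array([0.0, 1.0, 0.0]), rng)
        assert (z == 1).all()

    def test_unassignable_fish_error_names_individual(self, rng):
        logw = np.full((1, 2), -1e30)
        with pytest.raises(UnassignableFishError, match="lonely"):
            sample_memberships(logw, np.array([0.5, 0.5]), rng, individuals=["lonely"])


class TestSampleProportions:
    def test_posterior_mean_small_monte_carlo(self, rng):
        draws = np.stack(
            [sample_proportions([3, 1], np.array([0.5, 0.5]), rng) for _ in range(4000)]
        )
        assert draws[:, 0].mean() == pytest.approx(0.7, abs=0.02)

    def test_zero_counts_prior_draw(self, rng):
        draws = np.stack(
            [sample_proportions([0, 0], np.array([2.0, 2.0]), rng) for _ in range(2000)]
        )
        assert draws.mean(axis=0) == pytest.approx([0.5, 0.5], abs=0.03)


class TestSampleAlleleFreqs:
    def test_pure_prior_draw(self, rng):
        base = make_baseline(np.array([[[2, 2]]]), alleles=("A", "T"))
        beta = np.array([[3.0, 1.0]])
        q = np.stack(
            [
                sample_allele_freqs(base.loci, beta, rng, n_pops=1)[0, 0]
                for _ in range(3000)
            ]
        )
        assert q.mean(axis=0) == pytest.approx([0.75, 0.25], abs=0.02)

    def test_huge_baseline_concentrates_on_empirical(self, rng):
        counts = np.array([[[60_000, 40_000]]])
        base_counts = counts
        beta = np.array([[0.5, 0.5]])
        loci = make_baseline(np.array([[[2, 2]]]), alleles=("A", "T")).loci
        q = sample_allele_freqs(loci, beta, rng, baseline_counts=base_counts)
        assert q[0, 0, 0] == pytest.approx(0.6, abs=0.01)

    def test_rows_sum_to_one(self, rng):
        loci = make_baseline(np.zeros((1, 1, 3), int), alleles=("A", "C", "T")).loci
        beta = np.array([[0.5, 0.5, 0.5]])
        q = sample_allele_freqs(loci, beta, rng, n_pops=4)
        np.testing.assert_allclose(q.sum(axis=2), 1.0)


class TestRunSingleGsi:
    def test_single_population_is_degenerate(self, rng):
        base = make_baseline(np.array([[[5, 3]]]), alleles=("A", "T"))
        mix = make_mixture(np.array([[[1, 1]], [[2, 0]]]), base.loci)
        fit = run_single_gsi(
            mix, base, {"pop1": "only"},
            mcmc=McmcConfig(n_chains=2, n_iter=50, n_burn=10, thin=1, seed=1),
        )
        np.testing.assert_allclose(fit.draws, 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_posterior_mean_matches_enumeration(self, seed):
        """Two fish, two populations, one diallelic locus: the Gibbs mean
        agrees with exhaustive enumeration of all membership configurations."""
        rng = np.random.default_rng(seed)
        counts = np.zeros((2, 1, 2), np.int64)
        for k in range(2):
            n = int(rng.integers(3, 8))
            a = int(rng.integers(0, 2 * n + 1))
            counts[k, 0] = (a, 2 * n - a)
        base = make_baseline(counts, alleles=("A", "T"))
        x = np.zeros((2, 1, 2), np.int64)
        for m in range(2):
            a = int(rng.integers(0, 3))
            x[m, 0] = (a, 2 - a)
        mix = make_mixture(x, base.loci)
        prior = PriorSpec(alpha_mode="per_population_flat")
        group_of = {"pop1": "A", "pop2": "B"}
        alpha = prior.alpha_for(base.populations, group_of)
        beta = prior.beta_for(base.loci)
        oracle = single_stage_posterior_mean(mix, base, alpha, beta)
        fit = run_single_gsi(
            mix, base, group_of, prior=prior,
            mcmc=McmcConfig(n_chains=4, n_iter=2000, n_burn=500, thin=1, seed=100 + seed),
        )
        for g_idx, g in enumerate(fit.group_names):
            per_chain = fit.group(g)
            mcse = per_chain.std(ddof=1) / np.sqrt(effective_size(per_chain))
            assert abs(fit.mean()[g] - oracle[g_idx]) < 3 * mcse

    def test_population_label_permutation_equivariant(self):
        counts = np.array([[[9, 1]], [[2, 8]], [[5, 5]]])
        base = make_baseline(counts, alleles=("A", "T"))
        perm = [2, 0, 1]
        base_p = make_baseline(
            counts[perm], populations=[base.populations[i] for i in perm],
            alleles=("A", "T"),
        )
        x = np.array([[[2, 0]], [[0, 2]], [[1, 1]], [[2, 0]]])
        mix = make_mixture(x, base.loci)
        group_of = {"pop1": "GA", "pop2": "GB", "pop3": "GA"}
        cfg = McmcConfig(n_chains=4, n_iter=1500, n_burn=500, thin=1, seed=4)
        m1 = run_single_gsi(mix, base, group_of, mcmc=cfg).mean()
        m2 = run_single_gsi(mix, base_p, group_of, mcmc=cfg.replace(seed=5)).mean()
        for g in ("GA", "GB"):
            assert abs(m1[g] - m2[g]) < 0.03

    def test_retained_draws_are_simplexes(self):
        base = make_baseline(np.array([[[5, 3]], [[1, 7]]]), alleles=("A", "T"))
        mix = make_mixture(np.array([[[1, 1]], [[2, 0]]]), base.loci)
        fit = run_single_gsi(
            mix, base, {"pop1": "A", "pop2": "B"},
            mcmc=McmcConfig(n_chains=2, n_iter=200, n_burn=50, thin=2, seed=8),
        )
        sums = fit.stacked().sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-12
        assert (fit.stacked() >= 0).all()

    def test_conditional_and_fully_bayesian_agree_at_large_baseline(self):
        """With well-determined baseline frequencies, integrating q out and
        sampling q give the same posterior mean proportions."""
        rng = np.random.default_rng(21)
        K, L, n = 3, 12, 400
        q = rng.dirichlet([0.4, 0.4], size=(K, L))
        counts = np.zeros((K, L, 2), np.int64)
        for k in range(K):
            counts[k] = rng.multinomial(2 * n, q[k])
        base = make_baseline(counts, alleles=("A", "T"))
        M = 40
        x = np.zeros((M, L, 2), np.int64)
        src = rng.integers(0, K, size=M)
        for m in range(M):
            x[m] = rng.multinomial(2, q[src[m]])
        mix = make_mixture(x, base.loci)
        group_of = {p: p for p in base.populations}
        cfg = McmcConfig(n_chains=4, n_iter=1500, n_burn=500, thin=1, seed=31)
        cond = run_single_gsi(mix, base, group_of, mcmc=cfg).mean()
        full = run_single_gsi(
            mix, base, group_of, mcmc=cfg.replace(model="fully_bayesian", seed=32)
        ).mean()
        assert np.abs(cond - full).max() < 0.04
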