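"""The integrated multistage sampler: stage linkage, combination, reductions."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msgsi import (
    McmcConfig,
    PriorSpec,
    RegionMap,
    SyntheticScenario,
    combine_proportions,
    regional_eligibility,
    run_msgsi,
    run_single_gsi,
    sample_regional_memberships,
    sample_regional_proportions,
    simulate_study,
    synthesize_mixture,
)
from msgsi.diagnostics import effective_size
from _oracles import msgsi_posterior_mean
from conftest import diagnostic_study, tiny_joint_instance


@pytest.fixture
def two_region_map():
    return RegionMap(
        broad_group_of={"p1": "A", "p2": "B", "p3": "C"},
        region_of_group={"B": "r1", "C": "r2"},
        regional_group_of={"r1": {"x1": "Ba"}, "r2": {"y1": "Ca", "y2": "Cb"}},
    )


class TestEligibility:
    def test_nonregional_fish_eligible_nowhere(self, two_region_map):
        elig = regional_eligibility(np.array([0, 0]), ["p1", "p2", "p3"], two_region_map)
        assert not elig.any()

    def test_region_fish_eligible_exactly_once(self, two_region_map):
        elig = regional_eligibility(
            np.array([1, 2, 0]), ["p1", "p2", "p3"], two_region_map
        )
        assert elig.tolist() == [[True, False], [False, True], [False, False]]
        assert (elig.sum(axis=1) <= 1).all()

    def test_single_region_all_fish(self):
        rmap = RegionMap(
            broad_group_of={"p1": "A"},
            region_of_group={"A": "r"},
            regional_group_of={"r": {"x": "Aa"}},
        )
        elig = regional_eligibility(np.zeros(5, int), ["p1"], rmap)
        assert elig.all()


class TestRegionalDraws:
    def test_zero_eligible_fish_no_draws(self, rng):
        z_r = sample_regional_memberships(
            np.zeros((3, 2)), np.array([0.5, 0.5]), np.zeros(3, bool), rng
        )
        assert (z_r == -1).all()
        p_r = sample_regional_proportions(z_r, 2, np.array([0.5, 0.5]), rng)
        assert p_r.sum() == pytest.approx(1.0)

    def test_diagnostic_regional_alleles_deterministic(self, rng):
        logw = np.array([[0.0, -1e30], [-1e30, 0.0], [0.0, -1e30]])
        elig = np.array([True, True, False])
        z_r = sample_regional_memberships(logw, np.array([0.5, 0.5]), elig, rng)
        assert z_r.tolist() == [0, 1, -1]

    def test_identical_likelihoods_follow_regional_proportions(self, rng):
        logw = np.zeros((3000, 2))
        elig = np.ones(3000, bool)
        z_r = sample_regional_memberships(logw, np.array([0.3, 0.7]), elig, rng)
        assert np.abs((z_r == 1).mean() - 0.7) < 0.03

    def test_counts_plus_prior_mean(self, rng):
        z_r = np.array([0] * 10 + [-1] * 5)
        draws = np.stack(
            [
                sample_regional_proportions(z_r, 2, np.array([0.5, 0.5]), rng)
                for _ in range(3000)
            ]
        )
        assert draws[:, 0].mean() == pytest.approx(10.5 / 11, abs=0.01)


class TestCombineProportions:
    def test_two_stage_combination_rule(self, rng):
        """Broad groups A/B keep their shares; C's share is split by the
        regional proportions (the worked combination example)."""
        rmap = RegionMap(
            broad_group_of={"p1": "A", "p2": "B", "p3": "C"},
            region_of_group={"C": "reg"},
            regional_group_of={"reg": {"x1": "Ca", "x2": "Cb"}},
        )
        out = combine_proportions(
            np.array([0.2, 0.3, 0.5]),
            ["p1", "p2", "p3"],
            rmap,
            p_regional={"reg": np.array([0.4, 0.6])},
            regional_pops={"reg": ["x1", "x2"]},
        )
        assert out.to_dict() == pytest.approx(
            {"A": 0.2, "B": 0.3, "Ca": 0.2, "Cb": 0.3}
        )

    def test_no_regions_identity(self):
        rmap = RegionMap(broad_group_of={"p1": "A", "p2": "B"})
        out = combine_proportions(np.array([0.4, 0.6]), ["p1", "p2"], rmap)
        assert out.to_dict() == pytest.approx({"A": 0.4, "B": 0.6})

    @given(
        st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
        st.lists(st.floats(0.01, 1), min_size=2, max_size=2),
    )
    @settings(max_examples=50, deadline=None)
    def test_output_is_simplex(self, raw_p, raw_pr):
        p = np.asarray(raw_p) / np.sum(raw_p)
        pr = np.asarray(raw_pr) / np.sum(raw_pr)
        rmap = RegionMap(
            broad_group_of={"p1": "A", "p2": "B", "p3": "C"},
            region_of_group={"C": "reg"},
            regional_group_of={"reg": {"x1": "Ca", "x2": "Cb"}},
        )
        out = combine_proportions(
            p, ["p1", "p2", "p3"], rmap,
            p_regional={"reg": pr}, regional_pops={"reg": ["x1", "x2"]},
        )
        assert out.sum() == pytest.approx(1.0)
        assert (out >= 0).all()


class TestRunMsgsi:
    def test_no_regions_reduces_to_single_baseline_bit_identically(self):
        mix_b, base_b, _, _, rmap = tiny_joint_instance(0)
        flat = RegionMap(broad_group_of=dict(rmap.broad_group_of))
        cfg = McmcConfig(n_chains=3, n_iter=300, n_burn=100, thin=2, seed=17)
        a = run_msgsi(mix_b, base_b, flat, mcmc=cfg)
        b = run_single_gsi(mix_b, base_b, rmap.broad_group_of, mcmc=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_missing_regional_baseline_errors_before_sampling(self):
        mix_b, base_b, mix_r, base_r, rmap = tiny_joint_instance(1)
        with pytest.raises(ValueError, match="matching regional baseline"):
            run_msgsi(mix_b, base_b, rmap, regional_bases={}, mix_regional={"reg": mix_r})

    @pytest.mark.parametrize("seed", range(2))
    def test_combined_mean_matches_joint_enumeration(self, seed):
        """Tiny instances: Gibbs combined means agree with brute-force
        enumeration over all joint membership configurations."""
        mix_b, base_b, mix_r, base_r, rmap = tiny_joint_instance(seed)
        prior = PriorSpec()
        oracle = msgsi_posterior_mean(
            mix_b, base_b, mix_r, base_r, rmap,
            prior.alpha_for(base_b.populations, rmap.broad_group_of),
            prior.alpha_for(base_r.populations, rmap.regional_group_of["reg"]),
            prior.beta_for(base_b.loci),
            prior.beta_for(base_r.loci),
        )
        fit = run_msgsi(
            mix_b, base_b, rmap,
            regional_bases={"reg": base_r}, mix_regional={"reg": mix_r},
            mcmc=McmcConfig(n_chains=4, n_iter=2000, n_burn=500, thin=1, seed=1000 + seed),
        )
        for g in fit.group_names:
            per_chain = fit.group(g)
            mcse = per_chain.std(ddof=1) / np.sqrt(effective_size(per_chain))
            assert abs(fit.mean()[g] - oracle[g]) < 3 * mcse

    def test_combined_draws_are_simplexes(self):
        mix_b, base_b, mix_r, base_r, rmap = tiny_joint_instance(2)
        fit = run_msgsi(
            mix_b, base_b, rmap,
            regional_bases={"reg": base_r}, mix_regional={"reg": mix_r},
            mcmc=McmcConfig(n_chains=2, n_iter=400, n_burn=100, thin=1, seed=3),
        )
        assert np.abs(fit.stacked().sum(axis=1) - 1.0).max() < 1e-12

    def test_marginalization_consistency(self):
        """Summing a region's combined groups recovers the broad-scale mass
        of that region, draw by draw."""
        mix_b, base_b, mix_r, base_r, rmap = tiny_joint_instance(3)
        fit = run_msgsi(
            mix_b, base_b, rmap,
            regional_bases={"reg": base_r}, mix_regional={"reg": mix_r},
            mcmc=McmcConfig(n_chains=2, n_iter=400, n_burn=100, thin=1, seed=5),
        )
        region_cols = [fit.group_names.index(g) for g in ("GBa", "GBb")]
        in_region = np.array(
            [rmap.region_of_population(p) == "reg" for p in fit.pop_names]
        )
        mass = fit.pop_draws[:, :, in_region].sum(axis=2)
        np.testing.assert_allclose(
            fit.draws[:, :, region_cols].sum(axis=2), mass, atol=1e-12
        )

    def test_broad_diagnostic_fish_assigned_almost_surely(self):
        mix_b, base_b, mix_r, base_r, rmap, groups, _ = diagnostic_study()
        cfg = McmcConfig(
            n_chains=2, n_iter=600, n_burn=200, thin=1, seed=6,
            record_memberships=True,
        )
        fit = run_msgsi(
            mix_b, base_b, rmap,
            regional_bases={"reg": base_r}, mix_regional={"reg": mix_r}, mcmc=cfg,
        )
        pop_of = {p: i for i, p in enumerate(fit.pop_names)}
        want = np.array([pop_of["a1"] if g == "GA" else pop_of["y1"] for g in groups])
        frac_correct = (fit.memberships == want[None, None, :]).mean()
        assert frac_correct > 0.99

    def test_population_order_permutation_leaves_group_means(self):
        mix_b, base_b, mix_r, base_r, rmap = tiny_joint_instance(4)
        perm_base = type(base_b)(
            loci=base_b.loci,
            populations=base_b.populations[::-1],
            counts=base_b.counts[::-1],
            sample_sizes=base_b.sample_sizes[::-1],
        )
        cfg = McmcConfig(n_chains=4, n_iter=1500, n_burn=500, thin=1, seed=7)
        m1 = run_msgsi(
            mix_b, base_b, rmap,
            regional_bases={"reg": base_r}, mix_regional={"reg": mix_r}, mcmc=cfg,
        ).mean()
        m2 = run_msgsi(
            mix_b, perm_base, rmap,
            regional_bases={"reg": base_r}, mix_regional={"reg": mix_r},
            mcmc=cfg.replace(seed=8),
        ).mean()
        assert np.abs(m1 - m2[m1.index]).max() < 0.03

    def test_parameter_recovery_on_informative_scenario(self, rng):
        """Strong markers at both stages put every posterior mean within
        0.1 of the realized truth."""
        sc = SyntheticScenario(
            pops_per_group=2, regional_pops_per_group=2,
            n_broad_loci=30, n_regional_loci=30,
            baseline_n=30, mixture_size=100, theta_broad=0.3, theta_regional=0.3,
        )
        study = simulate_study(sc, rng)
        truth_p = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        synth = synthesize_mixture(study, truth_p, 100, rng)
        fit = run_msgsi(
            synth.mix_broad, synth.baseline_broad, study.region_map,
            regional_bases=synth.baselines_regional, mix_regional=synth.mix_regional,
            mcmc=McmcConfig(n_chains=3, n_iter=1200, n_burn=400, thin=1, seed=9),
        )
        est = fit.mean().reindex(synth.truth.group_names).to_numpy()
        assert np.abs(est - synth.truth.proportions).max() < 0.1
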