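"""Brute-force enumeration oracles for tiny stock-identification instances.

These compute exact posterior means by summing the unnormalized joint
posterior over all membership configurations, with genotype likelihoods
taken from scipy's Dirichlet-multinomial — an independent route from the
package's own samplers and likelihood tables.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln
from scipy.stats import dirichlet_multinomial

from msgsi.datatypes import BaselineData, MixtureData, RegionMap


def cdm_lik_table(mix: MixtureData, base: BaselineData, beta: np.ndarray) -> np.ndarray:
    """(M, K) conditional genotype likelihoods (coefficients included)."""
    M, K = mix.n_individuals, base.n_pops
    out = np.ones((M, K))
    for l, spec in enumerate(base.loci):
        j = spec.n_alleles
        for k in range(K):
            v = base.counts[k, l, :j] + beta[l, :j]
            for m in range(M):
                if mix.observed[m, l]:
                    out[m, k] *= dirichlet_multinomial.pmf(
                        mix.counts[m, l, :j], v, spec.ploidy
                    )
    return out


def dirmult_logweight(counts: np.ndarray, alpha: np.ndarray) -> float:
    """Log marginal of membership counts under a Dirichlet(alpha) prior."""
    a = np.asarray(alpha, dtype=float)
    c = np.asarray(counts, dtype=float)
    return float(
        gammaln(a.sum())
        - gammaln(a.sum() + c.sum())
        + (gammaln(c + a) - gammaln(a)).sum()
    )


def single_stage_posterior_mean(
    mix: MixtureData, base: BaselineData, alpha: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Exact posterior mean of population proportions by enumerating all
    K^M membership configurations of the conditional model."""
    lik = cdm_lik_table(mix, base, beta)
    M, K = lik.shape
    A = alpha.sum()
    total_w = 0.0
    mean_acc = np.zeros(K)
    for z in itertools.product(range(K), repeat=M):
        counts = np.bincount(z, minlength=K)
        w = np.exp(dirmult_logweight(counts, alpha) + np.log(lik[np.arange(M), z]).sum())
        total_w += w
        mean_acc += w * (counts + alpha) / (M + A)
    return mean_acc / total_w


def msgsi_posterior_mean(
    mix_b: MixtureData,
    base_b: BaselineData,
    mix_r: MixtureData,
    base_r: BaselineData,
    region_map: RegionMap,
    alpha_b: np.ndarray,
    alpha_r: np.ndarray,
    beta_b: np.ndarray,
    beta_r: np.ndarray,
) -> dict[str, float]:
    """Exact posterior mean of combined group proportions for one sub-region.

    Enumerates every joint configuration (broad memberships for all fish,
    regional memberships for the fish whose broad population lies in the
    sub-region).  The two stages are linked one-directionally: broad
    memberships are informed by broad-scale data alone, and the regional
    stage is conditioned on them, so the regional configuration distribution
    is normalized *within* each broad configuration.  Given a configuration,
    broad and regional proportion vectors are independent Dirichlets, so the
    combined regional groups have mean E[sum_g p_r] * E[region mass].
    """
    region = region_map.regions[0]
    lik_b = cdm_lik_table(mix_b, base_b, beta_b)
    lik_r = cdm_lik_table(mix_r, base_r, beta_r)
    M, B = lik_b.shape
    K_r = lik_r.shape[1]
    A_b, A_r = alpha_b.sum(), alpha_r.sum()
    pops_b = base_b.populations
    in_region = np.array(
        [region_map.region_of_population(p) == region for p in pops_b]
    )
    group_of = region_map.broad_group_of
    nonreg = region_map.groups_without_region()
    reg_groups = region_map.region_groups(region)
    gmap_r = region_map.regional_group_of[region]
    pops_r = base_r.populations

    names = nonreg + reg_groups
    acc = dict.fromkeys(names, 0.0)
    total_w = 0.0
    for zb in itertools.product(range(B), repeat=M):
        counts_b = np.bincount(zb, minlength=B)
        w_b = np.exp(
            dirmult_logweight(counts_b, alpha_b)
            + np.log(lik_b[np.arange(M), zb]).sum()
        )
        Ep = (counts_b + alpha_b) / (M + A_b)
        eligible = [m for m in range(M) if in_region[zb[m]]]
        mass = Ep[in_region].sum()
        # inner stage: normalized within this broad configuration
        inner_w = 0.0
        inner_reg = dict.fromkeys(reg_groups, 0.0)
        for zr in itertools.product(range(K_r), repeat=len(eligible)):
            counts_r = np.bincount(zr, minlength=K_r)
            w_r = np.exp(
                dirmult_logweight(counts_r, alpha_r)
                + sum(np.log(lik_r[m, zr[i]]) for i, m in enumerate(eligible))
            )
            Epr = (counts_r + alpha_r) / (len(eligible) + A_r)
            inner_w += w_r
            for g in reg_groups:
                sel = np.array([gmap_r[p] == g for p in pops_r])
                inner_reg[g] += w_r * Epr[sel].sum()
        total_w += w_b
        for g in nonreg:
            sel = np.array([group_of[p] == g for p in pops_b])
            acc[g] += w_b * Ep[sel].sum()
        for g in reg_groups:
            acc[g] += w_b * (inner_reg[g] / inner_w) * mass
    return {g: acc[g] / total_w for g in names}
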