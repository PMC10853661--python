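"""Integrated multistage genetic stock identification (Ms.GSI).

Two stacked Bayesian mixture models share one Gibbs sampler: a broad-scale
stage assigns every mixture fish to a broad-scale baseline population, and,
within the same sweep, each sub-region's regional stage reassigns the fish
whose current broad-scale population belongs to that sub-region.  Regional
membership is conditional on the broad-scale one: a fish whose broad draw
falls outside sub-region r carries the all-zero regional indicator there.
Broad and regional proportion vectors are combined each retained iteration
(regional proportions scaled by the broad-scale mass of their sub-region), so
the combined posterior propagates the uncertainty of both stages.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from typing import Mapping, Sequence

from .datatypes import (
    BaselineData,
    McmcConfig,
    MixtureData,
    PosteriorDraws,
    PriorSpec,
    RegionMap,
)
from .io import align_mixture_to_baseline
from .single import (
    AlleleFreqState,
    assigned_allele_counts,
    log_genotype_likelihood,
    sample_allele_freqs,
    sample_memberships,
    sample_proportions,
)

__all__ = [
    "regional_eligibility",
    "sample_regional_memberships",
    "sample_regional_proportions",
    "combine_proportions",
    "run_msgsi",
]


def regional_eligibility(
    z: np.ndarray, populations: Sequence[str], region_map: RegionMap
) -> np.ndarray:
    """(M, R) boolean table: fish m is eligible for region r iff its current
    broad-scale population belongs to that sub-region.  Rows sum to at most
    one because sub-regions are disjoint."""
    regions = region_map.regions
    reg_idx = {r: i for i, r in enumerate(regions)}
    pop_region = np.full(len(populations), -1, dtype=np.int64)
    for k, pop in enumerate(populations):
        r = region_map.region_of_population(pop)
        if r is not None:
            pop_region[k] = reg_idx[r]
    out = np.zeros((len(z), len(regions)), dtype=bool)
    assigned = pop_region[np.asarray(z, dtype=int)]
    for i in range(len(regions)):
        out[:, i] = assigned == i
    return out


def sample_regional_memberships(
    log_lik: np.ndarray,
    p_r: np.ndarray,
    eligible: np.ndarray,
    rng: np.random.Generator,
    individuals: Sequence[str] | None = None,
) -> np.ndarray:
    """Draw regional population indices for eligible fish; -1 elsewhere.

    Eligible fish draw from weights p_r[k] * exp(loglik[m, k]); ineligible
    fish keep the all-zero indicator (encoded as -1)."""
    M = log_lik.shape[0]
    z_r = np.full(M, -1, dtype=np.int64)
    idx = np.flatnonzero(eligible)
    if idx.size:
        names = [individuals[i] for i in idx] if individuals is not None else None
        z_r[idx] = sample_memberships(log_lik[idx], p_r, rng, individuals=names)
    return z_r


def sample_regional_proportions(
    z_r: np.ndarray,
    n_pops: int,
    alpha_r: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dirichlet draw of regional proportions from eligible-fish counts.

    With zero eligible fish this is a pure prior draw."""
    counts = np.bincount(z_r[z_r >= 0], minlength=n_pops)
    return sample_proportions(counts, alpha_r, rng)


def combine_proportions(
    p: np.ndarray,
    populations: Sequence[str],
    region_map: RegionMap,
    p_regional: Mapping[str, np.ndarray] | None = None,
    regional_pops: Mapping[str, Sequence[str]] | None = None,
) -> pd.Series:
    """Combine broad and regional proportion vectors into one simplex.

    Broad reporting groups without regional coverage keep their summed
    population proportions; each regional reporting group gets its regional
    proportion scaled by the broad-scale mass of its sub-region, so the
    output sums to one for any simplex inputs.
    """
    p = np.asarray(p, dtype=float)
    p_regional = p_regional or {}
    regional_pops = regional_pops or {}
    group_of = region_map.broad_group_of
    values: list[float] = []
    names: list[str] = []
    for g in region_map.groups_without_region():
        mask = [group_of[pop] == g for pop in populations]
        values.append(float(p[np.asarray(mask)].sum()))
        names.append(g)
    for r in region_map.regions:
        in_r = np.asarray(
            [region_map.region_of_population(pop) == r for pop in populations]
        )
        mass = float(p[in_r].sum())
        pr = np.asarray(p_regional[r], dtype=float)
        pops_r = list(regional_pops[r])
        gmap = region_map.regional_group_of[r]
        for g in region_map.region_groups(r):
            sel = np.asarray([gmap[pop] == g for pop in pops_r])
            values.append(float(pr[sel].sum()) * mass)
            names.append(g)
    return pd.Series(values, index=names)


def _indicator(groups: Sequence[str], labels: Sequence[str]) -> np.ndarray:
    """(G, K) group-membership indicator; labels outside ``groups`` get no row."""
    out = np.zeros((len(groups), len(labels)))
    gi = {g: i for i, g in enumerate(groups)}
    for k, lab in enumerate(labels):
        if lab in gi:
            out[gi[lab], k] = 1.0
    return out


def run_msgsi(
    mix_broad: MixtureData,
    broad_base: BaselineData,
    region_map: RegionMap,
    regional_bases: Mapping[str, BaselineData] | None = None,
    mix_regional: Mapping[str, MixtureData] | None = None,
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    progress=None,
) -> PosteriorDraws:
    """Run the integrated multistage Gibbs sampler.

    Per iteration: (a) draw broad-scale memberships for every fish; (b) per
    sub-region, recompute eligibility and draw regional memberships for the
    eligible fish; (c) draw broad and regional proportion vectors (and allele
    frequencies in the fully Bayesian model) from their full conditionals,
    then record the combined group-proportion vector.  Chains are independent
    and initialized from the priors; each chain's random stream is a spawned
    child of the master seed, so adding chains never perturbs earlier ones.

    All mixtures must list the same fish in the same order; every region in
    the map needs a matching regional baseline and mixture.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcConfig()
    regional_bases = dict(regional_bases or {})
    mix_regional = dict(mix_regional or {})
    region_map.validate()
    regions = region_map.regions
    missing = [r for r in regions if r not in regional_bases]
    if missing:
        raise ValueError(
            "region(s) in map without a matching regional baseline: "
            + ", ".join(missing)
        )
    missing = [r for r in regions if r not in mix_regional]
    if missing:
        raise ValueError(
            "region(s) in map without a matching regional mixture: "
            + ", ".join(missing)
        )

    mix_b, base_b = align_mixture_to_baseline(mix_broad, broad_base)
    pops_b = base_b.populations
    unmapped = [p for p in pops_b if p not in region_map.broad_group_of]
    if unmapped:
        raise ValueError(
            "broad-scale population(s) missing from region map: "
            + ", ".join(unmapped)
        )
    aligned_r: dict[str, tuple[MixtureData, BaselineData]] = {}
    for r in regions:
        mr, br = align_mixture_to_baseline(mix_regional[r], regional_bases[r])
        if mr.individuals != mix_b.individuals:
            raise ValueError(
                f"regional mixture for {r!r} must list the same fish in the "
                "same order as the broad-scale mixture"
            )
        bad = [p for p in br.populations if p not in region_map.regional_group_of[r]]
        if bad:
            raise ValueError(
                f"regional population(s) missing from region map for {r!r}: "
                + ", ".join(bad)
            )
        aligned_r[r] = (mr, br)

    M = mix_b.n_individuals
    B = base_b.n_pops
    group_of = region_map.broad_group_of
    alpha_b = prior.alpha_for(pops_b, group_of)
    beta_b = prior.beta_for(base_b.loci)

    reg_idx = {r: i for i, r in enumerate(regions)}
    pop_region = np.full(B, -1, dtype=np.int64)
    for k, pop in enumerate(pops_b):
        r = region_map.region_of_population(pop)
        if r is not None:
            pop_region[k] = reg_idx[r]
    region_mask = [pop_region == i for i in range(len(regions))]

    nonreg_groups = [
        g
        for g in region_map.groups_without_region()
        if any(group_of[p] == g for p in pops_b)
    ]
    A_nonreg = _indicator(nonreg_groups, [group_of[p] for p in pops_b])[
        :, : B
    ] if nonreg_groups else np.zeros((0, B))

    alpha_r: dict[str, np.ndarray] = {}
    beta_r: dict[str, np.ndarray] = {}
    G_r: dict[str, np.ndarray] = {}
    for r in regions:
        _, br = aligned_r[r]
        gmap = region_map.regional_group_of[r]
        alpha_r[r] = prior.alpha_for(br.populations, gmap)
        beta_r[r] = prior.beta_for(br.loci)
        G_r[r] = _indicator(
            region_map.region_groups(r), [gmap[p] for p in br.populations]
        )

    combined_names = list(nonreg_groups)
    for r in regions:
        combined_names.extend(region_map.region_groups(r))
    Gc = len(combined_names)

    conditional = mcmc.model == "conditional"
    if conditional:
        Lb = log_genotype_likelihood(mix_b, AlleleFreqState.conditional(base_b, beta_b))
        Lr = {
            r: log_genotype_likelihood(
                aligned_r[r][0], AlleleFreqState.conditional(aligned_r[r][1], beta_r[r])
            )
            for r in regions
        }

    C = mcmc.n_chains
    T_keep = mcmc.retained_per_chain
    draws = np.empty((C, T_keep, Gc))
    pop_draws = np.empty((C, T_keep, B))
    memb = (
        np.empty((C, T_keep, M), dtype=np.int16)
        if mcmc.record_memberships
        else None
    )

    seeds = np.random.SeedSequence(mcmc.seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        p = rng.dirichlet(alpha_b)
        p_r = {r: rng.dirichlet(alpha_r[r]) for r in regions}
        if not conditional:
            state_b = AlleleFreqState.from_prior(base_b.loci, B, beta_b, rng)
            state_r = {
                r: AlleleFreqState.from_prior(
                    aligned_r[r][1].loci,
                    aligned_r[r][1].n_pops,
                    beta_r[r],
                    rng,
                )
                for r in regions
            }
        kept = 0
        for t in range(mcmc.n_iter):
            if not conditional:
                Lb = log_genotype_likelihood(mix_b, state_b)
            zb = sample_memberships(Lb, p, rng, individuals=mix_b.individuals)
            assigned_region = pop_region[zb]
            z_r: dict[str, np.ndarray] = {}
            for i, r in enumerate(regions):
                mr, br = aligned_r[r]
                if not conditional:
                    Lr_r = log_genotype_likelihood(mr, state_r[r])
                else:
                    Lr_r = Lr[r]
                z_r[r] = sample_regional_memberships(
                    Lr_r, p_r[r], assigned_region == i, rng, individuals=mr.individuals
                )
            p = sample_proportions(
                np.bincount(zb, minlength=B), alpha_b, rng
            )
            for r in regions:
                p_r[r] = sample_regional_proportions(
                    z_r[r], aligned_r[r][1].n_pops, alpha_r[r], rng
                )
            if not conditional:
                state_b = AlleleFreqState(
                    model="fully_bayesian",
                    freqs=sample_allele_freqs(
                        base_b.loci,
                        beta_b,
                        rng,
                        baseline_counts=base_b.counts,
                        assigned_counts=assigned_allele_counts(mix_b, zb, B),
                    ),
                )
                for r in regions:
                    mr, br = aligned_r[r]
                    zr = z_r[r]
                    elig = zr >= 0
                    sub = mr.subset(np.flatnonzero(elig)) if elig.any() else None
                    ac = (
                        assigned_allele_counts(sub, zr[elig], br.n_pops)
                        if sub is not None
                        else None
                    )
                    state_r[r] = AlleleFreqState(
                        model="fully_bayesian",
                        freqs=sample_allele_freqs(
                            br.loci,
                            beta_r[r],
                            rng,
                            baseline_counts=br.counts,
                            assigned_counts=ac,
                        ),
                    )
            if t >= mcmc.n_burn and (t - mcmc.n_burn) % mcmc.thin == mcmc.thin - 1:
                if kept < T_keep:
                    parts = [A_nonreg @ p]
                    for i, r in enumerate(regions):
                        parts.append((G_r[r] @ p_r[r]) * p[region_mask[i]].sum())
                    draws[c, kept] = np.concatenate(parts)
                    pop_draws[c, kept] = p
                    if memb is not None:
                        memb[c, kept] = zb
                    kept += 1
        if progress is not None:
            progress(c + 1, C)

    return PosteriorDraws(
        group_names=combined_names,
        draws=draws,
        pop_names=list(pops_b),
        pop_draws=pop_draws,
        memberships=memb,
        individuals=list(mix_b.individuals),
        config=mcmc,
    )
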