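"""Hard cut-off two-step stock identification (the conventional comparator).

Step 1 fits the broad-scale baseline alone and computes, per fish, the
posterior probability of belonging to each broad reporting group.  Fish whose
probability of membership in a sub-region exceeds a hard threshold (0.8 by
default, strict inequality) are selected for step 2, an independent fit of
that sub-region's baseline restricted to the selected fish.  The combined
report keeps non-regional groups at their step-1 posterior and rescales each
regional group's step-2 draws by a *fixed* step-1 summary (the posterior mean
of the sub-region's broad-scale mass, or optionally the selected-fish
fraction) — so, unlike the integrated multistage model, the combined
intervals omit step-1 uncertainty.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    BaselineData,
    McmcConfig,
    MixtureData,
    PosteriorDraws,
    PriorSpec,
    RegionMap,
)
from .single import run_single_gsi

__all__ = ["AssignmentTable", "assignment_probabilities", "select_for_stage2", "run_hc2step", "Hc2StepResult"]


@dataclass
class AssignmentTable:
    """Per-fish posterior membership probabilities from the broad-scale step."""

    individuals: list[str]
    group_probs: pd.DataFrame  # (M, broad groups), rows sum to 1
    region_probs: pd.DataFrame  # (M, regions)
    threshold: float
    selected: pd.DataFrame  # boolean (M, regions), probability strictly > threshold


def assignment_probabilities(
    stage1: PosteriorDraws, region_map: RegionMap, threshold: float = 0.8
) -> AssignmentTable:
    """Summarize broad-scale membership draws into assignment probabilities.

    The probability for group g is the fraction of retained draws in which
    the fish's membership indicator falls in g's populations; region
    probabilities sum the groups mapped to that sub-region.
    """
    if stage1.memberships is None:
        raise ValueError("stage-1 draws were run without membership recording")
    pops = stage1.pop_names
    groups = region_map.broad_groups
    gi = {g: i for i, g in enumerate(groups)}
    pop_group = np.array([gi[region_map.broad_group_of[p]] for p in pops])
    z = stage1.memberships.reshape(-1, stage1.memberships.shape[-1])  # (D, M)
    gz = pop_group[z]
    M = z.shape[1]
    probs = np.stack([(gz == i).mean(axis=0) for i in range(len(groups))], axis=1)
    gp = pd.DataFrame(probs, index=stage1.individuals, columns=groups)
    regions = region_map.regions
    rp = pd.DataFrame(0.0, index=stage1.individuals, columns=regions)
    for r in regions:
        for g in groups:
            if region_map.region_of_group.get(g) == r:
                rp[r] += gp[g]
    sel = rp > threshold
    return AssignmentTable(
        individuals=list(stage1.individuals),
        group_probs=gp,
        region_probs=rp,
        threshold=threshold,
        selected=sel,
    )


def select_for_stage2(
    table: AssignmentTable, region: str, threshold: float | None = None
) -> np.ndarray:
    """Indices of fish whose region probability strictly exceeds the threshold."""
    tau = table.threshold if threshold is None else threshold
    return np.flatnonzero(table.region_probs[region].to_numpy() > tau)


@dataclass
class Hc2StepResult:
    draws: PosteriorDraws
    assignment: AssignmentTable
    stage1: PosteriorDraws
    stage2: dict[str, PosteriorDraws]
    scale: dict[str, float]


def run_hc2step(
    mix_broad: MixtureData,
    broad_base: BaselineData,
    region_map: RegionMap,
    regional_bases: Mapping[str, BaselineData],
    mix_regional: Mapping[str, MixtureData],
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    threshold: float = 0.8,
    rescale: str = "stage1_mean",
) -> Hc2StepResult:
    """Run both steps independently and combine their summaries.

    ``rescale`` chooses the fixed constant multiplying step-2 draws:
    ``stage1_mean`` (posterior mean of the sub-region's broad-scale mass) or
    ``selected_fraction`` (share of fish passing the threshold).
    """
    if rescale not in ("stage1_mean", "selected_fraction"):
        raise ValueError(f"unknown rescale rule {rescale!r}")
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcConfig()
    region_map.validate()
    regions = region_map.regions
    missing = [r for r in regions if r not in dict(regional_bases)]
    if missing:
        raise ValueError(
            "region(s) without a matching regional baseline: " + ", ".join(missing)
        )

    seeds = np.random.SeedSequence(mcmc.seed).spawn(1 + len(regions))
    stage_seed = [int(s.generate_state(1)[0] % np.int64(2**31)) for s in seeds]

    stage1 = run_single_gsi(
        mix_broad,
        broad_base,
        region_map.broad_group_of,
        prior=prior,
        mcmc=mcmc.replace(seed=stage_seed[0], record_memberships=True),
    )
    table = assignment_probabilities(stage1, region_map, threshold=threshold)

    M = mix_broad.n_individuals
    stage2: dict[str, PosteriorDraws] = {}
    scale: dict[str, float] = {}
    parts: list[np.ndarray] = []
    names: list[str] = []
    for g in region_map.groups_without_region():
        if g in stage1.group_names:
            parts.append(stage1.group(g)[:, :, None])
            names.append(g)
    for i, r in enumerate(regions):
        sel = select_for_stage2(table, r)
        if sel.size == 0:
            warnings.warn(
                f"no fish passed the {table.threshold} threshold for region "
                f"{r!r}; step 2 reports prior-only proportions",
                stacklevel=2,
            )
        mix_r = mix_regional[r].subset(sel)
        fit = run_single_gsi(
            mix_r,
            regional_bases[r],
            region_map.regional_group_of[r],
            prior=prior,
            mcmc=mcmc.replace(seed=stage_seed[1 + i], record_memberships=False),
        )
        stage2[r] = fit
        if rescale == "stage1_mean":
            mass = sum(
                stage1.mean()[g]
                for g in region_map.broad_groups
                if region_map.region_of_group.get(g) == r
            )
        else:
            mass = sel.size / M if M else 0.0
        scale[r] = float(mass)
        for g in region_map.region_groups(r):
            parts.append(fit.group(g)[:, :, None] * scale[r])
            names.append(g)

    combined = PosteriorDraws(
        group_names=names,
        draws=np.concatenate(parts, axis=2),
        individuals=list(mix_broad.individuals),
        config=mcmc,
    )
    return Hc2StepResult(
        draws=combined, assignment=table, stage1=stage1, stage2=stage2, scale=scale
    )
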