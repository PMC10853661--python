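"""Synthetic baselines, region maps, and leave-out mixtures.

The generator emulates the structure of a two-baseline study: a broad-scale
baseline spanning several reporting groups with a small, low-resolution
marker set, and one high-resolution regional baseline refining a subset of
those groups.  Population allele frequencies follow an F-model: each locus
has an ancestral frequency vector drawn flat-Dirichlet, and each population
drifts around it as q_k ~ Dirichlet(theta * ancestral) — smaller theta means
stronger drift and more informative markers.  An optional two-level variant
draws per-group centers first, which allows one regional group's broad-scale
signature to be blended toward the non-regional group (a deliberately
confusable pair, the situation in which hard cut-off selection breaks down).

Mixtures are synthesized by leave-out draws: mixture fish are removed from
every baseline copy returned, and each carries genotypes at both marker
sets.  Fish from groups without regional coverage have no source population
in any regional baseline; their regional-marker genotypes are simulated from
per-population ghost frequencies drawn from the same F-model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BaselineData,
    LocusSpec,
    MixtureData,
    RegionMap,
    TruthRecord,
)

__all__ = [
    "SyntheticScenario",
    "SyntheticBaseline",
    "StudyData",
    "MixtureSynthesis",
    "random_true_proportions",
    "allocate_counts",
    "generate_baseline",
    "simulate_study",
    "synthesize_mixture",
]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    The default shape mirrors the case-study design at desk scale: five
    broad reporting groups, the last four refined by a single sub-region;
    a 10-locus broad baseline and a 40-locus regional baseline with disjoint
    marker sets; 50 baseline fish per population; mixtures of 205 fish.
    """

    n_broad_groups: int = 5
    n_regional_groups: int = 4
    pops_per_group: int = 4
    regional_pops_per_group: int = 4
    n_broad_loci: int = 10
    n_regional_loci: int = 40
    n_alleles: int = 2
    ploidy: int = 2
    baseline_n: int = 50
    theta_broad: float = 0.3
    theta_regional: float = 0.3
    theta_group_centers: float | None = None
    confusable: tuple[str, str, float] | None = None
    mixture_size: int = 205
    true_group_proportions: Sequence[float] | None = None
    group_names: Sequence[str] | None = None
    region_name: str = "region_1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_broad_groups < 1 or not 0 <= self.n_regional_groups <= self.n_broad_groups:
            raise ValueError("invalid group counts")
        for v in (
            self.pops_per_group,
            self.regional_pops_per_group,
            self.n_broad_loci,
            self.n_regional_loci,
            self.baseline_n,
            self.mixture_size,
        ):
            if v < 1:
                raise ValueError("all sizes must be positive")
        if self.n_alleles < 2:
            raise ValueError("need at least two alleles per locus")
        if self.theta_broad <= 0 or self.theta_regional <= 0:
            raise ValueError("theta must be strictly positive")
        if self.true_group_proportions is not None:
            p = np.asarray(self.true_group_proportions, dtype=float)
            if p.shape != (self.n_broad_groups,) or (p < 0).any():
                raise ValueError("true_group_proportions must be a simplex over groups")
            if abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("true_group_proportions must sum to one")

    @property
    def groups(self) -> list[str]:
        if self.group_names is not None:
            if len(self.group_names) != self.n_broad_groups:
                raise ValueError("group_names length mismatch")
            return list(self.group_names)
        return [f"G{i + 1}" for i in range(self.n_broad_groups)]

    @property
    def regional_groups(self) -> list[str]:
        return self.groups[self.n_broad_groups - self.n_regional_groups :]

    @property
    def nonregional_groups(self) -> list[str]:
        return self.groups[: self.n_broad_groups - self.n_regional_groups]


@dataclass
class SyntheticBaseline:
    """A generated baseline with its latent truth and fish-level genotypes.

    ``fish`` has shape (populations, baseline_n, loci, alleles); ``freqs``
    are the latent population allele frequencies the fish were drawn from,
    ``ancestral`` the locus-level ancestral frequencies.
    """

    level: str
    data: BaselineData
    freqs: np.ndarray
    fish: np.ndarray
    ancestral: np.ndarray
    theta: float
    group_of: dict[str, str]


@dataclass
class StudyData:
    scenario: SyntheticScenario
    broad: SyntheticBaseline
    regional: dict[str, SyntheticBaseline]
    region_map: RegionMap


@dataclass
class MixtureSynthesis:
    mix_broad: MixtureData
    mix_regional: dict[str, MixtureData]
    baseline_broad: BaselineData
    baselines_regional: dict[str, BaselineData]
    truth: TruthRecord


def random_true_proportions(
    n_groups: int, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Flat-Dirichlet draw(s) of true reporting-group proportions."""
    if n_groups < 1:
        raise ValueError("need at least one group")
    if n_groups == 1:
        return np.ones((size, 1)) if size is not None else np.ones(1)
    if size is None:
        return rng.dirichlet(np.ones(n_groups))
    return rng.dirichlet(np.ones(n_groups), size=size)


def allocate_counts(proportions: Sequence[float], total: int) -> np.ndarray:
    """Integer per-group sizes: round(p_g * M) with largest-remainder repair.

    Floors each target, then hands the leftover fish to the groups with the
    largest fractional remainders (ties to the earlier group), so the sizes
    sum exactly to ``total``.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must be non-negative and sum to one")
    target = p * total
    counts = np.floor(target).astype(np.int64)
    short = total - counts.sum()
    if short:
        remainder = target - counts
        order = np.lexsort((np.arange(len(p)), -remainder))
        counts[order[:short]] += 1
    return counts


def _dirichlet_rows(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise Dirichlet draws from a padded weight array (zeros stay zero)."""
    g = rng.standard_gamma(weights)
    s = g.sum(axis=-1, keepdims=True)
    flat = s[..., 0] <= 0
    if flat.any():
        g[flat] = np.where(weights[flat] > 0, 1.0, 0.0)
        s = g.sum(axis=-1, keepdims=True)
    return g / s


def _draw_freqs(
    ancestral: np.ndarray, theta: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """(K, L, J) population frequencies drifted around the ancestral rows."""
    w = np.broadcast_to(theta * ancestral, (n_pops,) + ancestral.shape).copy()
    return _dirichlet_rows(w, rng)


def generate_baseline(
    scenario: SyntheticScenario, level: str, rng: np.random.Generator
) -> SyntheticBaseline:
    """Generate one baseline (``level`` in {'broad', 'regional'}) from the F-model.

    Fish are drawn as whole multilocus genotypes so that individual fish
    exist for leave-out mixture draws; the returned BaselineData aggregates
    them per population.
    """
    if level not in ("broad", "regional"):
        raise ValueError(f"level must be 'broad' or 'regional', got {level!r}")
    sc = scenario
    if level == "broad":
        groups = sc.groups
        pops_per = sc.pops_per_group
        L, theta, prefix, tag = sc.n_broad_loci, sc.theta_broad, "bL", "b"
    else:
        groups = sc.regional_groups
        if not groups:
            raise ValueError("scenario has no regional groups")
        pops_per = sc.regional_pops_per_group
        L, theta, prefix, tag = sc.n_regional_loci, sc.theta_regional, "rL", "r"
    J = sc.n_alleles
    loci = [
        LocusSpec(
            name=f"{prefix}{l + 1:03d}",
            alleles=tuple(f"A{j + 1}" for j in range(J)),
            ploidy=sc.ploidy,
        )
        for l in range(L)
    ]
    ancestral = rng.dirichlet(np.ones(J), size=L)  # (L, J)

    if level == "broad" and sc.theta_group_centers is not None:
        centers = {
            g: _dirichlet_rows(
                np.broadcast_to(sc.theta_group_centers * ancestral, ancestral.shape).copy(),
                rng,
            )
            for g in groups
        }
        if sc.confusable is not None:
            weak, target, w = sc.confusable
            if weak not in centers or target not in centers:
                raise ValueError("confusable groups not in scenario groups")
            blend = w * centers[target] + (1.0 - w) * centers[weak]
            centers[weak] = blend / blend.sum(axis=1, keepdims=True)
    else:
        centers = {g: ancestral for g in groups}

    populations: list[str] = []
    group_of: dict[str, str] = {}
    freq_rows = []
    for g in groups:
        q_g = _draw_freqs(centers[g], theta, pops_per, rng)
        for i in range(pops_per):
            pop = f"{g}_{tag}{i + 1}"
            populations.append(pop)
            group_of[pop] = g
            freq_rows.append(q_g[i])
    freqs = np.stack(freq_rows)  # (K, L, J)
    K = len(populations)

    n = sc.baseline_n
    fish = np.empty((K, n, L, J), dtype=np.int64)
    for k in range(K):
        fish[k] = rng.multinomial(sc.ploidy, freqs[k], size=(n, L))
    counts = fish.sum(axis=1)
    sample_sizes = np.full((K, L), n, dtype=np.int64)
    data = BaselineData(
        loci=loci, populations=populations, counts=counts, sample_sizes=sample_sizes
    )
    return SyntheticBaseline(
        level=level,
        data=data,
        freqs=freqs,
        fish=fish,
        ancestral=ancestral,
        theta=theta,
        group_of=group_of,
    )


def build_region_map(scenario: SyntheticScenario, regional: SyntheticBaseline) -> RegionMap:
    sc = scenario
    broad_group_of = {}
    for g in sc.groups:
        for i in range(sc.pops_per_group):
            broad_group_of[f"{g}_b{i + 1}"] = g
    region_of_group = {g: sc.region_name for g in sc.regional_groups}
    regional_group_of = (
        {sc.region_name: dict(regional.group_of)} if sc.regional_groups else {}
    )
    return RegionMap(
        broad_group_of=broad_group_of,
        region_of_group=region_of_group,
        regional_group_of=regional_group_of,
    )


def simulate_study(scenario: SyntheticScenario, rng: np.random.Generator) -> StudyData:
    """Generate the full study: broad baseline, regional baseline(s), region map."""
    broad = generate_baseline(scenario, "broad", rng)
    regional: dict[str, SyntheticBaseline] = {}
    if scenario.n_regional_groups:
        regional[scenario.region_name] = generate_baseline(scenario, "regional", rng)
        rmap = build_region_map(scenario, regional[scenario.region_name])
    else:
        rmap = build_region_map(scenario, None)  # type: ignore[arg-type]
    return StudyData(scenario=scenario, broad=broad, regional=regional, region_map=rmap)


def _prune(base: SyntheticBaseline, removed: Mapping[int, list[int]]) -> BaselineData:
    """Baseline aggregate after removing the drawn fish from each population."""
    counts = base.fish.sum(axis=1)
    n = np.full(base.data.sample_sizes.shape, base.fish.shape[1], dtype=np.int64)
    for k, idx in removed.items():
        if idx:
            counts[k] -= base.fish[k, idx].sum(axis=0)
            n[k] -= len(idx)
    return BaselineData(
        loci=base.data.loci,
        populations=base.data.populations,
        counts=counts,
        sample_sizes=n,
    )


def synthesize_mixture(
    study: StudyData,
    true_group_props: Sequence[float],
    M: int,
    rng: np.random.Generator,
) -> MixtureSynthesis:
    """Leave-out mixture of ``M`` fish at the given reporting-group proportions.

    Group sizes are round(p_g * M) with largest-remainder correction.  Within
    a group, source populations are chosen uniformly among those with fish
    remaining; drawing more fish than a group's baselines hold is an error.
    Each mixture fish carries genotypes at both marker sets; fish drawn from
    a baseline are removed from the pruned copies returned.
    """
    sc = study.scenario
    rmap = study.region_map
    groups = rmap.combined_group_names
    counts = allocate_counts(true_group_props, M)

    broad = study.broad
    bpop_idx = {p: k for k, p in enumerate(broad.data.populations)}
    broad_avail = {k: list(range(broad.fish.shape[1])) for k in range(broad.data.n_pops)}
    reg_avail = {
        r: {k: list(range(b.fish.shape[1])) for k in range(b.data.n_pops)}
        for r, b in study.regional.items()
    }
    rpop_idx = {
        r: {p: k for k, p in enumerate(b.data.populations)}
        for r, b in study.regional.items()
    }
    ghost_cache: dict[tuple[str, str], np.ndarray] = {}

    def ghost_freqs(bpop: str, region: str) -> np.ndarray:
        key = (bpop, region)
        if key not in ghost_cache:
            rb = study.regional[region]
            ghost_cache[key] = _dirichlet_rows(
                (rb.theta * rb.ancestral).copy(), rng
            )
        return ghost_cache[key]

    def draw_from(avail: dict[int, list[int]], pops: list[int]) -> tuple[int, int]:
        live = [k for k in pops if avail[k]]
        if not live:
            raise ValueError(
                "requested mixture draws exceed available baseline fish"
            )
        k = live[int(rng.integers(len(live)))]
        j = avail[k].pop(int(rng.integers(len(avail[k]))))
        return k, j

    region_of_combined: dict[str, str | None] = {}
    for g in rmap.groups_without_region():
        region_of_combined[g] = None
    for r in rmap.regions:
        for g in rmap.region_groups(r):
            region_of_combined[g] = r

    broad_removed: dict[int, list[int]] = {}
    reg_removed: dict[str, dict[int, list[int]]] = {r: {} for r in study.regional}
    Lb, Jb = broad.data.n_loci, broad.data.max_alleles
    x_broad = np.zeros((M, Lb, Jb), dtype=np.int64)
    x_reg = {
        r: np.zeros((M, b.data.n_loci, b.data.max_alleles), dtype=np.int64)
        for r, b in study.regional.items()
    }
    records = []

    m = 0
    for gi, g in enumerate(groups):
        r_of_g = region_of_combined[g]
        if r_of_g is None:
            broad_pops = [bpop_idx[p] for p in broad.data.populations if broad.group_of[p] == g]
        elif g in set(broad.group_of.values()):
            broad_pops = [bpop_idx[p] for p in broad.data.populations if broad.group_of[p] == g]
        else:
            broad_pops = [
                bpop_idx[p]
                for p in broad.data.populations
                if rmap.region_of_population(p) == r_of_g
            ]
        for _ in range(int(counts[gi])):
            bk, bj = draw_from(broad_avail, broad_pops)
            broad_removed.setdefault(bk, []).append(bj)
            x_broad[m] = broad.fish[bk, bj]
            bpop_name = broad.data.populations[bk]
            rpop_name = ""
            for r, rb in study.regional.items():
                if r == r_of_g:
                    pops_r = [
                        rpop_idx[r][p]
                        for p in rb.data.populations
                        if rb.group_of[p] == g
                    ]
                    rk, rj = draw_from(reg_avail[r], pops_r)
                    reg_removed[r].setdefault(rk, []).append(rj)
                    x_reg[r][m] = rb.fish[rk, rj]
                    rpop_name = rb.data.populations[rk]
                else:
                    q = ghost_freqs(bpop_name, r)
                    x_reg[r][m] = rng.multinomial(sc.ploidy, q)
            records.append(
                {
                    "indiv": "",
                    "group": g,
                    "broad_pop": bpop_name,
                    "regional_pop": rpop_name,
                }
            )
            m += 1

    order = rng.permutation(M)
    names = [f"mix_{i + 1:04d}" for i in range(M)]
    fish_df = pd.DataFrame([records[i] for i in order])
    fish_df["indiv"] = names
    x_broad = x_broad[order]
    for r in x_reg:
        x_reg[r] = x_reg[r][order]

    mix_broad = MixtureData(
        loci=broad.data.loci,
        individuals=names,
        counts=x_broad,
        observed=np.ones((M, Lb), dtype=bool),
    )
    mix_regional = {
        r: MixtureData(
            loci=b.data.loci,
            individuals=names,
            counts=x_reg[r],
            observed=np.ones((M, b.data.n_loci), dtype=bool),
        )
        for r, b in study.regional.items()
    }
    truth = TruthRecord(group_names=list(groups), counts=counts, fish=fish_df)
    return MixtureSynthesis(
        mix_broad=mix_broad,
        mix_regional=mix_regional,
        baseline_broad=_prune(broad, broad_removed),
        baselines_regional={
            r: _prune(b, reg_removed[r]) for r, b in study.regional.items()
        },
        truth=truth,
    )
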