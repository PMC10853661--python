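"""Core containers for multistage genetic stock identification.

Allele-count arrays are padded along the allele axis to the widest locus;
entries beyond a locus's own allele list are structural zeros.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusSpec",
    "BaselineData",
    "MixtureData",
    "RegionMap",
    "PriorSpec",
    "McmcConfig",
    "PosteriorDraws",
    "TruthRecord",
]


@dataclass(frozen=True)
class LocusSpec:
    """A genetic marker: its name, allele registry, and per-individual copy number."""

    name: str
    alleles: tuple[str, ...]
    ploidy: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        if self.ploidy < 1:
            raise ValueError(f"locus {self.name!r}: ploidy must be >= 1")
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r}: needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r}: duplicate allele names")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def max_alleles(loci: Sequence[LocusSpec]) -> int:
    return max(s.n_alleles for s in loci)


def _check_loci_match(a: Sequence[LocusSpec], b: Sequence[LocusSpec]) -> bool:
    return list(a) == list(b)


@dataclass(eq=False)
class BaselineData:
    """Per-population allele counts from reference (baseline) collections.

    ``counts[k, l, j]`` is the number of copies of allele ``j`` at locus ``l``
    observed in population ``k``; ``sample_sizes[k, l]`` is the number of fish
    with a complete genotype at that locus, so each count slice sums to
    ``ploidy_l * sample_sizes[k, l]``.
    """

    loci: list[LocusSpec]
    populations: list[str]
    counts: np.ndarray
    sample_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        self.populations = list(self.populations)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        K, L, J = len(self.populations), len(self.loci), max_alleles(self.loci)
        if len(set(self.populations)) != K:
            raise ValueError("duplicate population names")
        if self.counts.shape != (K, L, J):
            raise ValueError(
                f"counts shape {self.counts.shape} != {(K, L, J)}"
            )
        if self.sample_sizes.shape != (K, L):
            raise ValueError("sample_sizes shape mismatch")
        if (self.counts < 0).any() or (self.sample_sizes < 0).any():
            raise ValueError("negative counts or sample sizes")
        for l, spec in enumerate(self.loci):
            j = spec.n_alleles
            if (self.counts[:, l, j:] != 0).any():
                raise ValueError(f"locus {spec.name!r}: counts beyond allele registry")
            expect = spec.ploidy * self.sample_sizes[:, l]
            got = self.counts[:, l, :j].sum(axis=1)
            if not np.array_equal(got, expect):
                raise ValueError(
                    f"locus {spec.name!r}: allele counts do not sum to "
                    "ploidy * sample size"
                )

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def max_alleles(self) -> int:
        return max_alleles(self.loci)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BaselineData):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.populations == other.populations
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.sample_sizes, other.sample_sizes)
        )


@dataclass(eq=False)
class MixtureData:
    """Unlabelled multilocus genotypes from a mixed-stock sample.

    ``counts[m, l, j]`` are allele copy counts for fish ``m``; ``observed[m, l]``
    is False where the genotype is missing (all counts zero there).
    """

    loci: list[LocusSpec]
    individuals: list[str]
    counts: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        self.individuals = list(self.individuals)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.validate()

    def validate(self) -> None:
        M, L, J = len(self.individuals), len(self.loci), max_alleles(self.loci)
        if len(set(self.individuals)) != M:
            raise ValueError("duplicate individual ids")
        if self.counts.shape != (M, L, J):
            raise ValueError(f"counts shape {self.counts.shape} != {(M, L, J)}")
        if self.observed.shape != (M, L):
            raise ValueError("observed mask shape mismatch")
        for l, spec in enumerate(self.loci):
            j = spec.n_alleles
            if (self.counts[:, l, j:] != 0).any():
                raise ValueError(f"locus {spec.name!r}: counts beyond allele registry")
            sums = self.counts[:, l, :j].sum(axis=1)
            obs = self.observed[:, l]
            if not np.array_equal(sums[obs], np.full(obs.sum(), spec.ploidy)):
                raise ValueError(
                    f"locus {spec.name!r}: observed genotypes must carry "
                    "exactly ploidy allele copies"
                )
            if (sums[~obs] != 0).any():
                raise ValueError(
                    f"locus {spec.name!r}: missing genotypes must have zero counts"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def subset(self, indices: Sequence[int]) -> "MixtureData":
        idx = np.asarray(indices, dtype=int)
        return MixtureData(
            loci=self.loci,
            individuals=[self.individuals[i] for i in idx],
            counts=self.counts[idx],
            observed=self.observed[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MixtureData):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.observed, other.observed)
        )


@dataclass
class RegionMap:
    """Links broad-scale populations to reporting groups and sub-regions.

    ``broad_group_of`` maps each broad-scale population to its reporting
    group; ``region_of_group`` maps a broad group to the sub-region whose
    regional baseline refines it (groups absent from the mapping have no
    regional coverage); ``regional_group_of[region]`` maps each regional
    population to its regional reporting group.  Sub-regions are disjoint:
    a regional population may appear in exactly one region.
    """

    broad_group_of: dict[str, str]
    region_of_group: dict[str, str] = field(default_factory=dict)
    regional_group_of: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.broad_group_of = dict(self.broad_group_of)
        self.region_of_group = {
            g: r for g, r in dict(self.region_of_group).items() if r is not None
        }
        self.regional_group_of = {
            r: dict(m) for r, m in dict(self.regional_group_of).items()
        }
        self.validate()

    def validate(self) -> None:
        broad_groups = set(self.broad_group_of.values())
        for g, r in self.region_of_group.items():
            if g not in broad_groups:
                raise ValueError(f"region mapping refers to unknown broad group {g!r}")
            if r not in self.regional_group_of:
                raise ValueError(
                    f"broad group {g!r} maps to region {r!r} which has no "
                    "regional population block"
                )
        mapped_regions = set(self.region_of_group.values())
        seen_pops: dict[str, str] = {}
        for r, popmap in self.regional_group_of.items():
            if r not in mapped_regions:
                raise ValueError(f"region {r!r} has no broad group mapped to it")
            if not popmap:
                raise ValueError(f"region {r!r} has zero regional populations")
            for pop in popmap:
                if pop in seen_pops:
                    raise ValueError(
                        f"population {pop!r} claimed by regions "
                        f"{seen_pops[pop]!r} and {r!r}; sub-regions must be disjoint"
                    )
                seen_pops[pop] = r

    @property
    def broad_groups(self) -> list[str]:
        return list(dict.fromkeys(self.broad_group_of.values()))

    @property
    def regions(self) -> list[str]:
        return list(self.regional_group_of)

    def groups_without_region(self) -> list[str]:
        return [g for g in self.broad_groups if g not in self.region_of_group]

    def region_groups(self, region: str) -> list[str]:
        return list(dict.fromkeys(self.regional_group_of[region].values()))

    def region_of_population(self, pop: str) -> str | None:
        """Sub-region refining the broad group of ``pop`` (None if uncovered)."""
        return self.region_of_group.get(self.broad_group_of[pop])

    @property
    def combined_group_names(self) -> list[str]:
        names = self.groups_without_region()
        for r in self.regions:
            names.extend(self.region_groups(r))
        if len(set(names)) != len(names):
            raise ValueError("combined reporting-group names are not unique")
        return names


@dataclass
class PriorSpec:
    """Dirichlet prior weights for allele frequencies and stock proportions.

    ``beta`` defaults to 1/J_l per allele at each locus.  ``alpha_mode``
    selects how the unit of prior weight on proportions is spread:
    ``per_group_flat`` gives each reporting group equal weight (split equally
    among its populations), ``per_population_flat`` gives 1/K per population.
    """

    beta: np.ndarray | None = None
    alpha: np.ndarray | None = None
    alpha_mode: str = "per_group_flat"

    def __post_init__(self) -> None:
        if self.alpha_mode not in ("per_group_flat", "per_population_flat"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        if self.beta is not None and (np.asarray(self.beta) <= 0).any():
            raise ValueError("beta weights must be strictly positive")
        if self.alpha is not None and (np.asarray(self.alpha) <= 0).any():
            raise ValueError("alpha weights must be strictly positive")

    def beta_for(self, loci: Sequence[LocusSpec]) -> np.ndarray:
        """Padded (L, Jmax) prior weight array; padding entries are zero."""
        if self.beta is not None:
            return np.asarray(self.beta, dtype=float)
        J = max_alleles(loci)
        out = np.zeros((len(loci), J))
        for l, spec in enumerate(loci):
            out[l, : spec.n_alleles] = 1.0 / spec.n_alleles
        return out

    def alpha_for(
        self, populations: Sequence[str], group_of: Mapping[str, str]
    ) -> np.ndarray:
        """Per-population proportion prior weights, totalling one."""
        if self.alpha is not None:
            a = np.asarray(self.alpha, dtype=float)
            if a.shape != (len(populations),):
                raise ValueError("explicit alpha length does not match populations")
            return a
        K = len(populations)
        if self.alpha_mode == "per_population_flat":
            return np.full(K, 1.0 / K)
        groups = [group_of[p] for p in populations]
        sizes = {g: groups.count(g) for g in set(groups)}
        G = len(sizes)
        return np.array([1.0 / (G * sizes[g]) for g in groups])


@dataclass
class McmcConfig:
    """Gibbs sampler schedule.

    Defaults follow the long production schedule: five independent chains of
    25,000 iterations, the first 15,000 discarded as burn-in, thinned to every
    fifth draw (10,000 retained draws in total).
    """

    n_chains: int = 5
    n_iter: int = 25_000
    n_burn: int = 15_000
    thin: int = 5
    seed: int = 0
    model: str = "conditional"
    record_memberships: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("chains, iterations and thinning must be positive")
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.model not in ("conditional", "fully_bayesian"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    @property
    def total_retained(self) -> int:
        return self.n_chains * self.retained_per_chain

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "McmcConfig":
        """Short evaluation schedule: 5 chains x 5,000, half burn-in, no thinning."""
        kw.setdefault("n_chains", 5)
        kw.setdefault("n_iter", 5_000)
        kw.setdefault("n_burn", 2_500)
        kw.setdefault("thin", 1)
        return cls(seed=seed, **kw)

    def replace(self, **kw) -> "McmcConfig":
        return dataclasses.replace(self, **kw)


@dataclass(eq=False)
class PosteriorDraws:
    """Retained Gibbs draws of combined reporting-group proportions.

    ``draws`` has shape (chains, retained iterations, groups).  When the run
    recorded them, ``pop_draws`` holds broad-scale population proportions and
    ``memberships`` the broad-scale population index assigned to each fish.
    """

    group_names: list[str]
    draws: np.ndarray
    pop_names: list[str] | None = None
    pop_draws: np.ndarray | None = None
    memberships: np.ndarray | None = None
    individuals: list[str] | None = None
    config: McmcConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def stacked(self) -> np.ndarray:
        """All chains concatenated: (chains * retained, groups)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def group(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.group_names.index(name)]

    def mean(self) -> pd.Series:
        return pd.Series(self.stacked().mean(axis=0), index=self.group_names)

    def to_frame(self) -> pd.DataFrame:
        C, T, G = self.draws.shape
        chain = np.repeat(np.arange(C), T * G)
        iteration = np.tile(np.repeat(np.arange(T), G), C)
        group = np.tile(np.asarray(self.group_names, dtype=object), C * T)
        return pd.DataFrame(
            {
                "chain": chain,
                "iteration": iteration,
                "group": group,
                "value": self.draws.ravel(),
            }
        )


@dataclass
class TruthRecord:
    """Realized composition of a synthesized mixture.

    ``counts`` are the per-group fish counts actually drawn, so
    ``proportions`` equal counts / M exactly.  ``fish`` records, per mixture
    individual, its reporting group and source population(s).
    """

    group_names: list[str]
    counts: np.ndarray
    fish: pd.DataFrame

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.group_names)
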