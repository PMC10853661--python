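"""Readers and writers for genotype tables, region maps, summaries and draws.

Genotype files are wide CSVs, one row per fish, with ``ploidy`` columns per
locus named ``<locus>``, ``<locus>.1``, ...  holding allele names; blank cells
mean a missing genotype.  Baseline files carry a ``pop`` column, mixture files
an ``indiv`` column.  Region maps are YAML with three blocks (``broad_groups``,
``regions``, ``regional_groups``); posterior draws are flat CSVs with columns
chain, iteration, group, value; summaries are TSV.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    BaselineData,
    LocusSpec,
    MixtureData,
    PosteriorDraws,
    RegionMap,
    max_alleles,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "align_mixture_to_baseline",
    "read_region_map",
    "write_region_map",
    "read_draws",
    "write_draws",
    "read_summary",
    "write_summary",
]

_REP_SUFFIX = re.compile(r"^(?P<base>.+?)\.(?P<rep>\d+)$")


def _locus_columns(columns: Sequence[str]) -> dict[str, list[str]]:
    """Group genotype columns by locus, preserving file order."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        m = _REP_SUFFIX.match(col)
        base = m.group("base") if m and m.group("base") in groups else col
        groups.setdefault(base, []).append(col)
    return groups


def read_genotypes(path: str | Path, role: str) -> BaselineData | MixtureData:
    """Read a wide genotype CSV as a baseline or mixture table.

    The allele registry of each locus is the sorted union of the alleles seen
    in the file, so repeated loads give bit-identical arrays.  A partially
    filled genotype (one of two diploid cells blank) is a hard error.
    """
    if role not in ("baseline", "mixture"):
        raise ValueError(f"role must be 'baseline' or 'mixture', got {role!r}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    id_col = "pop" if role == "baseline" else "indiv"
    if id_col not in df.columns:
        raise ValueError(f"{path}: missing required column {id_col!r}")
    ids = df[id_col].astype(str).str.strip()
    locus_cols = _locus_columns([c for c in df.columns if c != id_col])
    if not locus_cols:
        raise ValueError(f"{path}: no locus columns found")

    cells: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    for name, cols in locus_cols.items():
        vals = df[cols].to_numpy(dtype=object)
        stripped = np.empty_like(vals)
        for idx in np.ndindex(vals.shape):
            v = vals[idx]
            stripped[idx] = None if (pd.isna(v) or str(v).strip() == "") else str(v).strip()
        cells[name] = stripped
        miss = np.array([[c is None for c in row] for row in stripped], dtype=bool)
        nmiss = miss.sum(axis=1)
        ragged = np.flatnonzero((nmiss > 0) & (nmiss < len(cols)))
        if ragged.size:
            i = int(ragged[0])
            raise ValueError(
                f"{path}: row {i + 2} ({id_col}={ids.iloc[i]!r}) has a partial "
                f"genotype at locus {name!r}"
            )
        missing[name] = nmiss > 0

    loci = []
    for name, cols in locus_cols.items():
        alleles = sorted(
            {c for row in cells[name] for c in row if c is not None}
        )
        if not alleles:
            raise ValueError(f"{path}: locus {name!r} has no observed alleles")
        loci.append(LocusSpec(name=name, alleles=tuple(alleles), ploidy=len(cols)))
    J = max_alleles(loci)
    L = len(loci)
    n_rows = len(df)

    row_counts = np.zeros((n_rows, L, J), dtype=np.int64)
    observed = np.ones((n_rows, L), dtype=bool)
    for l, spec in enumerate(loci):
        a_index = {a: j for j, a in enumerate(spec.alleles)}
        for i, row in enumerate(cells[spec.name]):
            if missing[spec.name][i]:
                observed[i, l] = False
                continue
            for c in row:
                row_counts[i, l, a_index[c]] += 1

    if role == "mixture":
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicated individual id {dup!r}")
        return MixtureData(
            loci=loci, individuals=list(ids), counts=row_counts, observed=observed
        )

    populations = list(pd.unique(ids))
    K = len(populations)
    pop_index = {p: k for k, p in enumerate(populations)}
    counts = np.zeros((K, L, J), dtype=np.int64)
    n = np.zeros((K, L), dtype=np.int64)
    for i, p in enumerate(ids):
        k = pop_index[p]
        counts[k] += row_counts[i]
        n[k] += observed[i]
    return BaselineData(
        loci=loci, populations=populations, counts=counts, sample_sizes=n
    )


def write_genotypes(data: BaselineData | MixtureData, path: str | Path) -> None:
    """Write a genotype table in the wide CSV dialect.

    Baseline rows are reconstructed fish: per locus the allele multiset is
    laid out in registry order across the fish with complete genotypes, which
    preserves counts and sample sizes exactly on re-reading.  Only observed
    alleles are carried on disk, so registry entries with zero counts
    everywhere are not representable.
    """
    loci = data.loci
    header = ["pop" if isinstance(data, BaselineData) else "indiv"]
    for spec in loci:
        header.append(spec.name)
        header.extend(f"{spec.name}.{i}" for i in range(1, spec.ploidy))

    rows: list[list[str]] = []
    if isinstance(data, BaselineData):
        for k, pop in enumerate(data.populations):
            n_pop = int(data.sample_sizes[k].max(initial=0))
            fish_cells = [[pop] for _ in range(n_pop)]
            for l, spec in enumerate(loci):
                seq = list(
                    np.repeat(
                        np.asarray(spec.alleles, dtype=object),
                        data.counts[k, l, : spec.n_alleles],
                    )
                )
                n_kl = int(data.sample_sizes[k, l])
                for i in range(n_pop):
                    if i < n_kl:
                        fish_cells[i].extend(
                            seq[i * spec.ploidy : (i + 1) * spec.ploidy]
                        )
                    else:
                        fish_cells[i].extend([""] * spec.ploidy)
            rows.extend(fish_cells)
    else:
        for m, indiv in enumerate(data.individuals):
            row = [indiv]
            for l, spec in enumerate(loci):
                if data.observed[m, l]:
                    row.extend(
                        np.repeat(
                            np.asarray(spec.alleles, dtype=object),
                            data.counts[m, l, : spec.n_alleles],
                        )
                    )
                else:
                    row.extend([""] * spec.ploidy)
            rows.append(row)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(str(c) for c in row) + "\n")


def align_mixture_to_baseline(
    mix: MixtureData, base: BaselineData, policy: str = "error"
) -> tuple[MixtureData, BaselineData]:
    """Reindex a mixture's allele axes onto a baseline's registry.

    Every baseline locus must be present in the mixture (extra mixture loci
    are dropped).  Mixture alleles absent from the baseline registry are a
    hard error by default; ``policy='extend'`` instead widens the registry
    with zero-count baseline columns that carry only prior mass.

    Returns the aligned (mixture, baseline) pair; the baseline is unchanged
    unless the registry was extended.
    """
    if policy not in ("error", "extend"):
        raise ValueError(f"unknown policy {policy!r}")
    mix_index = {spec.name: l for l, spec in enumerate(mix.loci)}
    missing = [spec.name for spec in base.loci if spec.name not in mix_index]
    if missing:
        raise ValueError(
            "baseline loci missing from mixture: " + ", ".join(missing)
        )

    new_loci: list[LocusSpec] = []
    extended = False
    for spec in base.loci:
        mspec = mix.loci[mix_index[spec.name]]
        if mspec.ploidy != spec.ploidy:
            raise ValueError(f"locus {spec.name!r}: ploidy mismatch")
        ml = mix_index[spec.name]
        extra = [
            a
            for j, a in enumerate(mspec.alleles)
            if a not in spec.alleles and mix.counts[:, ml, j].any()
        ]
        if extra:
            if policy == "error":
                raise ValueError(
                    f"locus {spec.name!r}: mixture allele(s) "
                    f"{', '.join(map(repr, extra))} absent from baseline registry"
                )
            extended = True
            new_loci.append(
                LocusSpec(
                    name=spec.name,
                    alleles=tuple(sorted(set(spec.alleles) | set(extra))),
                    ploidy=spec.ploidy,
                )
            )
        else:
            new_loci.append(spec)

    J = max_alleles(new_loci)
    L = len(new_loci)
    M = mix.n_individuals
    new_counts = np.zeros((M, L, J), dtype=np.int64)
    new_obs = np.zeros((M, L), dtype=bool)
    for l, spec in enumerate(new_loci):
        ml = mix_index[spec.name]
        mspec = mix.loci[ml]
        a_index = {a: j for j, a in enumerate(spec.alleles)}
        for j_old, a in enumerate(mspec.alleles):
            if a in a_index:
                new_counts[:, l, a_index[a]] += mix.counts[:, ml, j_old]
        new_obs[:, l] = mix.observed[:, ml]
    aligned_mix = MixtureData(
        loci=new_loci, individuals=mix.individuals, counts=new_counts, observed=new_obs
    )

    if not extended:
        return aligned_mix, base
    K = base.n_pops
    base_counts = np.zeros((K, L, J), dtype=np.int64)
    for l, (spec, old) in enumerate(zip(new_loci, base.loci)):
        a_index = {a: j for j, a in enumerate(spec.alleles)}
        for j_old, a in enumerate(old.alleles):
            base_counts[:, l, a_index[a]] = base.counts[:, l, j_old]
    new_base = BaselineData(
        loci=new_loci,
        populations=base.populations,
        counts=base_counts,
        sample_sizes=base.sample_sizes,
    )
    return aligned_mix, new_base


def read_region_map(path: str | Path) -> RegionMap:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "broad_groups" not in raw:
        raise ValueError(f"{path}: region map needs a 'broad_groups' block")
    return RegionMap(
        broad_group_of=raw["broad_groups"],
        region_of_group=raw.get("regions") or {},
        regional_group_of=raw.get("regional_groups") or {},
    )


def write_region_map(rmap: RegionMap, path: str | Path) -> None:
    payload = {
        "broad_groups": dict(rmap.broad_group_of),
        "regions": dict(rmap.region_of_group),
        "regional_groups": {r: dict(m) for r, m in rmap.regional_group_of.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_draws(draws: PosteriorDraws, path: str | Path) -> None:
    df = draws.to_frame()
    # shortest round-trip repr keeps draws bit-exact through the CSV
    df["value"] = df["value"].map(repr)
    df.to_csv(path, index=False)


def read_draws(path: str | Path) -> PosteriorDraws:
    df = pd.read_csv(path, float_precision="round_trip")
    groups = list(pd.unique(df["group"]))
    n_chains = df["chain"].nunique()
    n_iters = df["iteration"].nunique()
    gi = {g: i for i, g in enumerate(groups)}
    df = df.assign(_g=df["group"].map(gi)).sort_values(
        ["chain", "iteration", "_g"], kind="stable"
    )
    arr = df["value"].to_numpy().reshape(n_chains, n_iters, len(groups))
    return PosteriorDraws(group_names=groups, draws=arr)


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a population-to-group mapping from YAML.

    Accepts either a bare mapping or a full region-map file (in which case
    the ``broad_groups`` block is used).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "broad_groups" in raw:
        return dict(raw["broad_groups"])
    if isinstance(raw, dict):
        return {str(k): str(v) for k, v in raw.items()}
    raise ValueError(f"{path}: expected a mapping of population to group")
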