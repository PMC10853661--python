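"""Shared builders for small, fully controlled test instances."""
from __future__ import annotations

import numpy as np
import pytest

from msgsi.datatypes import BaselineData, LocusSpec, MixtureData, RegionMap


def make_baseline(counts, populations=None, prefix="L", ploidy=2, alleles=None):
    """BaselineData from a (K, L, J) count array (sample sizes inferred)."""
    counts = np.asarray(counts, dtype=np.int64)
    K, L, J = counts.shape
    alleles = alleles or tuple(f"A{j + 1}" for j in range(J))
    loci = [
        LocusSpec(name=f"{prefix}{l + 1}", alleles=alleles, ploidy=ploidy)
        for l in range(L)
    ]
    n = counts.sum(axis=2) // ploidy
    populations = populations or [f"pop{k + 1}" for k in range(K)]
    return BaselineData(
        loci=loci, populations=populations, counts=counts, sample_sizes=n
    )


def make_mixture(counts, loci, individuals=None, observed=None):
    counts = np.asarray(counts, dtype=np.int64)
    M, L = counts.shape[:2]
    if observed is None:
        observed = counts.sum(axis=2) > 0
    individuals = individuals or [f"f{m + 1}" for m in range(M)]
    return MixtureData(
        loci=loci, individuals=individuals, counts=counts, observed=observed
    )


def tiny_joint_instance(seed, theta=0.5, n=15):
    """Random tiny two-stage instance: 2 broad pops in 2 groups, one region
    with 2 regional pops, one diallelic locus per stage, 2-3 mixture fish.

    Baselines are drawn from the F-model at moderate differentiation, as
    reference baselines in this field are chosen to differentiate stocks.
    """
    rng = np.random.default_rng(seed)

    def mk_base(prefix, npop):
        anc = rng.dirichlet([1.0, 1.0])
        q = rng.dirichlet(theta * anc, size=npop)
        counts = np.zeros((npop, 1, 2), np.int64)
        for k in range(npop):
            counts[k, 0] = rng.multinomial(2 * n, q[k])
        base = make_baseline(
            counts,
            populations=[f"{prefix}{i + 1}" for i in range(npop)],
            prefix=f"{prefix}L",
            alleles=("A", "T"),
        )
        return base, q

    base_b, qb = mk_base("b", 2)
    base_r, qr = mk_base("r", 2)
    M = int(rng.integers(2, 4))

    def mk_mix(base, q):
        x = np.zeros((M, 1, 2), np.int64)
        for m in range(M):
            x[m, 0] = rng.multinomial(2, q[rng.integers(len(q))])
        return make_mixture(x, base.loci)

    rmap = RegionMap(
        broad_group_of={"b1": "GA", "b2": "GB"},
        region_of_group={"GB": "reg"},
        regional_group_of={"reg": {"r1": "GBa", "r2": "GBb"}},
    )
    return mk_mix(base_b, qb), base_b, mk_mix(base_r, qr), base_r, rmap


def diagnostic_study(n_ga=10, n_gba=6, n_gbb=4, baseline_n=20):
    """Perfectly diagnostic two-stage study: every population is fixed for a
    private allele at both marker sets, so assignments are deterministic."""
    # broad: pops a1 (group GA), y1 (group GB, refined by region 'reg')
    base_b = make_baseline(
        np.array([[[2 * baseline_n, 0]], [[0, 2 * baseline_n]]]),
        populations=["a1", "y1"],
        prefix="bL",
        alleles=("A", "T"),
    )
    base_r = make_baseline(
        np.array([[[2 * baseline_n, 0]], [[0, 2 * baseline_n]]]),
        populations=["r1", "r2"],
        prefix="rL",
        alleles=("A", "T"),
    )
    rmap = RegionMap(
        broad_group_of={"a1": "GA", "y1": "GB"},
        region_of_group={"GB": "reg"},
        regional_group_of={"reg": {"r1": "GBa", "r2": "GBb"}},
    )
    M = n_ga + n_gba + n_gbb
    xb = np.zeros((M, 1, 2), np.int64)
    xr = np.zeros((M, 1, 2), np.int64)
    groups = []
    for m in range(M):
        if m < n_ga:
            xb[m, 0] = (2, 0)
            xr[m, 0] = (2, 0)  # ineligible fish; regional genotype unused
            groups.append("GA")
        elif m < n_ga + n_gba:
            xb[m, 0] = (0, 2)
            xr[m, 0] = (2, 0)
            groups.append("GBa")
        else:
            xb[m, 0] = (0, 2)
            xr[m, 0] = (0, 2)
            groups.append("GBb")
    mix_b = make_mixture(xb, base_b.loci)
    mix_r = make_mixture(xr, base_r.loci)
    truth = np.array([n_ga, n_gba, n_gbb]) / M
    return mix_b, base_b, mix_r, base_r, rmap, groups, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20231130)
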