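"""Single-baseline Bayesian stock-identification samplers.

Implements the elemental Gibbs moves shared by both stages of the multistage
model: genotype log-likelihood tables (fully Bayesian product-multinomial or
conditional compound Dirichlet-multinomial), membership draws, proportion
draws, and allele-frequency draws.  ``run_single_gsi`` fits one baseline; it
is the degenerate (no-region) case of the multistage sampler.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .datatypes import (
    BaselineData,
    LocusSpec,
    McmcConfig,
    MixtureData,
    PosteriorDraws,
    PriorSpec,
)

__all__ = [
    "AlleleFreqState",
    "cdm_logpmf",
    "log_genotype_likelihood",
    "sample_memberships",
    "sample_proportions",
    "sample_allele_freqs",
    "run_single_gsi",
    "UnassignableFishError",
]

# Finite stand-in for log(0) in membership weights: small enough that the
# resulting probability underflows to exactly zero after normalization, while
# keeping arithmetic NaN-free.  Rows whose best weight is below _UNASSIGNABLE
# have no population with positive likelihood.
_LOG_ZERO = -1.0e30
_UNASSIGNABLE = -1.0e20


class UnassignableFishError(ValueError):
    """A mixture individual has zero likelihood under every population."""


def cdm_logpmf(
    x: np.ndarray, weights: np.ndarray, include_coeff: bool = True
) -> float:
    """Log pmf of the compound Dirichlet-multinomial at one locus.

    ``x`` are allele copy counts (summing to the ploidy) and ``weights`` the
    Dirichlet weights v = beta + y.  With ``include_coeff=False`` the
    multinomial coefficient is dropped, matching the constant omitted from
    membership weights.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(weights, dtype=float)
    n = x.sum()
    out = (
        gammaln(v.sum())
        - gammaln(v.sum() + n)
        + (gammaln(v + x) - gammaln(v)).sum()
    )
    if include_coeff:
        out += gammaln(n + 1) - gammaln(x + 1).sum()
    return float(out)


@dataclass
class AlleleFreqState:
    """Allele-frequency state of one baseline inside the Gibbs sampler.

    In the fully Bayesian model ``freqs`` holds current frequency draws q
    (updated every sweep); in the conditional model ``weights`` holds the
    fixed posterior weights v = beta + y, computed once and never updated.
    """

    model: str
    freqs: np.ndarray | None = None
    weights: np.ndarray | None = None

    @classmethod
    def conditional(cls, base: BaselineData, beta: np.ndarray) -> "AlleleFreqState":
        return cls(model="conditional", weights=base.counts + beta[None, :, :])

    @classmethod
    def from_prior(
        cls,
        loci: Sequence[LocusSpec],
        n_pops: int,
        beta: np.ndarray,
        rng: np.random.Generator,
    ) -> "AlleleFreqState":
        q = sample_allele_freqs(loci, beta, rng, n_pops=n_pops)
        return cls(model="fully_bayesian", freqs=q)


def log_genotype_likelihood(mix: MixtureData, state: AlleleFreqState) -> np.ndarray:
    """(M, K) table of per-fish, per-population genotype log-likelihoods.

    Computed in the log domain; unobserved loci contribute zero; multinomial
    coefficients are omitted (constant across populations, they cancel in the
    membership normalization).  Conditional model: compound Dirichlet-
    multinomial with weights v and size ploidy.  Fully Bayesian: product
    multinomial in the current q, with zero frequencies giving effectively
    minus-infinite weight where the fish carries that allele.
    """
    loci = mix.loci
    if state.model == "conditional":
        v = state.weights
        K = v.shape[0]
        M = mix.n_individuals
        out = np.zeros((M, K))
        for l, spec in enumerate(loci):
            j = spec.n_alleles
            vl = v[:, l, :j]
            xl = mix.counts[:, l, :j]
            V = vl.sum(axis=1)
            const = gammaln(V) - gammaln(V + spec.ploidy)
            term = (
                gammaln(vl[None, :, :] + xl[:, None, :]) - gammaln(vl[None, :, :])
            ).sum(axis=2)
            out += np.where(mix.observed[:, l, None], term + const[None, :], 0.0)
        return out
    q = state.freqs
    with np.errstate(divide="ignore"):
        logq = np.where(q > 0, np.log(np.clip(q, 1e-320, None)), _LOG_ZERO)
    K = q.shape[0]
    # unobserved loci and padded alleles have x == 0 and thus contribute 0
    return mix.counts.reshape(mix.n_individuals, -1) @ logq.reshape(K, -1).T


def sample_memberships(
    log_lik: np.ndarray,
    p: np.ndarray,
    rng: np.random.Generator,
    individuals: Sequence[str] | None = None,
) -> np.ndarray:
    """Draw one population index per fish from p_k * exp(loglik_mk).

    Uses stable log-sum-exp normalization followed by inverse-CDF sampling.
    A fish whose weights are all (effectively) minus infinity cannot be
    assigned anywhere and raises ``UnassignableFishError``.
    """
    M = log_lik.shape[0]
    if M == 0:
        return np.empty(0, dtype=np.int64)
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.clip(p, 1e-320, None)), _LOG_ZERO)
    W = log_lik + logp[None, :]
    top = W.max(axis=1)
    bad = np.flatnonzero(top < _UNASSIGNABLE)
    if bad.size:
        m = int(bad[0])
        name = individuals[m] if individuals is not None else f"index {m}"
        raise UnassignableFishError(
            f"fish {name} has zero posterior weight for every population "
            "(check marker registries are aligned)"
        )
    P = np.exp(W - top[:, None])
    P /= P.sum(axis=1, keepdims=True)
    u = rng.random((M, 1))
    return (P.cumsum(axis=1) > u).argmax(axis=1)


def sample_proportions(
    counts: np.ndarray, alpha: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet draw of stock proportions given membership counts."""
    return rng.dirichlet(np.asarray(counts, dtype=float) + alpha)


def sample_allele_freqs(
    loci: Sequence[LocusSpec],
    beta: np.ndarray,
    rng: np.random.Generator,
    baseline_counts: np.ndarray | None = None,
    assigned_counts: np.ndarray | None = None,
    n_pops: int | None = None,
) -> np.ndarray:
    """Dirichlet draw of allele frequencies per (population, locus).

    The Dirichlet parameter is beta + baseline counts + allele counts of the
    mixture fish currently assigned to the population; omitting both count
    arrays gives a pure prior draw.  Returns a padded (K, L, Jmax) array with
    zeros beyond each locus's registry.
    """
    if baseline_counts is not None:
        K = baseline_counts.shape[0]
    elif assigned_counts is not None:
        K = assigned_counts.shape[0]
    elif n_pops is not None:
        K = n_pops
    else:
        raise ValueError("cannot infer number of populations")
    L = len(loci)
    J = beta.shape[1]
    q = np.zeros((K, L, J))
    for l, spec in enumerate(loci):
        j = spec.n_alleles
        a = np.broadcast_to(beta[l, :j], (K, j)).astype(float).copy()
        if baseline_counts is not None:
            a += baseline_counts[:, l, :j]
        if assigned_counts is not None:
            a += assigned_counts[:, l, :j]
        g = rng.standard_gamma(a)
        s = g.sum(axis=1, keepdims=True)
        # guard against total underflow at very small weights
        flat = s[:, 0] <= 0
        if flat.any():
            g[flat] = 1.0
            s = g.sum(axis=1, keepdims=True)
        q[:, l, :j] = g / s
    return q


def assigned_allele_counts(
    mix: MixtureData, z: np.ndarray, n_pops: int
) -> np.ndarray:
    """Sum mixture allele counts per population under assignment ``z``."""
    out = np.zeros((n_pops,) + mix.counts.shape[1:], dtype=np.int64)
    np.add.at(out, z, mix.counts)
    return out


def run_single_gsi(
    mix: MixtureData,
    base: BaselineData,
    group_of: Mapping[str, str],
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorDraws:
    """Fit the single-baseline mixture model.

    ``group_of`` maps baseline populations to reporting groups; draws are
    recorded at the reporting-group level (population draws are kept too).
    This is exactly the multistage sampler with zero sub-regions.
    """
    from .multistage import run_msgsi
    from .datatypes import RegionMap

    rmap = RegionMap(broad_group_of=dict(group_of))
    return run_msgsi(mix, base, rmap, prior=prior, mcmc=mcmc)
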