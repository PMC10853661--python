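"""Convergence diagnostics and posterior summaries.

Classic (non-split, non-rank-normalized) Gelman-Rubin potential scale
reduction factor, a multi-chain autocorrelation-based effective sample size
with initial-positive-sequence truncation, and a tabular summary (mean, SD,
equal-tailed 90% credible interval, R-hat, N_eff) per reporting group.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import PosteriorDraws

__all__ = ["gelman_rubin", "effective_size", "summarize"]


def _chain_stats(chains: np.ndarray) -> tuple[float, float, float]:
    """Within-chain variance W, between-chain variance B, pooled var-plus."""
    m, n = chains.shape
    W = float(chains.var(axis=1, ddof=1).mean())
    if m > 1:
        B = float(n * chains.mean(axis=1).var(ddof=1))
    else:
        B = 0.0
    varplus = (n - 1) / n * W + B / n
    return W, B, varplus


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor from >= 2 chains of retained draws.

    Computed from between- and within-chain variances of the post-burn-in,
    thinned draws.  Values below one (a finite-sample artefact) are floored
    at 1.0.  ``split=True`` halves each chain first.
    """
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    if split:
        n2 = x.shape[1] // 2
        x = np.concatenate([x[:, :n2], x[:, n2 : 2 * n2]], axis=0)
    if x.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least two chains")
    if x.shape[1] < 2:
        raise ValueError("need at least two draws per chain")
    W, _, varplus = _chain_stats(x)
    if W == 0.0:
        return 1.0 if varplus == 0.0 else float("inf")
    return max(1.0, float(np.sqrt(varplus / W)))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain for all lags, via FFT."""
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    return acov


def effective_size(chains: np.ndarray) -> float:
    """Effective number of independent draws across chains.

    Combined-chain autocorrelations are summed in Geyer pairs until the
    first negative pair (initial positive sequence); the result is capped at
    the total number of retained draws.  A constant chain has no information
    about autocorrelation and returns NaN with a warning.
    """
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = x.shape
    if n < 4:
        raise ValueError("need at least four draws per chain")
    W, _, varplus = _chain_stats(x)
    if varplus <= 0 or W <= 0:
        warnings.warn("effective size undefined for constant draws", stacklevel=2)
        return float("nan")
    acov = np.stack([_autocov(row) for row in x]).mean(axis=0)
    rho = 1.0 - (W - acov) / varplus
    tau_parts = 0.0
    for t in range(n // 2):
        pair = rho[2 * t] + (rho[2 * t + 1] if 2 * t + 1 < n else 0.0)
        if t > 0 and pair < 0:
            break
        tau_parts += pair
    tau = max(-1.0 + 2.0 * tau_parts, 1e-12)
    return float(min(m * n, m * n / tau))


def summarize(
    draws: PosteriorDraws, truth: dict[str, float] | pd.Series | None = None
) -> pd.DataFrame:
    """Posterior summary table per reporting group.

    Columns: group, [true,] mean, sd, lower/upper 90% equal-tailed credible
    interval (5th/95th percentiles, linear interpolation between order
    statistics), R-hat and N_eff computed from the per-chain retained draws.
    """
    rows = []
    multi = draws.n_chains >= 2
    for g_idx, g in enumerate(draws.group_names):
        per_chain = draws.draws[:, :, g_idx]
        flat = per_chain.ravel()
        sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
        lo, hi = np.percentile(flat, [5.0, 95.0])
        constant = sd == 0.0
        if constant:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                neff = float("nan")
            rhat = 1.0 if multi else float("nan")
        else:
            rhat = gelman_rubin(per_chain) if multi else float("nan")
            neff = effective_size(per_chain)
        row = {"group": g}
        if truth is not None:
            row["true"] = float(truth[g])
        row.update(
            {
                "mean": float(flat.mean()),
                "sd": sd,
                "lower_90": float(lo),
                "upper_90": float(hi),
                "rhat": rhat,
                "n_eff": neff,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
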