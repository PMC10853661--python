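"""Repeated cross-validation evaluation: RMSE, bias, and percent deviation.

Each replicate draws fresh random true proportions, synthesizes a leave-out
mixture, and fits the requested methods on identical data (a paired design,
so method differences are not confounded by simulation noise).  Only
posterior means are compared with the truth.  Per-group adequacy follows the
standard baseline-evaluation guidelines: estimates within +/-0.1 of truth at
least 90% of the time, |bias| <= 0.05, RMSE <= 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import McmcConfig, PriorSpec
from .multistage import run_msgsi
from .simulate import (
    SyntheticScenario,
    random_true_proportions,
    simulate_study,
    synthesize_mixture,
)
from .two_step import run_hc2step

__all__ = [
    "rmse",
    "bias",
    "pct_deviation",
    "EvaluationResult",
    "run_repeated_cv",
    "GUIDELINE_WITHIN_PCT",
    "GUIDELINE_BIAS",
    "GUIDELINE_RMSE",
]

GUIDELINE_WITHIN_PCT = 90.0
GUIDELINE_BIAS = 0.05
GUIDELINE_RMSE = 0.05


def rmse(truths: Sequence[float], estimates: Sequence[float]) -> float:
    """Root-mean-square error of mean estimates against true values."""
    y = np.asarray(truths, dtype=float)
    yhat = np.asarray(estimates, dtype=float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def bias(truths: Sequence[float], estimates: Sequence[float]) -> float:
    """Mean of mean estimates minus mean of true values."""
    return float(np.mean(estimates) - np.mean(truths))


def pct_deviation(
    truths: Sequence[float], estimates: Sequence[float], tol: float = 0.1
) -> float:
    """Percent of replicates whose estimate deviates strictly more than ``tol``."""
    y = np.asarray(truths, dtype=float)
    yhat = np.asarray(estimates, dtype=float)
    return float(100.0 * np.mean(np.abs(yhat - y) > tol))


@dataclass
class EvaluationResult:
    """Per-group, per-method metrics over replicate cross-validation analyses."""

    group_names: list[str]
    methods: list[str]
    truths: np.ndarray  # (n_reps, G)
    estimates: dict[str, np.ndarray]  # method -> (n_reps, G)
    metrics: pd.DataFrame
    n_reps: int

    def method_metrics(self, method: str) -> pd.DataFrame:
        return self.metrics[self.metrics["method"] == method].set_index("group")


def _metrics_table(
    group_names: list[str],
    truths: np.ndarray,
    estimates: dict[str, np.ndarray],
) -> pd.DataFrame:
    rows = []
    for method, est in estimates.items():
        for g_idx, g in enumerate(group_names):
            y, yhat = truths[:, g_idx], est[:, g_idx]
            r, b, d = rmse(y, yhat), bias(y, yhat), pct_deviation(y, yhat)
            rows.append(
                {
                    "group": g,
                    "method": method,
                    "rmse": r,
                    "bias": b,
                    "pct_deviation": d,
                    "pct_within": 100.0 - d,
                    "meets_guidelines": (
                        (100.0 - d) >= GUIDELINE_WITHIN_PCT
                        and abs(b) <= GUIDELINE_BIAS
                        and r <= GUIDELINE_RMSE
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_repeated_cv(
    scenario: SyntheticScenario,
    methods: Sequence[str] = ("msgsi", "hc2step"),
    n_reps: int = 50,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
    prior: PriorSpec | None = None,
    threshold: float = 0.8,
    rescale: str = "stage1_mean",
    progress=None,
) -> EvaluationResult:
    """Repeat the cross-validation analysis ``n_reps`` times.

    Each replicate uses randomly chosen group proportions (flat Dirichlet,
    unless the scenario pins them), a freshly generated study, and a new
    leave-out mixture; every requested method is fit on the identical data.
    The default sampler schedule is the short evaluation one (five chains of
    5,000 iterations, half burn-in, no thinning) since only posterior means
    are compared.  The same master seed reproduces the result bit-identically.
    """
    methods = list(methods)
    unknown = [m for m in methods if m not in ("msgsi", "hc2step")]
    if unknown:
        raise ValueError(f"unknown method(s): {unknown}")
    mcmc = mcmc or McmcConfig.reduced()
    prior = prior or PriorSpec()
    children = np.random.SeedSequence(seed).spawn(n_reps)

    truths = []
    estimates: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    group_names: list[str] | None = None
    for i, child in enumerate(children):
        sub = child.spawn(1 + len(methods))
        rng = np.random.default_rng(sub[0])
        try:
            study = simulate_study(scenario, rng)
            groups = study.region_map.combined_group_names
            if scenario.true_group_proportions is not None:
                p_true = np.asarray(scenario.true_group_proportions, dtype=float)
            else:
                p_true = random_true_proportions(len(groups), rng)
            synth = synthesize_mixture(study, p_true, scenario.mixture_size, rng)
            if group_names is None:
                group_names = groups
            truths.append(synth.truth.proportions)
            for j, method in enumerate(methods):
                fit_seed = int(sub[1 + j].generate_state(1)[0] % np.int64(2**31))
                cfg = replace(mcmc, seed=fit_seed)
                if method == "msgsi":
                    fit = run_msgsi(
                        synth.mix_broad,
                        synth.baseline_broad,
                        study.region_map,
                        regional_bases=synth.baselines_regional,
                        mix_regional=synth.mix_regional,
                        prior=prior,
                        mcmc=cfg,
                    )
                    means = fit.mean()
                else:
                    fit = run_hc2step(
                        synth.mix_broad,
                        synth.baseline_broad,
                        study.region_map,
                        regional_bases=synth.baselines_regional,
                        mix_regional=synth.mix_regional,
                        prior=prior,
                        mcmc=cfg,
                        threshold=threshold,
                        rescale=rescale,
                    ).draws.mean()
                    means = fit
                estimates[method].append(means.reindex(groups).to_numpy())
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"replicate {i} (master seed {seed}) failed: {exc}"
            ) from exc
        if progress is not None:
            progress(i + 1, n_reps)

    truths_arr = np.asarray(truths)
    est_arr = {m: np.asarray(v) for m, v in estimates.items()}
    return EvaluationResult(
        group_names=list(group_names or []),
        methods=methods,
        truths=truths_arr,
        estimates=est_arr,
        metrics=_metrics_table(list(group_names or []), truths_arr, est_arr),
        n_reps=n_reps,
    )
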