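# msgsi — integrated multistage genetic stock identification

`msgsi` estimates the stock composition of a mixed-stock sample (for
example, a Chinook salmon fishery catch spanning coastal and river
populations) by Bayesian genetic stock identification (GSI), for fishery
scientists and population geneticists who maintain genetic baselines at
more than one geographic scale.

Regional baselines resolve local reporting groups with large marker panels,
but broad-scale baselines that cover a whole fishery usually carry far fewer
shared markers and cannot separate fine-scale groups.  The conventional
workaround — assign each fish to a broad-scale group, keep the fish whose
assignment probability exceeds a hard cut-off (typically 0.8), and run a
second, independent GSI against the regional baseline — discards
hard-to-assign fish and ignores first-stage uncertainty, biasing regional
estimates.  `msgsi` instead stacks the two mixture models inside one Gibbs
sampler so the stages share every sweep and errors propagate, even when the
two baselines share no markers and no populations.

## Model

For a baseline of `K` populations genotyped at `L` loci, baseline allele
counts follow `y_k ~ Mult(n_k, q_k)` with a Dirichlet prior
`q_{k,l} ~ Dir(β)`, `β = 1/J_l`.  Mixture fish carry latent memberships
`z_m ~ Mult(1, p)` with `p ~ Dir(α)`, and genotypes
`x_m ~ Mult(ploidy, z_m ∘ q)`.  In the default *conditional* variant `q` is
integrated out, giving a compound Dirichlet-multinomial genotype likelihood
with fixed weights `v = β + y` that mixture fish never update; the *fully
Bayesian* (Pella-Masuda) variant samples `q` alongside.

The multistage model adds, for each of `R` disjoint sub-regions `r`, a
second mixture model over the `K^(r)` regional-baseline populations.  The
stages are linked one-directionally: a fish draws a regional membership
`z^(r)_m ~ Mult(1, p^(r))` only in the sweep iterations where its current
broad-scale membership falls in that sub-region's broad populations `B_r`;
otherwise `z^(r)_m = 0`.  Each retained iteration records the combined
vector: broad groups without regional coverage at their summed population
proportions, and every regional group at `p^(r)_g · Σ_{b∈B_r} p_b`, which
sums to one and carries the uncertainty of both stages.

The package also implements the hard cut-off two-step comparator
(`run_hc2step`), classic Gelman-Rubin R̂ and autocorrelation-based effective
sample size, an F-model synthetic-data generator with leave-out mixtures,
and a repeated cross-validation harness reporting RMSE, bias, and the
percentage of estimates deviating more than ±0.1 from truth.

## Worked example

Five reporting groups, the last four refined by one regional baseline
(30 broad-scale and 40 regional SNPs, 50 baseline fish per population);
a 205-fish mixture drawn at known proportions by leave-out; production
schedule of five chains × 25,000 iterations (15,000 burn-in, thin 5):

```python
import numpy as np
from msgsi import (McmcConfig, SyntheticScenario, run_msgsi,
                   simulate_study, summarize, synthesize_mixture)

scenario = SyntheticScenario(n_broad_loci=30, n_regional_loci=40, seed=42)
rng = np.random.default_rng(scenario.seed)
study = simulate_study(scenario, rng)
truth = np.array([0.27, 0.10, 0.19, 0.13, 0.31])
synth = synthesize_mixture(study, truth, scenario.mixture_size, rng)
fit = run_msgsi(
    synth.mix_broad, synth.baseline_broad, study.region_map,
    regional_bases=synth.baselines_regional, mix_regional=synth.mix_regional,
    mcmc=McmcConfig(seed=7),
)
print(summarize(fit, truth=synth.truth.as_series()).round(3).to_string(index=False))
```

```text
group  true  mean    sd  lower_90  upper_90  rhat    n_eff
   G1 0.268 0.270 0.031     0.221     0.322   1.0 9282.434
   G2 0.098 0.097 0.021     0.066     0.133   1.0 9967.493
   G3 0.190 0.191 0.027     0.148     0.238   1.0 8634.284
   G4 0.132 0.133 0.024     0.096     0.173   1.0 9693.644
   G5 0.312 0.309 0.032     0.258     0.362   1.0 9946.961
```

`true` is the realized mixture composition (G1 is the non-regional coastal
group; G2–G5 are regional groups reported through the second stage), `mean`
/ `sd` / the 90% equal-tailed credible interval summarize the combined
posterior, and R̂ ≈ 1 with N_eff near the 10,000-draw cap indicates
well-mixed chains.  Every posterior mean lands within 0.003 of the truth.

The same fits are available from the shell: `msgsi simulate`,
`msgsi fit-single`, `msgsi fit-msgsi`, `msgsi fit-hc2step`,
`msgsi evaluate`, and `msgsi summarize` (see `msgsi --help`); each run
writes its draws, summary table, and an echo of the resolved configuration
beside its outputs.

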