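# Methods

## The two single-baseline samplers

Both stages reuse one building block: a Bayesian mixture model over the `K`
populations of a baseline.  Baseline allele counts are multinomial in the
latent population frequencies, `y_k ~ Mult(n_k, q_k)`, with conjugate prior
`q_{k,l} ~ Dir(β_l)` and `β_{l,j} = 1/J_l`.  Mixture memberships are
`z_m ~ Mult(1, p)`, `p ~ Dir(α)`, and mixture genotypes
`x_m ~ Mult(ploidy_l, z_m ∘ q)` per locus.

The Gibbs sweep draws, in order: memberships from
`w_{m,k} ∝ p_k · Π_l Π_j q_{k,l,j}^{x_{m,l,j}}`, then proportions from
`p | z ~ Dir(Σ_m z_m + α)`, and (fully Bayesian variant only) frequencies
from `q_{k,l} | · ~ Dir(Σ_m x_{m,l} z_{m,k} + y_{k,l} + β_l)`.  The default
*conditional* variant integrates `q` out instead: the genotype likelihood
becomes a compound Dirichlet-multinomial with weights `v = β + y`, computed
once per run and never updated by mixture fish.  All likelihood tables are
computed in the log domain with multinomial coefficients dropped (constant
across populations, they cancel in the membership normalization); the
conditional model precomputes the full `M × K` table exactly once.

### Proportion priors

`α` carries total weight one.  Two spreadings are provided:

* `per_group_flat` (default): each reporting group receives weight `1/G`,
  split equally among its populations — a flat prior over reporting groups,
  which is the quantity actually reported.
* `per_population_flat`: `α_k = 1/K`.

Regional priors are normalized within each sub-region (total weight one per
region), so the pure-prior draw taken when no fish is currently eligible is
proper.

## The integrated multistage sampler

Let the broad-scale baseline have populations `b = 1..B`, partitioned by a
region map into `B*` (no regional coverage) and `B_r` for each of `R`
disjoint sub-regions, each sub-region carrying its own baseline with
populations `k = 1..K^(r)` and an arbitrary, possibly disjoint marker set.
Every mixture fish is genotyped (with missingness allowed) at every
baseline's markers.

Each sweep: (1) draw broad memberships `z` for all fish; (2) per sub-region,
recompute eligibility — fish `m` is eligible for `r` iff its current broad
population lies in `B_r` — and draw `z^(r)` for eligible fish from
`w^(r)_{m,k} ∝ p^(r)_k · (regional genotype likelihood)`; ineligible fish
carry the all-zero regional indicator, recomputed from scratch every sweep
(statelessness avoids stale assignments when eligibility flips); (3) draw
`p | z` and, per region, `p^(r) | z^(r)` from their Dirichlet full
conditionals (and the `q`'s in the fully Bayesian variant, regional `q^(r)`
using eligible fish only).  Each retained iteration records the combined
vector: non-regional groups at their summed broad proportions, regional
groups at `p^(r)_g · Σ_{b∈B_r} p_b`.  The combined vector is a simplex by
construction and its spread reflects both stages' uncertainty.

### What the sampler targets

The stage linkage is deliberately one-directional: the broad-stage
membership weights contain no regional term, so regional genotypes never
inform broad-scale assignment.  (A fully joint model would need a genotype
distribution at regional markers for fish outside every sub-region, which
the framework does not posit.)  The idealized target is therefore a nested
("cut") posterior — the broad-scale posterior, with the regional posterior
conditioned on the broad configuration.  One subtlety is worth recording:
because the regional stage reuses the previous sweep's `p^(r)` while
eligibility follows the current broad draw, the chain equilibrates to that
nested target only to the extent that eligible sets are stable across
sweeps.  With baselines informative enough to be useful for assignment,
eligibility is nearly constant per fish and the tiny-instance enumeration
checks in the test suite agree with the sampler within Monte Carlo error;
with deliberately uninformative single-marker baselines a small residual
offset (order 0.01) can be resolved.  This mirrors how the procedure is
defined operationally — stage two is conditioned on stage one within each
sweep — rather than as the exact posterior of one joint generative model.

### Chains, initialization, seeding

Five independent chains by default, 25,000 iterations each, the first
15,000 discarded and the rest thinned to every fifth draw (10,000 retained
draws total); the short evaluation schedule is 5 × 5,000 with half burn-in
and no thinning, adequate when only posterior means are consumed.  Each
chain initializes `p`, `p^(r)` (and `q`'s) from their priors.  Per-chain
random streams are spawned children of the master seed
(`SeedSequence(seed).spawn(n_chains)`), so adding chains never perturbs
earlier chains' draws and every run is bit-reproducible.

A fish whose membership weights are all zero (possible only with
pathological frequency inputs or misaligned registries) raises an error
naming the fish rather than being silently dropped, since silent dropping
would bias `p`.

## Hard cut-off two-step comparator

Step one fits the broad baseline alone and computes each fish's posterior
probability of membership in each sub-region (the fraction of retained
draws whose membership falls in `B_r`).  Fish with probability strictly
greater than the threshold τ (default 0.8; a fish at exactly τ is excluded)
enter step two, an independent fit of the regional baseline restricted to
the selected fish; an empty selection degrades to a prior-only regional
report with a warning.  The combined report keeps non-regional groups at
their step-one posterior and multiplies step-two draws by a *fixed*
constant per region — by default the step-one posterior mean of
`Σ_{b∈B_r} p_b`, optionally the selected-fish fraction.  The fixed rescale
is the point: combined intervals deliberately omit step-one uncertainty,
reproducing the known deficiency of the two-step procedure.  With the
default rescale the combined means form a simplex exactly.

## Synthetic data generator

The generator emulates the structure of a two-baseline study — a
low-resolution broad-scale baseline over all reporting groups and one
high-resolution regional baseline refining a subset of them — so that every
sampler and the evaluation harness run without external data.

* **F-model differentiation.**  Per locus an ancestral frequency vector is
  drawn flat-Dirichlet; population frequencies drift around it as
  `q_k ~ Dir(θ · ancestral)`.  Smaller θ means stronger drift and more
  informative markers; θ = 0.3 with diallelic loci gives near-diagnostic
  panels, θ ≈ 10 nearly exchangeable populations.  This matches the mixture
  model's own Dirichlet-multinomial assumptions, so simulation truth and
  model family coincide.  An optional two-level variant draws per-group
  centers first (`θ_centers` between groups, θ within), and a `confusable`
  setting blends one regional group's broad-marker center toward the
  non-regional group — the regime in which hard cut-off selection loses
  fish and the integrated sampler shows its advantage.
* **Default shape** (desk scale): five reporting groups, the last four
  refined by a single sub-region; four populations per group at both
  levels; 10 broad and 40 regional diallelic loci with disjoint marker
  sets; 50 baseline fish per population; mixtures of 205 fish.  The engine
  itself supports any number of disjoint sub-regions; the generator emits
  one, the configuration the comparator study exercises.
* **Leave-out mixtures.**  Per-group sizes are `round(p_g · M)` with
  largest-remainder correction (sizes sum exactly to `M`; the recorded
  truth equals realized counts / M).  Within a group, source populations
  are drawn uniformly among those with fish remaining.  A mixture fish from
  a regional group is assembled from one broad-baseline fish and one
  regional-baseline fish of that group (the two marker sets are disjoint
  and genotypes are independent across loci given the population, so the
  stitched fish is distributed exactly as the model assumes); both source
  fish are removed from the pruned baselines returned.  Fish from
  non-regional groups have no source population in any regional baseline;
  their regional-marker genotypes are simulated from per-population "ghost"
  frequencies drawn from the same F-model around the regional ancestral
  vector.
* **Not modeled:** linkage disequilibrium, null alleles, genotyping error,
  within-group population structure beyond the F-model, and real-world
  features such as shared markers between baselines or unequal per-group
  population counts.  Passing tests therefore demonstrate correctness of
  the samplers under the model's own assumptions and realistic information
  levels — not robustness to marker-model violations in field data.

## Diagnostics and summaries

* **R̂**: classic (non-split, non-rank-normalized) potential scale
  reduction factor from between/within-chain variances of the retained
  draws; values below one, a finite-sample artefact, are floored at 1.0;
  a `split=True` option halves chains first.
* **N_eff**: multi-chain autocorrelation estimator — combined-chain
  autocorrelations from per-chain FFT autocovariances, summed in Geyer
  pairs to the first negative pair — capped at the total retained draws.
  A constant chain returns NaN with a warning.
* **Summaries**: posterior mean, SD, and the equal-tailed 90% credible
  interval from the 5th/95th percentiles with linear interpolation between
  order statistics (numpy's default convention; pinned by a grid test).

## Evaluation harness

`run_repeated_cv` repeats the cross-validation analysis (default 50
replicates): each replicate draws fresh flat-Dirichlet true proportions,
generates a new study, synthesizes a leave-out mixture, and fits every
requested method on identical data — a paired design, so method contrasts
are not confounded by simulation noise.  Only posterior means enter the
metrics: per group, `RMSE = sqrt(mean((Y_i − Ŷ_i)²))`, bias = mean of
estimates minus mean of truths, and percent deviation = the share of
replicates with `|Ŷ_i − Y_i|` strictly above 0.1.  Per-group adequacy
follows the standard baseline-evaluation guidelines: within ±0.1 at least
90% of the time, |bias| ≤ 0.05, RMSE ≤ 0.05.  The acceptance script runs
this experiment at 50 replicates on the informative design (30/40 loci,
θ = 0.3, baseline n = 50, M = 205) with the short schedule; the paired
comparison test uses 20 replicates of the confusable design at 4 × 2,000
sweeps, sufficient for mean-level contrasts.

## Numerical conventions and edge cases

* Likelihoods in the log domain; `log 0` is represented by a finite
  sentinel (−10³⁰) so arithmetic stays NaN-free while underflowing to
  exactly zero probability after normalization; a fish whose best weight is
  below −10²⁰ is treated as unassignable (hard error).
* Membership draws use stable softmax plus inverse-CDF sampling; Dirichlet
  draws guard against total gamma underflow at very small weights.
* Allele-count arrays are padded to the widest locus; padded entries are
  structural zeros excluded from every likelihood and Dirichlet update.
* Genotype CSVs carry only observed alleles, so a registry allele with zero
  observed copies everywhere is not representable on disk; within a run the
  registry is preserved.  Allele order is sorted, population order is file
  order, making repeated loads bit-identical.
* Mixture alleles absent from a baseline registry are a hard error by
  default (`policy="extend"` opts into zero-count registry extension where
  the new allele carries only prior mass β).

## Known limitations

* No bootstrap correction for reporting-unit bias (unequal numbers of
  poorly resolved populations per group); the framework inherits that bias.
* Regional genotypes of fish from outside a sub-region are not modeled by
  the sampler (and only ghost-simulated by the generator), which is what
  forces the one-directional stage linkage discussed above.
* No support for genotype likelihoods, VCF input, or microsatellite
  mobility binning; genotypes are hard calls in wide CSV.
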