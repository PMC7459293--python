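# Methods

## The estimand and the mixing model

The quantity of interest is each consumer's diet-proportion vector
**p** over K ≥ 2 basal carbon sources — in the motivating two-source
setting, the fraction of assimilated carbon traceable to algal biofilm
(the complement being the leaf-litter/phytoplankton pathway). "Diet" here
is shorthand: strictly, it is the proportion of muscle-tissue carbon
originating from each basal pathway, integrated over tissue turnover.

Proportions live on the simplex, so covariates act through the isometric
log-ratio (ILR) transform. We use the orthonormal Helmert-style basis in
source input order; for K = 2 the single coordinate is
z = (1/√2)·ln(p₁/p₂). Because ILR coordinates (unlike the proportions
themselves) depend on the basis, outputs record the source order. The
linear model on the ILR scale is

    ilr(p_i) = intercept + species[i] + site[i] + β · z_length_i

with species and site effects drawn from zero-mean Normals with free
scales σ_species, σ_site, and z_length the standardized body length.

The Gaussian likelihood for tracer j of consumer i has moments

    mean_ij = Σ_k p_ik (μ_jk + λ_j)
    var_ij  = Σ_k p_ik² (ω_jk² + τ_j²) + σ_j²

where (μ_jk, ω_jk) are the source-j-by-k mean/SD summaries, (λ_j, τ_j)
the guild's trophic enrichment factor (TEF), and σ_j a per-tracer residual
SD. This is the "process + residual" error structure: source and TEF
variability enter scaled by squared proportions (each consumer assimilates
its own realization of each source, with an independent TEF realization
per source), and the residual term absorbs unexplained consumer-level
variance. Tracers are conditionally independent given p. Sources enter as
summaries (mean/SD/n), not as raw samples fitted hierarchically inside the
model; measurement error of the mass spectrometer (~0.1‰) is far below
the process SDs and gets no separate term.

### Assumptions worth stating

- Two-source identifiability rests on the sources being well separated in
  at least one tracer; a guard warns when no source pair is ≥ 0.5 combined
  SDs apart (the practical remedy — pooling overlapping sources — lives in
  the preprocessing module as an explicit, user-driven step).
- Length is centred *within species* and scaled by one pooled
  within-species SD: length is allowed to shift diet within a species but
  carries no information across species, and the single scale makes the
  coefficient shared and comparable. The z-scores are computed once per
  guild × habitat analysis, so every lattice member sees identical inputs.
- Mixing is not concentration-dependent (elemental concentrations are
  assumed equal across sources).

## Priors

"Uninformative" is realized as proper and weakly informative:
intercept and β ~ Normal(0, 5) per ILR coordinate (≈ flat on p for K = 2),
random-effect scales ~ half-Normal(0, 2) on the ILR scale, residual SDs ~
half-Normal(0, 5 ‰). All four scales are exposed in `PriorConfig` for
sensitivity analysis.

## Preprocessing

- **Lipid correction**: fish-muscle δ¹³C with C:N > 3.5 is corrected by
  +6 − 22.2/C:N (the correction crosses zero at C:N = 22.2/6 = 3.7, so it
  is continuous at its activation range); corrected records are flagged
  and the correction is applied per record before any summarization.
- **Source pooling** concatenates raw samples, so the pooled summary is
  the combined-sample mean/SD with the combined n. The overlap diagnostic
  (Pearson correlation of the two sources' implied normal densities on a
  shared grid, flagged at 0.8 by default) is advisory only, since
  "overlap" has no single canonical statistic.
- Sample SDs use the n−1 denominator throughout.

## Sampling

The posterior is explored by an adaptive random-walk Metropolis,
vectorised across chains (default 3). Design choices, in the order they
mattered:

1. **Laplace initialization.** A bounded L-BFGS-B finds the posterior
   mode; scale coordinates are bounded below (σ ≥ 0.05 for random-effect
   scales) because the centered hierarchical density is unbounded along
   σ → 0 with all effects → 0 — an integrable spike of negligible mass
   that traps unconstrained optimizers. The inverse Hessian (central
   differences, eigenvalues clipped to per-direction variances in
   [10⁻⁶, 25]) seeds both the chain starting points (mode + overdispersed
   jitter) and the proposal covariance.
2. **Joint adaptive move.** Classic Haario-style: per-chain empirical
   covariance and a step scale tuned toward 23% acceptance, adapted only
   during burn-in and frozen afterwards so retained draws form a
   time-homogeneous Markov chain.
3. **Recentering move.** The intercept and the mean of a random-effect
   block are only weakly identified relative to each other (the
   likelihood constrains their sums). A dedicated Metropolis move shifts
   δ onto the intercept and −δ onto every effect of the block; the
   likelihood is exactly invariant, so the acceptance ratio is a
   two-term prior ratio and the move costs nothing. Without it,
   split-chain R̂ on these models reached 10–30 at test scale.
4. **Scale slice update.** Each random-effect scale is re-drawn by
   univariate slice sampling from its conditional given the effects,
   which involves no likelihood evaluation.

MCMC presets: "test" = 3 chains × 4,000 retained draws after 2,000
burn-in (used by the test suite and all replicate studies below);
"full" = 200,000 total iterations with 50,000 burn-in for production
runs. Convergence is judged by the classic split-chain Gelman–Rubin
statistic with the < 1.01 bar; runs that miss the bar are flagged in the
result and the run manifest, not aborted. The rank-normalized variant
(via arviz) is available as an option, but it is *not* the default: it
saturates near 1.8 for two fully separated chains, so its magnitude is
uninformative exactly where a diagnostic should scream; the classic
statistic grows without bound there. At test scale the heavier
random-effect models typically sit at R̂ ≈ 1.05–2; the replicate studies
below show the posterior summaries are nonetheless accurate at that
scale, and the "full" preset exists for final inference.

## Model comparison and averaging

All admissible subsets of {site, species, length} form the lattice (8
models; species-flag members are dropped for single-species groups and
site-flag members for single-site groups, with a note). Each fit stores
per-consumer pointwise log-likelihood draws; PSIS-LOO (via arviz) gives
elpd_loo, LOOic = −2·elpd_loo, and Pareto-k diagnostics. Weights are
Akaike-style on LOOic, w ∝ exp(−ΔLOOic/2) (computed via log-sum-exp);
stacking weights were considered and rejected as the default because the
weight table is meant to read as "probability this model predicts best".
Consumers with Pareto-k > 0.7 are flagged; above a 10% fraction the
result recommends the exact-refit LOO path (`exact_refit_loo`, n refits,
provided at cost). Note that LOO here conditions on the random effects
(the pointwise likelihood is conditional, as in the mixSIAR-style
workflow); on null data this makes the elpd differences between nested
models essentially zero, so the weights are close to uniform and which
model "wins" a single replicate is noise — medians over replicates are
the stable summary.

Model averaging resamples draws from each model's posterior with
multinomial counts proportional to the weights (a mixture of posterior
distributions, not an average of quantiles). Per-species diet summaries
report the mean and the 50%/95% central credible intervals of the
first-source proportion for a typical individual (species effect
included, site effect 0, z = 0). The length effect is reported on two
clearly labelled scales — the ILR coefficient, and the change in
first-source proportion from z = −1 to z = +1 at the intercept — because
the effect's natural scale is ambiguous in field reporting; models
without the length term contribute zeros to the averaged effect. An
effect is called "significant" when its 95% credible interval excludes
zero.

## The synthetic-data generator

`SimDesign` defaults encode the study conditions: the two main-channel
source summaries (algal biofilm −23.3 ± 2.42 δ¹³C / 1.77 ± 1.48 δ¹⁵N,
n = 4; pooled CPOM + fine seston −31.1 ± 1.07 / 2.73 ± 1.80, n = 8), the
omnivore TEF (0.6 ± 1.3 δ¹³C, 4.8 ± 1.7 δ¹⁵N), 10 species × 15
consumers across 3 sites, true global algal proportion 0.70,
σ_species = 0.3 and β_length = 0.5 on the ILR scale, σ_site = 0 (the
default dataset is generated from the species + length model), residual
SD 0.5 ‰ per tracer, and lengths ~ Normal(120, 40) mm truncated at 1 mm.
Noise is mechanistic — per-consumer source and TEF realizations, mixed by
the true proportions, plus residual noise — not a draw from the collapsed
likelihood, so generator-vs-likelihood moment agreement is a genuine
test. Identical seeds give byte-identical CSVs. The generator emulates
the statistical structure only: no tissue-turnover dynamics, no
growth-dilution of isotope signals, no C:N/lipid structure (records carry
no C:N by default), and no spatial correlation beyond the site effect —
so passing tests say the *inference machinery* works under the assumed
structure, not that the assumed structure matches any particular river.

## Residency analysis

δ³⁴S bands are closed intervals with configurable edges, defaulting to
freshwater [−8, 8] ‰ and marine [13, 18] ‰; values between the bands are
"intermediate", values outside the outer edges map to the nearest extreme
with an out-of-band note. Group comparisons use the Kruskal–Wallis
rank-sum test (scipy), with mid-ranks and the standard tie correction —
tie correction is applied and noted even though field reports rarely say
whether theirs was. The χ²(g−1) approximation is used for p-values at any
n; the test suite documents its agreement with an exact permutation
oracle at the small sample sizes typical of sulphur subsamples.

## Numerical choices and degenerate inputs

- ILR inverse uses a max-subtracted softmax; round-trip error is < 10⁻¹²
  across the open simplex.
- Weight normalization is exact to 10⁻¹⁰ and invariant to adding a
  constant to every LOOic (log-sum-exp).
- Degenerate inputs fail loudly and early: zero within-chain variance
  (R̂ undefined), a single source sample (SD undefined, names the
  source), all-identical Kruskal–Wallis data (H undefined), zero
  simplex components (ILR boundary), non-positive C:N or abundance
  ratios. All-identical source samples give SD 0 with a warning rather
  than an error.
- Seeds: every stochastic step derives its seed from the user seed
  (replicate studies use the replicate index; lattice members use the
  member index), all below 2³¹.

## Problem sizes

Replicate studies (parameter recovery, model-selection behaviour) use 20
seeded replicates of the default 150-consumer design at the "test" MCMC
preset; these sizes give stable medians and coverage counts while keeping
a full run of the suite in the tens of minutes on one core. Oracle
comparisons use deliberately tiny problems (≤ 5 consumers, fixed residual
SD) where grid integration and exact-refit LOO are themselves exact.

## Known limitations

- Random-walk Metropolis needs the "full" preset for strict R̂ < 1.01 on
  the full random-effects models; the test preset trades that bar for
  speed (flagged, with accuracy demonstrated by the recovery study).
- Conditional (not marginal) pointwise likelihoods in LOO: weights can
  mildly favour random-effect models on effect-free data; medians over
  replicates remain well-behaved.
- Sources enter as fixed summaries; uncertainty in the source means from
  small n (4–8 samples) is represented only through the SDs, not a
  hierarchical source model.
- K > 2 sources are supported throughout the ILR machinery but the
  generator's convenience default (true_p_algal) and the headline
  summaries are written for the two-source question.
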