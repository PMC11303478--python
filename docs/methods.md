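# Methods

This note documents the models implemented in `gxesim`, the defaults
and numerical choices, what the synthetic data do and do not emulate,
and the known limitations.

## TPE covariance model

A target population of environments (TPE) is a p × p genetic
covariance matrix `Ge = De^{1/2} Ce De^{1/2}`.

**Genetic variances** (diagonal of `De`) are i.i.d. Gamma(α, θ).
Defaults α = 1.5, θ = 1 give a mean genetic variance of 1.5 trait
units² with a realistic right skew. The gamma law guarantees strictly
positive variances and controls heterogeneity through a single
closed-form quantity: the population value of the
heterogeneity-of-genetic-variance statistic
`mean(σ²_gj) − mean(σ_gj)²` is `αθ − θ (Γ(α+½)/Γ(α))²`
(≈ 0.227 at the defaults).

**Genetic correlations** come from a structured-noise construction:
`Ce = ρ J_p + ε ΛᵀΛ`, with `Λ` a (k−1) × p matrix whose columns are
drawn elementwise U(−1, 1+γ) and scaled to unit length. Properties
used throughout:

- the diagonal is exactly 1 when ε = 1 − ρ, and then rank(Ce) = k;
- off-diagonals lie in [ρ − ε, ρ + ε] ⊆ [2ρ − 1, 1];
- with γ = 0 the mean off-diagonal converges to ρ as p grows;
- γ < 0 shifts the latent covariates coherently, skewing the
  correlation distribution negatively (as observed in real MET data)
  and raising the mean correlation above ρ.

ρ < 0 is rejected rather than repaired: the constraint 0 ≤ ρ < 1 is
what guarantees positive semi-definiteness and the rank property, so
the generator never produces indefinite output. `bend_to_psd`
(eigenvalue clipping, the Frobenius-nearest PSD repair) exists only
for user-supplied matrices. When ε < 1 − ρ the diagonal is explicitly
reset to one and the rank guarantee is forfeited (the trailing p − k
terms each carry 1 − ρ − ε of variance).

**Scenario presets.** Four named presets are shipped: `none`
(compound symmetry, common variance 1.5, correlation 1 — a
no-interaction baseline), `low` (ρ = 0.5, ε = 0.5, γ = −0.5, k = 7),
`moderate` (ρ = 0.2, ε = 0.8, γ = −0.5, k = 7) and `high` (ρ = 0,
ε = 1, γ = −0.35, k = 7), all with the default gamma variances. At
p = 1000 these give main-effect proportions of roughly 0.51 / 0.32 /
0.08 and mean correlations of roughly 0.61 / 0.37 / 0.10.

One caveat on the non-crossover measure: `σ²_n` averages
`ρ*²_gj σ²_gj`, with `ρ*_gj = rowmean_j(Ge) / (σ_gj σ_g)` the
correlation between the genotype main effects and the environment-j
effects, computed analytically from `Ge` (the empirical route via
simulated effects is used only as a test oracle — the analytic form
is exact and fast). For the low preset this yields v_n ≈ 0.62. For
the moderate and high presets the formula yields v_n ≈ 0.41 and
≈ 0.23; higher structured noise makes the row means of `Ge` disperse,
which this definition counts as non-crossover variance. Users tuning
to a target v_n should tune against this implementation's output (the
`tune_to_targets` grid search does exactly that).

## Multiplicative decomposition and GE effects

`Ge = U L Uᵀ` is eigendecomposed (scipy `eigh`); the first k
eigenvectors are the environmental covariates `S_k`, the eigenvalues
the term variances `L_k`. Numerical conventions:

- eigenvalues sorted decreasing; values below 1e−12 of the largest
  are treated as zero for rank decisions;
- eigenvector signs fixed so each column's largest-magnitude element
  is positive, ties broken by first index. `Ge` is invariant to this
  choice; fixing it makes covariates reproducible across BLAS
  implementations.

Genotype slopes are `f_k ~ N(0, L_k ⊗ G)` with `G` a genotype
relationship matrix (identity by default; a genomic `G` is built in
the breeding module). The PSD square root of `G` is taken by
eigendecomposition with negative eigenvalues clipped at zero;
matrices failing PSD-ness beyond 1e−8 relative are rejected with a
pointer to `bend_to_psd`. GE effects are `u = f_k S_kᵀ`
(genotypes × environments), so the between-environment covariance of
the rows is `S_k L_k S_kᵀ`, which equals `Ge` exactly whenever
rank(Ge) ≤ k. Genotype main effects are row means of `u` over a
chosen environment subset.

## Expected accuracies and MET sampling

For a MET of p_m environments with r replicates and mean plot-error
variance σ²_ε, with TPE components σ²_g (main) and σ²_ge
(interaction):

```
r_g  = sqrt( σ²_g / (σ²_g + σ²_ge/p_m + σ²_ε/(p_m r)) )   accuracy in the TPE
r_m  = sqrt( (σ²_g + σ²_ge/p_m) / (same denominator) )     accuracy in the MET
r_mt = sqrt( σ²_g / (σ²_g + σ²_ge/p_m) )                   MET-TPE alignment
r_ge = sqrt( (σ²_g + σ²_ge) / (σ²_g + σ²_ge + σ²_ε/r) )    within-environment
```

with the identity `r_g = r_m r_mt` holding exactly. MET environments
are sampled uniformly without replacement by shuffling the TPE and
taking a prefix; across years of a breeding simulation environments
may recur, mirroring a finite TPE. Expected-accuracy annotations on a
sample always use the TPE-true σ²_g and σ²_ge, never values
re-estimated from the sample.

A precision caveat established during validation: `r_mt` is a
first-order approximation to the expected realized alignment. Under
heterogeneous `Ge` the mean realized alignment exceeds it by a
relative bias of order 1/p_m (about +0.005 at p_m = 20, +0.01 at
p_m = 10 for the low-GEI preset at p = 1000) because the realized
alignment is a convex function of the sampled-subset variance. The
expected value sits well inside the central spread of realized
alignments, but averages over ~1000 resamples resolve the bias. Tests
of this expectation therefore allow a 2% relative discrepancy.

## Phenotype generation

Plot phenotypes follow `y = 1μ + Xτ + Zu + ε` on a randomised
complete block design (r blocks per environment, every genotype once
per block, genotype placement randomized per block).

- Environmental main effects: i.i.d. N(0, σ²_e) with σ²_e = 1 by
  default, or deterministically `τ = S_k τ_s` (regression on the
  environmental covariates), which induces a mean–variance
  relationship across environments.
- Plot errors: per-environment error variances are, by default, drawn
  from a gamma distribution (shape 10) rescaled to the requested mean
  σ²_ε — real METs show error variances spread around their centre —
  with a homogeneous option available. The mean σ²_ε can be set from
  a target plot-level heritability via
  `σ²_ε = σ̄²_g (1 − H²)/H²`. Within an environment errors are
  independent or follow a separable AR(1) × AR(1) process on the
  row × column plot grid (blocks occupy contiguous column ranges,
  plots ordered row-major).
- The dataset stores the true GE effect and plot error per plot, so
  the phenotype decomposition is exactly recoverable; summaries
  report per-environment realized genetic variance, true error
  variance and `H²_j = σ²_gj/(σ²_gj + σ²_εj)`, with the overall `H²`
  the mean of the per-environment values (not a pooled ratio).

## Breeding-programme simulation

The TPE enters a recurrent programme through its multiplicative
terms: each term is one additive trait. Founders are doubled-haploid
lines with allele frequencies U(0.1, 0.9) on 10 chromosomes × 200
biallelic loci (defaults); raw marker effects are drawn per term and
then jointly standardised (centred, whitened, rescaled) so the
founder slope sample covariance is exactly diag(L_k) — the founder
population therefore starts at genetic mean 0 and variance
`s̄_k L_k s̄_kᵀ` by construction. Meiosis models crossovers as a
Poisson process (rate 1 per chromosome) via Haldane inter-locus
recombination probabilities; doubled haploids take one recombinant F1
gamete and double it, so selfing a homozygous line reproduces it
exactly.

The default programme (all counts config-driven) runs 20 years with
20 environments sampled per year and four stages — headrow
(200 genotypes, 1 environment, 1 replicate), preliminary (50/5/2),
advanced (20/10/2) and elite (10/20/2) yield trials, each stage's
environments a nested prefix of the year's sample, plot-error
variance 4 throughout (plot heritability ≈ 0.27 at the default TPE
scale). Each year the top fraction of each stage advances, the best
20 lines of the last two stages are crossed (40 crosses × 5 doubled
haploids) and enter the headrow. These sizes are deliberately
compact; they preserve the structure of a line programme (decreasing
sizes, increasing testing intensity) while keeping replicated
multi-scenario experiments fast.

Selection criteria:

- *phenotypic*: ranking on phenotype means across the stage's
  current-year environments;
- *genomic*: ranking on genotype main-effect BLUPs from a
  compound-symmetry mixed model (environment fixed; genotype with
  covariance σ²_g K, genomic relationship K from VanRaden method 1;
  interaction homogeneous σ²_ge; plot error absorbed into
  genotype-by-environment cell means, which are sufficient because
  blocks are not modelled), pooling all stages from the trailing
  3 years. Variance components are plugged in from the true TPE
  parameters — estimating them by REML is out of scope, which
  isolates the simulation framework from estimation machinery. A
  ridge of 1e−8 on the genetic covariance keeps K invertible for
  near-duplicate lines.

Progress is tracked per stage and year as `μ*_g = s̄_k τ*_{s_k}`
(covariate means × current slope means) and
`σ*²_g = s̄_k L*_k s̄_kᵀ` (with `L*_k` the current slope covariance),
identical to the mean/variance of directly computed genotype main
effects; MET analogues use the covariate rows of the year's sampled
environments; accuracies are Pearson correlations between the
selection criterion and true main effects.

## What the synthetic data do not emulate

The generator reproduces the covariance structure of GEI, not its
mechanism: environments are exchangeable draws with no year/location
labels, weather or management covariates, and no temporal drift in
the TPE. Error models cover independent and separable AR(1) × AR(1)
spatial noise only; designs are balanced RCBDs (no p-rep or sparse
testing). Genetic effects are purely additive; dominance and
epistasis enter only through a user-supplied `Ge`/`G`. Passing tests
therefore demonstrate correctness of the simulation machinery and its
internal identities, not fidelity to any particular crop or region.

## Numerical and design choices

- One integer seed controls a whole run; named child streams (tpe,
  slopes, tau, errors, sampling, breeding) are spawned in fixed order
  so components can be re-run independently.
- Latent covariates are drawn in environment order, so extending p
  reuses the first p draws.
- Matrices are written as labelled CSV with 17 significant digits and
  read back with round-trip float parsing; repeated runs under the
  same seed and config produce byte-identical CSVs.
- Symmetry is required within 1e−10 relative, PSD-ness within 1e−8
  relative of the largest eigenvalue; zero-variance environments get
  ρ*_gj = 0 with a warning and are excluded from the mean
  correlation.
- Monte-Carlo tests use fixed seeds and 3-standard-error bands at the
  stated simulation sizes (e.g. 10⁵ genotypes for distributional
  checks, 1000 resamples for alignment means); the acceptance
  experiments average 20 TPE realisations at p = 1000 and 20 breeding
  replicates per scenario and strategy.

## Known limitations

- The compound-symmetry BLUP assumes homogeneous interaction variance
  even when the truth is strongly heterogeneous; this is the realistic
  operational choice for large yearly METs, and it caps genomic
  selection's advantage at high GEI.
- `tune_to_targets` is a plain grid search with seed-averaged
  estimates; it does not optimise continuously.
- Alternative base correlation functions (autoregressive,
  year/location variance components, multi-trait blocks) are
  supported only through the `base_matrix` plug-in of
  `simulate_correlation_matrix`; no named structures are shipped.
- Expected accuracies are first-order formulas (see the alignment
  caveat above); they are indicators for design, not exact
  expectations of realized correlations.
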