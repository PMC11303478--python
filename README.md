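# gxesim

Simulation of genotype-by-environment interaction (GEI) for plant
breeding research, built on reduced-rank multiplicative models.

Plant breeding programmes evaluate candidate varieties in
multi-environment trials (METs) that sample a breeder's target
population of environments (TPE). Genotypes re-rank and re-scale
between environments, and how strongly they do so — the level of
non-crossover and crossover GEI — governs how well a MET predicts
performance in the TPE and how fast a programme can gain. Most
breeding simulations either ignore GEI or reduce it to a single noise
term. `gxesim` gives quantitative geneticists and breeding-programme
modellers a controllable, scalable GEI generator, plus the summary
measures needed to tune it and the machinery to embed it in trial and
breeding-programme simulations.

## The model

A TPE of `p` environments is represented by a between-environment
genetic covariance matrix

```
Ge = De^{1/2} Ce De^{1/2}
```

with heterogeneous genetic variances `σ²_gj ~ Gamma(α, θ)` on the
diagonal of `De` and a reduced-rank correlation matrix

```
Ce = ρ J_p + ε ΛᵀΛ,      Λ_j ~ U(−1, 1+γ)  (columns scaled to unit length)
```

where `ρ` is the baseline genetic correlation, `ε` the noise
magnitude (`ε = 1 − ρ` forces `rank(Ce) = k`) and `γ ∈ [−1, 0]` skews
the correlation distribution negatively. Eigendecomposing
`Ge = U L Uᵀ` and keeping the leading `k` terms gives environmental
covariates `S_k` and term variances `L_k`; genotype slopes
`f_k ~ N(0, L_k ⊗ G)` then yield the GE effects `u = f_k S_kᵀ`, which
are embedded in the linear mixed model
`y = 1μ + Xτ + Zu + ε` to generate plot-level phenotypes.

Summary measures computed from the true parameters include the
proportions of main-effect vs interaction variance (`v_g`, `v_ge`),
non-crossover vs crossover variance (`v_n`, `v_c`), the interaction
partition into heterogeneity of genetic variance and lack of genetic
correlation, and the expected accuracies
`r_g = r_m × r_mt` linking MET accuracy and MET-TPE alignment.

## Worked example

```python
import gxesim as g

# a low-GEI TPE with 1000 environments (rank-7 correlation structure)
ge = g.scenario_covariance("low", p=1000, seed=1)
dec = g.variance_decomposition(ge)
print(f"v_g={dec.v_g:.2f} v_ge={dec.v_ge:.2f} v_n={dec.v_n:.2f} "
      f"v_c={dec.v_c:.2f} mean_var={dec.mean_variance:.2f} "
      f"mean_corr={dec.mean_correlation:.2f}")

# expected accuracy of a 10-environment, 2-replicate MET in this TPE
acc = g.expected_accuracies(dec.sigma2_g, dec.sigma2_ge,
                            sigma2_eps=4.0, p_m=10, r=2)
print(f"r_g={acc.r_g:.3f} r_m={acc.r_m:.3f} r_mt={acc.r_mt:.3f}")
```

prints

```
v_g=0.51 v_ge=0.49 v_n=0.61 v_c=0.39 mean_var=1.49 mean_corr=0.60
r_g=0.859 r_m=0.899 r_mt=0.956
```

About half of the genetic variance in this TPE is genotype main
effect (`v_g`) and roughly a third of it causes rank changes between
environments (`v_c`). A 10-environment MET is expected to rank
genotypes in the TPE with accuracy 0.86; of the gap to 1, most comes
from the imperfect MET-TPE alignment (0.96) rather than plot error.

The same objects drive the higher-level tools: `build_met_dataset`
generates plot-level RCBD phenotypes, `sample_met` quantifies
realized MET-TPE alignment, and `run_programme` runs a multi-year
breeding programme with phenotypic or genomic (compound-symmetry
BLUP) selection under any GEI scenario.

A CLI mirrors the pipeline:

```
gxesim simulate-tpe --p 1000 --rho 0.5 --gamma -0.5 --k 7 --seed 1 --out-dir tpe/
gxesim measures --ge-csv tpe/Ge.csv
gxesim simulate-met --tpe-dir tpe/ --p-m 10 --v 400 --r 2 --h2 0.3 --seed 2 --out-dir met/
gxesim run-breeding --config programme.yaml --scenario high --seed 3 --out-dir runs/
```

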