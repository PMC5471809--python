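# fattygs

Genomic evaluation of fatty-acid composition traits in beef cattle: a
tested, end-to-end re-implementation of the standard workflow used to
dissect and predict meat-quality traits from dense SNP panels —
quality control, trait construction, variance components, Bayesian
whole-genome regression, association mapping and cross-validated
genomic prediction — driven by a synthetic-data generator with known
genetic architecture so every stage can be verified against ground
truth.

## Who this is for

Animal-breeding and quantitative-genetics researchers who want a
transparent, scriptable reference implementation of the classic
HD-chip analysis stack (the kind of analysis usually spread across
PLINK, ASReml, GenABEL, FREGAT and custom MCMC code) in one Python
package, with reproducible simulated benchmarks.

## The models

**Traits.** Twenty-one individual fatty acids (% of total fatty acid
methyl esters) are combined into group traits: SFA, MUFA, PUFA, the
omega subsets n-3 and n-6, the ratios PUFA/SFA and n-6/n-3, and the
health index HI = (MUFA + PUFA) / (4 × C14:0 + C16:0). Phenotypes are
adjusted by OLS for gender, farm and year plus slaughter-age,
days-to-extraction, carcass-weight and marbling covariates before any
genomic model sees them.

**Variance components.** With the VanRaden genomic relationship matrix
G = WW′ / 2Σpⱼ(1−pⱼ) (W = dosage − 2pⱼ), the animal model

    y = 1u + a + e,   a ~ N(0, G σ²ₐ),   e ~ N(0, I σ²ₑ)

is fitted by REML (exact profiled 1-D search after one
eigendecomposition of G); h² = σ²ₐ/(σ²ₐ+σ²ₑ). The bivariate version
with unstructured 2×2 genetic/residual covariances yields the genetic
correlation r_g = σₐ₁₂/√(σ²ₐ₁σ²ₐ₂).

**BayesB.** yᵢ = u + Σⱼ Zᵢⱼ αⱼ δⱼ + eᵢ with locus-specific variances
σ²ⱼ ~ scaled-inv-χ²(νₐ, S²ₐ), inclusion prior P(δⱼ=0) = π, and a
Metropolis-Hastings locus update with αⱼ analytically marginalized.
Association is summarized per 100 kb window as the posterior mean
share of whole-genome breeding-value variance; windows carrying ≥ 1%
are the candidate regions.

**GRAMMAR-GC.** Environmental residuals of the polygenic model are
score-tested against each SNP and the χ² statistics are divided by the
genomic-control factor λ = median(χ²)/0.4549. Candidate regions can be
re-tested jointly with a weighted linear-kernel (SKAT-style) score
test, and region LD is computed as EM-haplotype r².

**Prediction.** GBLUP (mixed-model equations, relationships propagated
to masked individuals) and BayesB (test genotypes scored by
posterior-mean effects) under 5-fold cross-validation; accuracy
r = cor(GEBV, y_adj)/√h², dispersion bias as the regression slope
relating GEBV and phenotype (both directions reported).

## Worked example

```python
import fattygs as fg

cfg   = fg.SimConfig(n_individuals=500, n_chromosomes=3, snps_per_chrom=300,
                     n_qtl=1, target_h2=0.5, seed=42)
geno  = fg.simulate_genotypes(cfg)
table, truth = fg.simulate_phenotypes(geno, cfg)
adj   = fg.adjust_phenotypes(table, "sim_trait")
grm   = fg.build_grm(geno)
vc    = fg.reml_univariate(adj, grm)
print(f"h2 = {vc.h2:.3f}")

bcfg = fg.derive_scale_params(vc.sigma_a2, vc.sigma_e2, geno,
                              fg.BayesBConfig(pi=0.99, n_iter=3000, burn_in=600,
                                              seed=5, gv_thin=5))
post = fg.run_bayesb(adj, geno, bcfg)
wins = fg.window_variance_proportions(post, geno)
top  = max(wins, key=lambda w: w.var_proportion)
print(f"top window chr{top.chrom}:{top.start_bp}-{top.end_bp} "
      f"share = {top.var_proportion:.3f}")
```

prints

```
h2 = 0.570
top window chr2:1800001-1900000 share = 0.974
```

i.e. REML estimates the simulated heritability of 0.5 at 0.57 (one
replicate at n = 500; the 20-replicate benchmark mean is within 0.01
of the target) and the single planted QTL's 100 kb window absorbs ~97%
of the posterior genetic variance, with the remainder scattered across
the other windows.

The same steps are available from the shell:

```bash
fattygs simulate --out-dir fix --n 500 --n-qtl 1 --h2 0.5 --seed 42
fattygs qc       --bfile fix/sim --out fix/qc
fattygs varcomp  --bfile fix/qc --pheno fix/sim.pheno.tsv --trait sim_trait
fattygs bayesb   --bfile fix/qc --pheno fix/sim.pheno.tsv --trait sim_trait --pi 0.99
fattygs predict  --bfile fix/qc --pheno fix/sim.pheno.tsv --trait sim_trait --method gblup
```

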