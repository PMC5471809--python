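# Methods

This note records the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Synthetic data generator

The generator emulates the structure of a beef-cattle HD-chip study at
desk scale. Its defaults describe the emulated study population:
~700 animals, a handful of autosomes carrying a few thousand SNPs in
LD blocks, tens of QTL, moderate heritability, fixed effects for
gender (2 levels), farm (3) and year (4), and slaughter covariates
(age ~N(610, 45²) days, days-to-extraction ~N(30, 8²), hot carcass
weight ~N(330, 35²) kg, marbling ~N(5, 1.5²)) with small slopes so the
non-genetic terms stay modest relative to the unit genetic-plus-
residual variance.

**LD model.** Haplotypes follow a first-order Markov rank-copying
chain: each SNP carries a latent uniform u_j that is copied from its
left neighbour with probability ρ (`ld_decay_rho`, default 0.9) and
refreshed otherwise; the allele is the indicator u_j < p_j. Copying on
the uniform rank rather than the allele keeps the marginal frequency
of every SNP exactly at its drawn p_j while correlation decays
geometrically (≈ ρ^lag between same-frequency markers). The genotype
is the sum of two independent haplotypes. This produces block-wise LD
sufficient to exercise window methods; it does not model recombination
hotspots, mutation, selection or multi-breed structure, so passing
tests say nothing about robustness to those features of real data.

**Heritability calibration** is deterministic: QTL (drawn uniformly
without replacement; effects Gaussian or signed-gamma(0.4)) are
rescaled so the sample variance of breeding values equals `target_h2`,
and residuals are rescaled to sample variance 1 − `target_h2`, so the
realized variance ratio equals the target exactly. Recovery tests
therefore measure estimator error only, not generator noise.
`simulate_trait_pair` draws effects for two traits from a bivariate
normal with the requested correlation at shared QTL; the realized
breeding-value correlation matches the target up to effect-sampling
noise (≈ ±0.05 at 50 QTL).

Missing genotypes are injected only on request (default rate 0), so QC
tests construct their own positive cases.

## Genotype I/O and QC

PLINK v1.00 SNP-major bed/bim/fam is read and written directly (2-bit
codes: 00 hom-A1, 10 het, 11 hom-A2, 01 missing; dosage counts A1
alleles). QC order: individuals with > 10% missing genotypes are
removed first (PLINK convention), then non-autosomal markers
(autosomes 1–29), then — with statistics computed on the retained
sample — SNPs kept when MAF > 0.05, missing rate < 0.05 and HWE
p > 1e-6. The HWE test is the 1-df chi-square goodness-of-fit
(monomorphic SNPs p = 1 by convention); an exact test could be swapped
in, but the 1e-6 threshold is far too coarse for the difference to
matter. Removed SNPs are attributed to the first failed filter in the
order MAF, call rate, HWE, so the report's categories partition the
dropped set. Missing dosages are never imputed in storage; mean
imputation to 2p_j happens only when a design/relationship matrix is
built.

## GRM and REML

G = WW′ / 2Σp_j(1−p_j) with frequencies from the analyzed sample.
The univariate animal model is fitted by maximizing the profiled
restricted likelihood over h² with Brent search after one
eigendecomposition of G: in the eigenbasis the covariance is diagonal,
the intercept and total variance profile out analytically, and each
likelihood evaluation is O(n). This is exact to the search tolerance
(1e-6) and cannot step outside the parameter space, which is why it
was preferred over an AI-REML iteration for a two-component model.
Negative eigenvalues below −1e-8 trigger a 1e-6 ridge with a warning;
variance components are floored at 1e-8 × phenotypic variance so
boundary fits cannot yield h² outside [0, 1]. Standard errors come
from the inverse numerical observed information on the log-variance
scale, delta-method-transformed; they are reporting aids, not
quantities any test asserts tightly.

The bivariate model uses the same eigenbasis (per-eigenvalue 2×2
blocks) and maximizes over a log-Cholesky parameterization of the
genetic and residual covariance matrices with L-BFGS-B, warm-started
from the univariate fits. Positive semi-definiteness holds by
construction; r_g is clamped to [−1, 1] with a warning when the
overshoot exceeds 0.01. Exactly collinear trait pairs make the
restricted likelihood unbounded at the singular boundary, so they are
detected (|cor| > 1 − 1e-10) and returned as the boundary estimate
r_g = ±1 with the univariate components.

## BayesB

Locus update: joint Metropolis-Hastings on (δ_j, σ²_j) with the effect
α_j analytically integrated out and the proposal drawn from the prior,
so the acceptance ratio is the marginal-likelihood ratio
(−½ log(1 + σ²z′z/σ²ₑ) + σ²(z′r)²/(2σ²ₑ(σ²ₑ + σ²z′z)) against the
null); α_j is then Gibbs-refreshed for included loci, the overall mean
and σ²ₑ have conjugate updates after each sweep (systematic scan).
Genotypes are centered by 2p_j inside the sampler (the mean absorbs
the constant), matching the GRM; genetic values and GEBV are reported
on the raw dosage scale, where centering constants are irrelevant to
variances and correlations. Prior scales are derived from REML
estimates so the prior-mean genetic and residual variances match them:
S²ₐ = σ̂²ₐ(νₐ−2)/νₐ / ((1−π)·2Σp(1−p)), S²ₑ = σ̂²ₑ(νₑ−2)/νₑ.

Defaults are the full-scale settings (π = 0.9998 for a ~600 K panel,
50 000/10 000 chain); desk-scale runs use shorter chains (the CLI
defaults to 5 000/1 000 with `--paper-chain` restoring the full
schedule) and a π giving an expected fitted-SNP count in the tens,
e.g. π = 0.99 at M ≈ 1 000. Running sums provide posterior means/SDs
and inclusion frequencies; full effect vectors are stored every
`gv_thin`-th retained sweep (default 10) to bound memory while
supporting window variances. The conjugate limit (π = 0, fixed σ²_j
and σ²ₑ) reduces the sampler to Gibbs ridge regression, whose
posterior mean has the closed form (Z′Z + λI)⁻¹Z′y — the sampler's
correctness gate, asserted within 3 posterior SDs.

## Window GWAS

Windows are fixed 100 kb bins anchored at position 1 (SNP at bp b maps
to bin ⌊(b−1)/100 000⌋). For each retained effect sample the window's
breeding-value variance across individuals is divided by the **sum of
window variances**, and shares are averaged over samples. The summed
denominator (rather than the variance of the total breeding value)
makes shares partition to exactly 1 within every sample; the two
denominators coincide when windows are unlinked and differ only
through inter-window LD covariance terms. Samples with zero total
genetic variance are skipped. Windows with posterior mean share ≥ 1%
are reported as candidate regions.

## GRAMMAR-GC and the region test

Stage 1 computes environmental residuals ê = σ²ₑV⁻¹(y − 1û) from the
polygenic fit; stage 2 score-tests each centered SNP,
χ² = (z′ê)²/(z′z·var(ê)); stage 3 divides by λ = median(χ²)/0.4549
(the χ²₁ median) and recomputes p-values, which preserves ranking and
restores calibration in both the deflated and inflated direction.

A property worth knowing: the raw GRAMMAR statistic is deflated by
proximal contamination — each tested SNP contributes to G, and the
polygenic BLUP absorbs part of its signal — by a factor of roughly
1 − h²·n/M_e. In the emulated study's regime (panel hundreds of times
denser than the sample) λ is close to 1; at desk scales with M ≈ 2n
raw λ drops to ~0.6–0.87 while the GC-corrected type-I error stays at
the nominal level throughout. The calibration benchmark therefore runs
in the dense-panel regime (n = 300, M = 2000, ρ = 0.5), and the unit
suite documents λ behaviour separately.

The region test is a weighted linear-kernel score test on the GRAMMAR
residuals: Q = Σ_j w_j²(z_j′ê)² with beta(1, 25) MAF weights, null
distribution Σλ_iχ²₁ with λ_i the eigenvalues of σ̂²·(WZ′ZW), p-value
by the Liu moment-matched (non-central) chi-square. A one-SNP region
reduces to the marginal score test exactly. The beta(1, 25) weighting
concentrates power on lower-frequency variants; common-variant regions
can use flat weights via `weights_beta=(1, 1)`, and a burden collapse
is available with `method="burden"`. Monomorphic regions return p = 1.
Pairwise LD is the EM haplotype-frequency r² on unphased two-locus
tables (double heterozygotes split by phase probability), with the
squared genotype correlation as a fallback and r² = 0 against
monomorphic SNPs.

Significance thresholds are plain Bonferroni arithmetic: 0.05/#SNPs
genome-wide and 0.05/#independent-SNPs suggestive, with the
independent count supplied by the caller (block-counting algorithms
vary and are out of scope).

## Genomic prediction

GBLUP solves the training-set GLS system (Cholesky; tiny ridge with a
warning if V is numerically singular) and propagates
â = σ²ₐ G[:, train] V⁻¹(y − 1û) to all individuals, which equals
SNP-BLUP with λ = σ²ₑ/(σ²ₐ/denominator) on the same centered
genotypes — the module's correctness gate (agreement to 1e-6). BayesB
prediction scores test genotypes by posterior-mean effects from a
chain trained on the training fold only.

Cross-validation uses 5 random folds of near-equal size, deterministic
under the seed. Variance components are re-estimated on each training
fold (no leakage); the h² in the accuracy denominator is the
whole-data estimate, fixed across folds, matching the convention of a
single reported heritability per trait. Both regression directions are
reported because the field's verbal convention (phenotype on GEBV) and
the definition used here as the headline (GEBV on phenotype) differ;
fold SEs are SD/√k over folds.

## Benchmark problem sizes

The recovery battery uses: ridge/equivalence oracles at n = 200,
M = 500; REML recovery over 20 replicates at n = 1000, M = 2000;
bivariate r_g over 10 replicates at n = 600, M = 1000; window
localization at n = 500, M = 900 with one QTL; GRAMMAR calibration
over 10 seeds at n = 300, M = 2000; prediction ordering over 10 seeds
at n = 400, M = 800 with 5 QTL and a 1500/300 chain. These sizes keep
every benchmark at seconds-to-a-minute on one CPU while leaving the
measured quantities comfortably inside their tolerance bands;
rerunning at larger n only tightens them.

## Known limitations

- The simulator's ρ is a free parameter, not calibrated to any real
  cattle population's LD; genotypes carry no population structure,
  pedigree or selection signatures, so stratification-robustness of
  GRAMMAR is not tested here.
- The trait adjustment is fixed-effects OLS; if the non-genetic design
  were confounded with genetic structure, pre-adjustment could absorb
  genetic signal. The simulator draws factors independently of
  genotype, so the benchmarks do not probe that failure mode.
- Bivariate REML SEs are not reported (only point estimates and
  convergence); multi-trait (> 2) models, dominance/epistasis,
  pedigree matrices and single-step methods are out of scope.
- The BayesB locus proposal is prior-based; with very strong single
  loci the chain mixes more slowly than a tuned proposal would, which
  is why benchmark chains use thousands of sweeps at desk scale.
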