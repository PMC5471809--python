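"""Synthetic genotype/phenotype generator with known genetic architecture.

Emulates the structure of a beef-cattle HD-chip study at desk scale:
LD-blocked biallelic genotypes over several autosomes, a sparse (or
fully polygenic) QTL architecture, fixed non-genetic factors (gender,
farm, year) and slaughter covariates, with exact control of the
realized heritability.  Every downstream stage of the pipeline can be
tested against the stored truth (QTL positions and effects, breeding
values, realized h2).

The LD model is a first-order Markov rank-copying chain: each SNP's
latent uniform is copied from its left neighbour with probability
``ld_decay_rho`` and refreshed otherwise, and the allele is the
indicator ``u < p_j``.  Marginal allele frequencies are therefore exact
while pairwise LD decays geometrically with marker distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, write_plink
from .traits import TraitTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_trait_pair",
    "write_fixture_set",
]


def _default_fixed_effects() -> dict:
    return {"gender": 2, "farm": 3, "year": 4}


def _default_covariates() -> dict:
    # name -> (mean, sd, slope); slaughter at ~20 months, carcass/marbling on
    # customary scales, slopes sized so non-genetic terms stay modest relative
    # to the unit genetic + residual variance.
    return {
        "slaughter_age": (610.0, 45.0, 0.004),
        "days_to_extraction": (30.0, 8.0, 0.01),
        "hot_carcass_weight": (330.0, 35.0, 0.003),
        "marbling_score": (5.0, 1.5, 0.08),
    }


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults emulate the study population at desk scale: ~700 animals,
    a few thousand SNPs in LD blocks, tens of QTL, moderate h2.
    """

    n_individuals: int = 700
    n_chromosomes: int = 5
    snps_per_chrom: int = 400
    chrom_length_bp: int = 2_000_000
    ld_decay_rho: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 50
    target_h2: float = 0.5
    effect_dist: str = "gaussian"          # or "gamma-signed"
    fixed_effect_levels: dict = field(default_factory=_default_fixed_effects)
    covariate_specs: dict = field(default_factory=_default_covariates)
    missing_rate: float = 0.0
    base_mean: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_individuals, self.n_chromosomes, self.snps_per_chrom) <= 0:
            raise ValueError("simulation dimensions must be positive")
        if self.chrom_length_bp < self.snps_per_chrom:
            raise ValueError("chromosome shorter than its SNP count")
        if not 0.0 <= self.ld_decay_rho <= 1.0:
            raise ValueError("ld_decay_rho must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must lie in [0, 1]")
        if self.n_qtl > self.n_chromosomes * self.snps_per_chrom:
            raise ValueError("n_qtl exceeds total SNP count")
        if self.effect_dist not in ("gaussian", "gamma-signed"):
            raise ValueError(f"unknown effect_dist {self.effect_dist!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth stored alongside a simulated phenotype."""

    qtl_indices: np.ndarray       # sorted SNP indices of the QTL
    qtl_effects: np.ndarray       # allele-substitution effect per QTL (trait units)
    true_bv: np.ndarray           # per-individual total breeding value
    realized_h2: float
    sigma_e2: float               # realized residual variance
    fixed_effect_values: np.ndarray  # per-individual non-genetic contribution

    def effect_vector(self, n_snps: int) -> np.ndarray:
        """Full-length effect vector; exactly zero off the QTL."""
        alpha = np.zeros(n_snps)
        alpha[self.qtl_indices] = self.qtl_effects
        return alpha


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw LD-structured genotypes as the sum of two Markov haplotypes."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_individuals
    rho = config.ld_decay_rho

    chroms, bps, snp_ids, dosage_blocks = [], [], [], []
    for c in range(1, config.n_chromosomes + 1):
        m = config.snps_per_chrom
        pos = np.sort(rng.choice(config.chrom_length_bp, size=m, replace=False)) + 1
        p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

        geno = np.zeros((n, m), dtype=np.float32)
        for _hap in range(2):
            u = np.empty((n, m))
            u[:, 0] = rng.random(n)
            for j in range(1, m):
                fresh = rng.random(n)
                copy = rng.random(n) < rho
                u[:, j] = np.where(copy, u[:, j - 1], fresh)
            geno += (u < p).astype(np.float32)
        dosage_blocks.append(geno)
        chroms.append(np.full(m, c))
        bps.append(pos)
        snp_ids.append(np.array([f"chr{c}_snp{j + 1}" for j in range(m)], dtype=object))

    dosage = np.concatenate(dosage_blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    return GenotypeMatrix(
        ids=np.array([f"ind{i + 1:05d}" for i in range(n)], dtype=object),
        snp_ids=np.concatenate(snp_ids),
        chrom=np.concatenate(chroms),
        bp=np.concatenate(bps),
        dosage=dosage,
    )


def _draw_effects(rng: np.random.Generator, n_qtl: int, dist: str) -> np.ndarray:
    if dist == "gaussian":
        return rng.standard_normal(n_qtl)
    # gamma-signed: heavy-tailed magnitudes with random sign
    return rng.gamma(shape=0.4, scale=1.66, size=n_qtl) * rng.choice([-1.0, 1.0], size=n_qtl)


def _exact_variance(x: np.ndarray, target: float) -> np.ndarray:
    """Rescale (after centering-invariant shift) so the population variance equals target."""
    v = float(np.var(x))
    if v == 0.0:
        raise ValueError("cannot rescale a constant vector to positive variance")
    return x * np.sqrt(target / v)


def _nongenetic_terms(
    rng: np.random.Generator, config: SimConfig, n: int
) -> tuple[pd.DataFrame, np.ndarray]:
    cols = {}
    contrib = np.zeros(n)
    for fac, n_levels in config.fixed_effect_levels.items():
        levels = rng.integers(0, n_levels, size=n)
        effects = rng.normal(0.0, 0.5, size=n_levels)
        cols[fac] = np.array([f"{fac}{l + 1}" for l in levels], dtype=object)
        contrib = contrib + effects[levels]
    for cov, (mean, sd, slope) in config.covariate_specs.items():
        x = rng.normal(mean, sd, size=n)
        cols[cov] = x
        contrib = contrib + slope * x
    return pd.DataFrame(cols), contrib


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimConfig, trait_name: str = "sim_trait"
) -> tuple[TraitTable, SimTruth]:
    """Simulate one trait on ``geno`` with exact heritability calibration.

    QTL are drawn uniformly, effects from the configured distribution, and
    both effect sizes and residuals are rescaled so that the realized
    variance ratio var(bv) / (var(bv) + var(e)) equals ``target_h2``
    exactly (genetic + residual variance is normalized to 1; the fixed
    factors and covariates are added on top).
    """
    config.validate()
    n = geno.n_individuals
    if n < 2:
        raise ValueError("need at least two individuals")
    h2 = config.target_h2
    if h2 > 0 and config.n_qtl == 0:
        raise ValueError("positive target_h2 requires at least one QTL")
    rng = np.random.default_rng([config.seed, 1])

    m = geno.n_snps
    n_qtl = min(config.n_qtl, m)
    qtl = np.sort(rng.choice(m, size=n_qtl, replace=False)) if n_qtl else np.array([], dtype=int)

    if h2 > 0:
        raw = _draw_effects(rng, n_qtl, config.effect_dist)
        zc = geno.centered()[:, qtl]
        bv_raw = zc @ raw
        scale = np.sqrt(h2 / float(np.var(bv_raw)))
        effects = raw * scale
        bv = bv_raw * scale
    else:
        effects = np.zeros(n_qtl)
        bv = np.zeros(n)

    if h2 < 1.0:
        e = rng.standard_normal(n)
        e = (e - e.mean()) / np.std(e) * np.sqrt(1.0 - h2)
    else:
        e = np.zeros(n)
    sigma_e2 = float(np.var(e))
    var_bv = float(np.var(bv))
    realized_h2 = var_bv / (var_bv + sigma_e2) if (var_bv + sigma_e2) > 0 else 0.0

    covars, contrib = _nongenetic_terms(rng, config, n)
    y = config.base_mean + contrib + bv + e

    data = pd.DataFrame({"id": geno.ids})
    data[trait_name] = y
    for c in covars.columns:
        data[c] = covars[c]

    table = TraitTable(
        data=data,
        trait_columns=[trait_name],
        factor_columns=list(config.fixed_effect_levels),
        covariate_columns=list(config.covariate_specs),
    )
    truth = SimTruth(
        qtl_indices=qtl,
        qtl_effects=effects,
        true_bv=bv,
        realized_h2=realized_h2,
        sigma_e2=sigma_e2,
        fixed_effect_values=contrib,
    )
    return table, truth


def simulate_trait_pair(
    geno: GenotypeMatrix,
    config: SimConfig,
    genetic_corr: float,
    trait_names: tuple = ("trait_a", "trait_b"),
) -> tuple[TraitTable, SimTruth, SimTruth]:
    """Two traits sharing the same QTL with correlated effect sizes.

    Effects are drawn from a bivariate normal with correlation
    ``genetic_corr``; each trait is then calibrated to ``target_h2``
    exactly as in :func:`simulate_phenotypes`.  The realized genetic
    correlation (correlation of the two breeding-value vectors) matches
    the target up to effect-sampling noise.
    """
    config.validate()
    if not -1.0 <= genetic_corr <= 1.0:
        raise ValueError("genetic_corr must lie in [-1, 1]")
    if config.n_qtl == 0 or config.target_h2 <= 0:
        raise ValueError("trait pairs require a positive QTL count and heritability")
    rng = np.random.default_rng([config.seed, 2])
    n, m = geno.dosage.shape
    n_qtl = min(config.n_qtl, m)
    qtl = np.sort(rng.choice(m, size=n_qtl, replace=False))

    cov = np.array([[1.0, genetic_corr], [genetic_corr, 1.0]])
    raw = rng.multivariate_normal(np.zeros(2), cov, size=n_qtl)
    zc = geno.centered()[:, qtl]

    data = pd.DataFrame({"id": geno.ids})
    truths = []
    h2 = config.target_h2
    for k, name in enumerate(trait_names):
        bv = _exact_variance(zc @ raw[:, k], h2)
        scale = np.sqrt(h2 / float(np.var(zc @ raw[:, k])))
        e = rng.standard_normal(n)
        e = (e - e.mean()) / np.std(e) * np.sqrt(1.0 - h2) if h2 < 1 else np.zeros(n)
        data[name] = config.base_mean + bv + e
        var_bv, s_e2 = float(np.var(bv)), float(np.var(e))
        truths.append(
            SimTruth(
                qtl_indices=qtl,
                qtl_effects=raw[:, k] * scale,
                true_bv=bv,
                realized_h2=var_bv / (var_bv + s_e2) if var_bv + s_e2 > 0 else 0.0,
                sigma_e2=s_e2,
                fixed_effect_values=np.zeros(n),
            )
        )

    table = TraitTable(
        data=data, trait_columns=list(trait_names), factor_columns=[], covariate_columns=[]
    )
    return table, truths[0], truths[1]


def write_fixture_set(geno: GenotypeMatrix, traits: TraitTable, directory) -> dict:
    """Write a PLINK triplet plus a tab-delimited phenotype/covariate file.

    Round-trips losslessly through :func:`fattygs.genio.read_plink`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_plink(geno, directory / "sim")
    pheno_path = directory / "sim.pheno.tsv"
    traits.data.to_csv(pheno_path, sep="\t", index=False, na_rep="NA")
    paths["pheno"] = pheno_path
    return paths
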