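"""Association mapping: window-based variance shares, GRAMMAR-GC, region tests, LD.

Four complementary views of marker-trait association are provided:

* **Window GWAS** — the genome is partitioned into fixed 100 kb bins and
  the share of whole-genome breeding-value variance carried by each
  bin is averaged over retained BayesB samples; bins with a posterior
  mean share >= 1% are the candidate regions.
* **GRAMMAR-GC** — a two-stage single-SNP scan: the polygenic animal
  model is fitted once, its environmental residuals are score-tested
  against each SNP, and the chi-square statistics are divided by the
  median-based genomic-control inflation factor lambda.
* **Region score test** — a weighted linear-kernel (SKAT-style) score
  test of all SNPs in a candidate region against the GRAMMAR residuals,
  with beta(1, 25) MAF weights and a Liu moment-matched chi-square
  null; a burden variant collapses the region into one weighted score.
* **Pairwise r2** — haplotype-frequency LD estimated by EM over
  unphased two-locus genotype tables (composite fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .traits import AdjustedPhenotype
from .varcomp import GRM, VarComp, reml_univariate
from .bayesb import BayesBPosterior

__all__ = [
    "WindowResult",
    "GrammarResult",
    "RegionTestResult",
    "window_partition",
    "window_variance_proportions",
    "candidate_windows",
    "grammar_gc_scan",
    "significance_thresholds",
    "region_score_test",
    "pairwise_r2",
]

#: Median of the chi-square(1) distribution, the genomic-control normalizer.
CHI2_1_MEDIAN = 0.45493642311957174

DEFAULT_WINDOW_BP = 100_000
CANDIDATE_MIN_PROPORTION = 0.01


@dataclass
class WindowResult:
    """Posterior genetic-variance share of one genomic window."""

    chrom: int
    start_bp: int       # 1-based inclusive
    end_bp: int
    n_snp: int
    var_proportion: float


@dataclass
class GrammarResult:
    """Single-SNP GRAMMAR-GC scan: per-SNP table plus the inflation factor."""

    table: pd.DataFrame     # snp_id, chrom, bp, beta, chi2, p_raw, p_gc
    lambda_gc: float
    varcomp: VarComp


@dataclass
class RegionTestResult:
    chrom: int
    start_bp: int
    end_bp: int
    n_snp: int
    statistic: float
    p_value: float
    snp_p_values: np.ndarray


def window_partition(
    geno: GenotypeMatrix, window_bp: int = DEFAULT_WINDOW_BP
) -> tuple[np.ndarray, list]:
    """Assign each SNP to its fixed-width genomic window.

    A SNP at 1-based position bp on chromosome c belongs to window
    floor((bp - 1) / window_bp); windows are anchored at position 1 and
    empty windows are omitted.  Returns (labels, windows): ``labels[j]``
    indexes into ``windows``, a list of (chrom, start_bp, end_bp, n_snp).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    win_idx = (geno.bp - 1) // window_bp
    keys = np.stack([geno.chrom, win_idx], axis=1)
    uniq, labels = np.unique(keys, axis=0, return_inverse=True)
    counts = np.bincount(labels, minlength=len(uniq))
    windows = [
        (int(c), int(w * window_bp + 1), int((w + 1) * window_bp), int(k))
        for (c, w), k in zip(uniq, counts)
    ]
    return labels, windows


def window_variance_proportions(
    posterior: BayesBPosterior,
    geno: GenotypeMatrix,
    assignment: tuple[np.ndarray, list] | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[WindowResult]:
    """Posterior mean share of genetic variance per window.

    For each retained effect sample, the window's breeding-value
    variance across individuals is divided by the summed variance over
    all windows (so shares partition to 1 within every sample; with
    unlinked windows this denominator coincides with the variance of
    the whole-genome breeding value).  Samples with zero total genetic
    variance are skipped with a warning.
    """
    labels, windows = window_partition(geno, window_bp) if assignment is None else assignment
    Z = geno.imputed()
    samples = posterior.alpha_samples
    n_win = len(windows)
    prop_sum = np.zeros(n_win)
    n_used = 0
    win_cols = [np.flatnonzero(labels == w) for w in range(n_win)]

    for s in range(samples.shape[0]):
        alpha = samples[s]
        var_w = np.empty(n_win)
        for w, cols in enumerate(win_cols):
            gv = Z[:, cols] @ alpha[cols]
            var_w[w] = np.var(gv)
        total = var_w.sum()
        if total <= 0.0:
            continue
        prop_sum += var_w / total
        n_used += 1

    if n_used == 0:
        warnings.warn("all retained samples carry zero genetic variance", stacklevel=2)
        props = np.zeros(n_win)
    else:
        props = prop_sum / n_used

    return [
        WindowResult(chrom=c, start_bp=s, end_bp=e, n_snp=k, var_proportion=float(p))
        for (c, s, e, k), p in zip(windows, props)
    ]


def candidate_windows(
    results: list, min_proportion: float = CANDIDATE_MIN_PROPORTION
) -> list:
    """Windows whose posterior mean variance share reaches the reporting cut."""
    return [w for w in results if w.var_proportion >= min_proportion]


def _polygenic_residuals(
    y_adj: AdjustedPhenotype, grm: GRM, varcomp: VarComp | None
) -> tuple[np.ndarray, VarComp, np.ndarray]:
    """Stage-1 GRAMMAR fit: environmental residuals e = y - 1u - a_blup."""
    if varcomp is None:
        varcomp = reml_univariate(y_adj, grm)
    idx = grm.index_of(y_adj.ids)
    sub = grm if idx.size == grm.n and np.array_equal(idx, np.arange(grm.n)) else grm.subset(idx)
    d, U = sub.eigen()
    y = np.asarray(y_adj.y_adj, dtype=float)
    sa2 = varcomp.sigma_a2 if np.isscalar(varcomp.sigma_a2) else varcomp.sigma_a2[0]
    se2 = varcomp.sigma_e2 if np.isscalar(varcomp.sigma_e2) else varcomp.sigma_e2[0]
    w = sa2 * d + se2
    yt = U.T @ y
    xt = U.T @ np.ones(y.size)
    u_hat = np.sum(xt * yt / w) / np.sum(xt * xt / w)
    resid_t = se2 * (yt - xt * u_hat) / w        # se2 V^-1 (y - 1u)
    return U @ resid_t, varcomp, idx


def grammar_gc_scan(
    y_adj: AdjustedPhenotype,
    geno: GenotypeMatrix,
    grm: GRM,
    varcomp: VarComp | None = None,
) -> GrammarResult:
    """Two-stage GRAMMAR scan with genomic-control correction.

    Stage 1 fits the polygenic model and extracts environmental
    residuals; stage 2 score-tests each centered SNP dosage against
    them; stage 3 divides every chi-square by
    lambda = median(chi2) / 0.4549 and recomputes p-values.
    """
    resid, varcomp, _ = _polygenic_residuals(y_adj, grm, varcomp)
    # residuals are in y_adj order; align genotype rows to the same individuals
    pos = {i: k for k, i in enumerate(geno.ids)}
    rows = np.array([pos[i] for i in y_adj.ids])
    Zc = geno.centered()[rows]

    zty = Zc.T @ resid
    zsq = np.sum(Zc * Zc, axis=0)
    s2 = float(np.mean(resid**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(zsq > 0, zty / zsq, 0.0)
        chi2 = np.where(zsq > 0, zty**2 / (zsq * s2), 0.0)
    p_raw = stats.chi2.sf(chi2, df=1)

    if geno.n_snps < 10:
        warnings.warn("fewer than 10 SNPs: genomic-control lambda is unreliable", stacklevel=2)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    p_gc = stats.chi2.sf(chi2 / lam, df=1)

    table = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": geno.chrom,
            "bp": geno.bp,
            "beta": beta,
            "chi2": chi2,
            "p_raw": p_raw,
            "p_gc": p_gc,
        }
    )
    return GrammarResult(table=table, lambda_gc=lam, varcomp=varcomp)


def significance_thresholds(n_snps: int, n_independent: int) -> tuple[float, float]:
    """Bonferroni (0.05 / #SNPs) and suggestive (0.05 / #independent SNPs) cuts.

    The independent count — one SNP per LD block plus all interblock
    SNPs — is supplied by the caller.
    """
    if n_snps <= 0 or n_independent <= 0:
        raise ValueError("SNP counts must be positive")
    return 0.05 / n_snps, 0.05 / n_independent


def _liu_sf(q: float, lambdas: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matched survival function of sum lambda_i chi2_1."""
    lambdas = lambdas[lambdas > 0]
    if lambdas.size == 0:
        return 1.0
    c1 = lambdas.sum()
    c2 = np.sum(lambdas**2)
    c3 = np.sum(lambdas**3)
    c4 = np.sum(lambdas**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(x, df, delta) if delta > 0 else stats.chi2.sf(x, df))


def region_score_test(
    y_adj: AdjustedPhenotype,
    geno_region: GenotypeMatrix,
    grm: GRM,
    varcomp: VarComp | None = None,
    weights_beta: tuple = (1.0, 25.0),
    method: str = "kernel",
) -> RegionTestResult:
    """Variance-component (SKAT-style) region test on GRAMMAR residuals.

    Q = sum_j w_j^2 (z_j' e)^2 with beta(a, b) MAF weights w_j; the null
    distribution of Q is the moment-matched mixture of chi-squares with
    weights sigma^2 w_j^2 z_j' z_j (eigenvalues of the weighted kernel).
    ``method="burden"`` instead tests the single weighted sum of
    dosages.  Monomorphic regions return p = 1 with a warning.
    """
    if geno_region.n_snps < 1:
        raise ValueError("region must contain at least one SNP")
    resid, varcomp, _ = _polygenic_residuals(y_adj, grm, varcomp)
    pos = {i: k for k, i in enumerate(geno_region.ids)}
    rows = np.array([pos[i] for i in y_adj.ids])
    Zc = geno_region.centered()[rows]

    p = geno_region.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    poly = maf > 0
    s2 = float(np.mean(resid**2))

    zty = Zc.T @ resid
    zsq = np.sum(Zc * Zc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        snp_chi2 = np.where(zsq > 0, zty**2 / (zsq * s2), 0.0)
    snp_p = stats.chi2.sf(snp_chi2, df=1)

    chrom = int(geno_region.chrom[0])
    start, end = int(geno_region.bp.min()), int(geno_region.bp.max())
    if not poly.any():
        warnings.warn("monomorphic region: p = 1 by convention", stacklevel=2)
        return RegionTestResult(chrom, start, end, geno_region.n_snps, 0.0, 1.0, snp_p)

    w = np.zeros_like(maf)
    w[poly] = stats.beta.pdf(maf[poly], *weights_beta)

    if method == "burden":
        b = Zc @ w
        bsq = float(b @ b)
        stat = float((b @ resid) ** 2 / (bsq * s2)) if bsq > 0 else 0.0
        p_value = float(stats.chi2.sf(stat, df=1))
    elif method == "kernel":
        stat = float(np.sum((w * zty) ** 2))
        Zw = Zc * w
        K = Zw.T @ Zw
        lambdas = np.linalg.eigvalsh(K) * s2
        p_value = _liu_sf(stat, lambdas)
    else:
        raise ValueError(f"unknown region test method {method!r}")

    return RegionTestResult(
        chrom=chrom,
        start_bp=start,
        end_bp=end,
        n_snp=geno_region.n_snps,
        statistic=stat,
        p_value=min(max(p_value, np.finfo(float).tiny), 1.0),
        snp_p_values=snp_p,
    )


def _em_haplotype_r2(g1: np.ndarray, g2: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Two-locus r2 from EM haplotype frequencies on unphased genotypes.

    Returns NaN when EM cannot resolve (degenerate table); callers fall
    back to the composite (genotype-correlation) estimate.
    """
    ok = ~(np.isnan(g1) | np.isnan(g2))
    x, z = g1[ok], g2[ok]
    n = x.size
    if n == 0:
        return np.nan
    p1 = x.mean() / 2.0
    p2 = z.mean() / 2.0
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return 0.0

    # 3x3 genotype table; phase is determined except for double heterozygotes
    t = np.zeros((3, 3))
    for xi, zi in zip(x.astype(int), z.astype(int)):
        t[xi, zi] += 1
    n_dh = t[1, 1]
    cAB = 2 * t[2, 2] + t[2, 1] + t[1, 2]

    fAB = p1 * p2  # start from linkage equilibrium
    total_h = 2.0 * n
    for _ in range(max_iter):
        # split double heterozygotes between AB/ab and Ab/aB phases
        fAb = max(p1 - fAB, 1e-12)
        faB = max(p2 - fAB, 1e-12)
        fab = max(1.0 - p1 - p2 + fAB, 1e-12)
        num = fAB * fab
        den = num + fAb * faB
        frac = num / den if den > 0 else 0.5
        new_fAB = (cAB + n_dh * frac) / total_h
        if abs(new_fAB - fAB) < tol:
            fAB = new_fAB
            break
        fAB = new_fAB

    D = fAB - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom <= 0:
        return 0.0
    return min((D * D) / denom, 1.0)


def pairwise_r2(geno_region: GenotypeMatrix) -> np.ndarray:
    """Symmetric matrix of pairwise LD r2 between SNPs in a region.

    Haplotype frequencies by EM over unphased genotype pairs, with the
    composite (squared genotype correlation) estimate as fallback;
    monomorphic SNPs get r2 = 0 against everything, diagonal = 1.
    """
    m = geno_region.n_snps
    if m < 2:
        raise ValueError("need at least two SNPs for pairwise LD")
    d = geno_region.dosage.astype(float)
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r2 = _em_haplotype_r2(d[:, i], d[:, j])
            if np.isnan(r2):
                ok = ~(np.isnan(d[:, i]) | np.isnan(d[:, j]))
                if ok.sum() > 1 and np.std(d[ok, i]) > 0 and np.std(d[ok, j]) > 0:
                    r2 = float(np.corrcoef(d[ok, i], d[ok, j])[0, 1] ** 2)
                else:
                    r2 = 0.0
            out[i, j] = out[j, i] = r2
    return out
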