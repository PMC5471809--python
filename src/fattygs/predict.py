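"""Genomic prediction: GBLUP and BayesB with k-fold cross-validation.

GBLUP solves the animal model y = 1u + Za + e on the training records
with V(a) = G sa2, V(e) = I se2 and propagates breeding values to the
masked individuals through the genomic relationships (joint system over
all individuals with test records absent).  BayesB prediction scores
test genotypes by the posterior-mean SNP effects of a chain trained on
the training fold only.

Predictive accuracy follows the convention of dividing the
GEBV/adjusted-phenotype correlation by the square root of the trait
heritability; dispersion bias is the regression slope relating the two
(both directions are reported, the GEBV-on-phenotype slope is the
headline figure).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .bayesb import BayesBConfig, derive_scale_params, run_bayesb
from .genio import GenotypeMatrix
from .traits import AdjustedPhenotype
from .varcomp import GRM, VarComp, reml_univariate

__all__ = [
    "CVResult",
    "AccuracyBias",
    "make_folds",
    "gblup_predict",
    "bayesb_predict",
    "accuracy_and_bias",
    "crossvalidate",
]


@dataclass
class AccuracyBias:
    """Accuracy and dispersion-bias summaries for one validation set."""

    r: float            # cor(GEBV, y_adj) / sqrt(h2)
    r_raw: float        # plain correlation cor(GEBV, y_adj)
    b: float            # slope of GEBV on y_adj
    b_reverse: float    # slope of y_adj on GEBV


@dataclass
class CVResult:
    """k-fold cross-validation summary for one trait and method."""

    trait: str
    method: str
    fold_accuracies: np.ndarray
    mean_r: float
    se_r: float
    fold_regressions: np.ndarray
    mean_b: float
    se_b: float
    fold_regressions_reverse: np.ndarray = field(default=None)
    seed: int = 0
    h2: float = float("nan")


def make_folds(ids, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition of individuals into k folds of near-equal size.

    Returns the fold index (0..k-1) per individual; sizes differ by at
    most one and the assignment is deterministic under the seed.
    """
    ids = np.asarray(ids)
    n = ids.size
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} individuals")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    for fold, chunk in enumerate(np.array_split(order, k)):
        assignment[chunk] = fold
    return assignment


def gblup_predict(
    y_adj_train: AdjustedPhenotype, grm: GRM, varcomp: VarComp
) -> tuple[np.ndarray, float]:
    """GBLUP breeding values for every individual in the GRM.

    Solves the training mixed model (V = G_tt sa2 + I se2, GLS
    intercept) and propagates a_hat = sa2 G[:, train] V^-1 (y - 1u) to
    all individuals.  Returns (gebv aligned to ``grm.ids``, u_hat).
    """
    sa2 = varcomp.sigma_a2 if np.isscalar(varcomp.sigma_a2) else varcomp.sigma_a2[0]
    se2 = varcomp.sigma_e2 if np.isscalar(varcomp.sigma_e2) else varcomp.sigma_e2[0]
    train = grm.index_of(y_adj_train.ids)
    y = np.asarray(y_adj_train.y_adj, dtype=float)

    V = sa2 * grm.G[np.ix_(train, train)] + se2 * np.eye(train.size)
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        V = V + 1e-8 * np.trace(V) / train.size * np.eye(train.size)
        c = np.linalg.cholesky(V)

    def vsolve(b):
        return np.linalg.solve(c.T, np.linalg.solve(c, b))

    ones = np.ones(train.size)
    vi_y = vsolve(y)
    vi_1 = vsolve(ones)
    u_hat = float(ones @ vi_y / (ones @ vi_1))
    resid = vsolve(y - u_hat * ones)
    gebv = sa2 * grm.G[:, train] @ resid
    return gebv, u_hat


def bayesb_predict(posterior, geno_test: GenotypeMatrix) -> np.ndarray:
    """Score test genotypes by posterior-mean SNP effects."""
    if geno_test.n_snps != posterior.alpha_hat.size or not np.array_equal(
        geno_test.snp_ids, posterior.snp_ids
    ):
        raise ValueError("test marker set does not match the trained posterior")
    return geno_test.imputed() @ posterior.alpha_hat


def accuracy_and_bias(gebv_test, y_adj_test, h2: float) -> AccuracyBias:
    """Predictive accuracy r = cor(GEBV, y_adj)/sqrt(h2) and slopes.

    ``b`` regresses GEBV on the adjusted phenotype; ``b_reverse`` the
    conventional phenotype-on-GEBV direction.
    """
    g = np.asarray(gebv_test, dtype=float)
    y = np.asarray(y_adj_test, dtype=float)
    if g.size != y.size or g.size < 3:
        raise ValueError("need at least three aligned test individuals")
    if h2 <= 0:
        raise ValueError("h2 must be positive for the accuracy denominator")
    vg, vy = np.var(g), np.var(y)
    if vg == 0:
        return AccuracyBias(r=float("nan"), r_raw=float("nan"), b=float("nan"),
                            b_reverse=float("nan"))
    cov = float(np.cov(g, y, ddof=0)[0, 1])
    r_raw = cov / np.sqrt(vg * vy)
    return AccuracyBias(
        r=float(r_raw / np.sqrt(h2)),
        r_raw=float(r_raw),
        b=float(cov / vy),
        b_reverse=float(cov / vg),
    )


def crossvalidate(
    y_adj: AdjustedPhenotype,
    geno: GenotypeMatrix,
    grm: GRM,
    method: str = "gblup",
    k: int = 5,
    seed: int = 0,
    h2: float | None = None,
    bayesb_config: BayesBConfig | None = None,
    reuse_varcomp: VarComp | None = None,
) -> CVResult:
    """k-fold cross-validated genomic prediction.

    Variance components are re-estimated on each training fold unless
    ``reuse_varcomp`` is given; the h2 in the accuracy denominator is
    the whole-data REML estimate (fixed across folds) unless supplied.
    """
    if method not in ("gblup", "bayesb"):
        raise ValueError(f"unknown prediction method {method!r}")
    ids = y_adj.ids
    y = y_adj.align(ids)
    folds = make_folds(ids, k=k, seed=seed)

    if h2 is None:
        whole = reuse_varcomp if reuse_varcomp is not None else reml_univariate(y_adj, grm)
        h2 = whole.h2 if np.isscalar(whole.h2) else whole.h2[0]
    h2 = max(float(h2), 1e-6)

    accs, slopes, slopes_rev = [], [], []
    for fold in range(k):
        test_mask = folds == fold
        train_ids = ids[~test_mask]
        test_ids = ids[test_mask]
        y_train = AdjustedPhenotype(ids=train_ids, y_adj=y[~test_mask], trait=y_adj.trait)

        train_rows = np.flatnonzero(~test_mask)
        test_rows = np.flatnonzero(test_mask)
        vc = reuse_varcomp
        if vc is None:
            grm_train = grm.subset(grm.index_of(train_ids))
            vc = reml_univariate(y_train, grm_train)

        if method == "gblup":
            gebv_all, _ = gblup_predict(y_train, grm, vc)
            gebv_test = gebv_all[grm.index_of(test_ids)]
        else:
            cfg = bayesb_config if bayesb_config is not None else BayesBConfig(
                pi=0.99, n_iter=3000, burn_in=600
            )
            cfg = dataclasses.replace(cfg, seed=cfg.seed + fold)
            geno_train = geno.subset(individuals=train_rows)
            sa2 = vc.sigma_a2 if np.isscalar(vc.sigma_a2) else vc.sigma_a2[0]
            se2 = vc.sigma_e2 if np.isscalar(vc.sigma_e2) else vc.sigma_e2[0]
            cfg = derive_scale_params(sa2, se2, geno_train, cfg)
            posterior = run_bayesb(y_train, geno_train, cfg)
            gebv_test = bayesb_predict(posterior, geno.subset(individuals=test_rows))

        ab = accuracy_and_bias(gebv_test, y[test_mask], h2)
        accs.append(ab.r)
        slopes.append(ab.b)
        slopes_rev.append(ab.b_reverse)

    accs = np.array(accs)
    slopes = np.array(slopes)
    slopes_rev = np.array(slopes_rev)
    return CVResult(
        trait=y_adj.trait,
        method=method,
        fold_accuracies=accs,
        mean_r=float(np.nanmean(accs)),
        se_r=float(np.nanstd(accs, ddof=1) / np.sqrt(k)),
        fold_regressions=slopes,
        mean_b=float(np.nanmean(slopes)),
        se_b=float(np.nanstd(slopes, ddof=1) / np.sqrt(k)),
        fold_regressions_reverse=slopes_rev,
        seed=seed,
        h2=h2,
    )
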