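"""VanRaden genomic relationship matrix and REML variance components.

The additive relationship matrix is G = W W' / (2 sum p_j (1 - p_j))
with W the allele dosages centered by twice the allele frequency of the
analyzed sample (missing calls imputed to 2 p_j).  Heritabilities come
from the single-trait animal model y = 1 u + a + e with V(a) = G sa2,
V(e) = I se2; genetic correlations from the corresponding bivariate
model with unstructured 2x2 genetic and residual covariance matrices.

Both REML fits exploit a single eigendecomposition of G, which makes
each restricted-likelihood evaluation O(n).  The univariate fit
maximizes the profiled restricted likelihood over the heritability by
Brent search (exact to the requested tolerance; no update step can
leave the parameter space); the bivariate fit runs quasi-Newton on a
log-Cholesky parameterization, which keeps both covariance matrices
positive semi-definite by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .genio import GenotypeMatrix
from .traits import AdjustedPhenotype

__all__ = ["GRM", "VarComp", "build_grm", "reml_univariate", "reml_bivariate"]

_VAR_FLOOR = 1e-8   # x phenotypic variance; keeps h2 inside [0, 1]
_RIDGE = 1e-6


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its scaling denominator."""

    ids: np.ndarray
    G: np.ndarray
    denom: float

    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (values, vectors); ridge-stabilized if needed."""
        if self._eig is None:
            d, U = np.linalg.eigh(self.G)
            if d.min() < -1e-8:
                warnings.warn(
                    f"G has negative eigenvalue {d.min():.3g}; adding ridge {_RIDGE:g}",
                    stacklevel=2,
                )
                d = d + _RIDGE
            d = np.clip(d, 0.0, None)
            self._eig = (d, U)
        return self._eig

    def index_of(self, ids) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        return np.array([lookup[i] for i in ids])

    def subset(self, idx) -> "GRM":
        idx = np.asarray(idx)
        return GRM(ids=self.ids[idx], G=self.G[np.ix_(idx, idx)], denom=self.denom)


@dataclass
class VarComp:
    """REML variance components for one trait or a trait pair."""

    traits: tuple
    sigma_a2: float | tuple
    sigma_e2: float | tuple
    h2: float | tuple
    sigma_a12: float | None = None
    sigma_e12: float | None = None
    r_g: float | None = None
    se: dict = field(default_factory=dict)
    converged: bool = True
    loglik: float = float("nan")


def build_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden G from QC-passed genotypes (missing imputed to 2p)."""
    p = geno.allele_freq()
    if np.isnan(p).any():
        raise ValueError("all-missing SNPs present; run qc_filter first")
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    W = geno.centered(p)
    G = (W @ W.T) / denom
    return GRM(ids=geno.ids, G=G, denom=denom)


# ---------------------------------------------------------------------------
# univariate REML

def _profile_reml_neg_loglik(h2: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """-2 x profiled restricted log-likelihood at heritability h2.

    Works on the eigenbasis of G: V = sp2 diag(h2 d + 1 - h2); the total
    variance sp2 and the intercept are profiled out analytically.
    """
    n = yt.size
    w = h2 * d + (1.0 - h2)
    xtwx = np.sum(xt * xt / w)
    u_hat = np.sum(xt * yt / w) / xtwx
    r = yt - xt * u_hat
    quad = np.sum(r * r / w)
    sp2 = quad / (n - 1)
    return float(np.sum(np.log(w)) + (n - 1) * np.log(sp2) + np.log(xtwx) + (n - 1))


def reml_univariate(
    y_adj: AdjustedPhenotype,
    grm: GRM,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> VarComp:
    """REML fit of y = 1u + a + e with V(a) = G sa2, V(e) = I se2.

    Returns estimates with h2 = sa2 / (sa2 + se2) and standard errors
    from the inverse observed information (numerical, on the variance
    scale, delta method for h2).
    """
    idx = grm.index_of(y_adj.ids)
    if idx.size < 30:
        raise ValueError("REML needs at least 30 individuals")
    sub = grm if idx.size == grm.n and np.array_equal(idx, np.arange(grm.n)) else grm.subset(idx)
    d, U = sub.eigen()
    y = np.asarray(y_adj.y_adj, dtype=float)
    yt = U.T @ y
    xt = U.T @ np.ones(y.size)

    res = optimize.minimize_scalar(
        _profile_reml_neg_loglik,
        bounds=(0.0, 1.0 - 1e-9),
        args=(d, yt, xt),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    h2 = float(res.x)
    # recover profiled total variance at the optimum
    w = h2 * d + (1.0 - h2)
    xtwx = np.sum(xt * xt / w)
    u_hat = np.sum(xt * yt / w) / xtwx
    sp2 = float(np.sum((yt - xt * u_hat) ** 2 / w) / (y.size - 1))
    floor = _VAR_FLOOR * sp2
    sigma_a2 = max(h2 * sp2, floor)
    sigma_e2 = max((1.0 - h2) * sp2, floor)
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)

    se = _univariate_se(sigma_a2, sigma_e2, d, yt, xt)
    return VarComp(
        traits=(y_adj.trait,),
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        h2=h2,
        se=se,
        converged=bool(res.success),
        loglik=-0.5 * float(res.fun),
    )


def _neg_reml_2comp(theta: np.ndarray, d, yt, xt) -> float:
    sa2, se2 = np.exp(theta)
    w = sa2 * d + se2
    xtwx = np.sum(xt * xt / w)
    u_hat = np.sum(xt * yt / w) / xtwx
    r = yt - xt * u_hat
    return float(np.sum(np.log(w)) + np.sum(r * r / w) + np.log(xtwx))


def _univariate_se(sa2, se2, d, yt, xt) -> dict:
    """SEs from the numerical observed information on the (sa2, se2) scale."""
    theta = np.log([max(sa2, 1e-12), max(se2, 1e-12)])
    h = 1e-4
    f0 = _neg_reml_2comp(theta, d, yt, xt)
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei, ej = np.zeros(2), np.zeros(2)
            ei[i] = h
            ej[j] = h
            fpp = _neg_reml_2comp(theta + ei + ej, d, yt, xt)
            fpm = _neg_reml_2comp(theta + ei - ej, d, yt, xt)
            fmp = _neg_reml_2comp(theta - ei + ej, d, yt, xt)
            fmm = _neg_reml_2comp(theta - ei - ej, d, yt, xt)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    H *= 0.5  # -2 loglik -> -loglik curvature
    try:
        cov_log = np.linalg.inv(H)
        if np.any(np.diag(cov_log) < 0):
            raise np.linalg.LinAlgError
        # delta method: var on natural scale, then h2 = sa2/(sa2+se2)
        J = np.diag([sa2, se2])
        cov = J @ cov_log @ J
        tot = sa2 + se2
        g = np.array([se2 / tot**2, -sa2 / tot**2])
        return {
            "sigma_a2": float(np.sqrt(cov[0, 0])),
            "sigma_e2": float(np.sqrt(cov[1, 1])),
            "h2": float(np.sqrt(g @ cov @ g)),
        }
    except np.linalg.LinAlgError:
        return {"sigma_a2": float("nan"), "sigma_e2": float("nan"), "h2": float("nan")}


# ---------------------------------------------------------------------------
# bivariate REML

def _chol_from_theta(theta3: np.ndarray) -> np.ndarray:
    """(log l11, l21, log l22) -> lower-triangular Cholesky factor."""
    return np.array([[np.exp(theta3[0]), 0.0], [theta3[1], np.exp(theta3[2])]])


def _neg_reml_bivariate(theta: np.ndarray, d, y1t, y2t, xt) -> float:
    La = _chol_from_theta(theta[:3])
    Le = _chol_from_theta(theta[3:])
    Sa = La @ La.T
    Se = Le @ Le.T
    # per-eigenvalue 2x2 blocks V_i = d_i Sa + Se
    a = d * Sa[0, 0] + Se[0, 0]
    b = d * Sa[0, 1] + Se[0, 1]
    c = d * Sa[1, 1] + Se[1, 1]
    det = a * c - b * b
    if np.any(det <= 0) or np.any(a <= 0):
        return 1e30
    i11 = c / det
    i12 = -b / det
    i22 = a / det
    # GLS intercepts (one per trait): X = I2 (x) x in the eigenbasis
    A11 = np.sum(xt * xt * i11)
    A12 = np.sum(xt * xt * i12)
    A22 = np.sum(xt * xt * i22)
    r1 = np.sum(xt * (i11 * y1t + i12 * y2t))
    r2 = np.sum(xt * (i12 * y1t + i22 * y2t))
    detA = A11 * A22 - A12 * A12
    if detA <= 0:
        return 1e30
    b1 = (A22 * r1 - A12 * r2) / detA
    b2 = (A11 * r2 - A12 * r1) / detA
    e1 = y1t - xt * b1
    e2 = y2t - xt * b2
    quad = np.sum(i11 * e1 * e1 + 2 * i12 * e1 * e2 + i22 * e2 * e2)
    return float(np.sum(np.log(det)) + quad + np.log(detA))


def reml_bivariate(
    y1: AdjustedPhenotype,
    y2: AdjustedPhenotype,
    grm: GRM,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> VarComp:
    """Bivariate animal-model REML: genetic and residual 2x2 covariances.

    Individuals present for both traits are used.  Returns per-trait
    variances and heritabilities, the additive covariance, and the
    genetic correlation r_g = sa12 / sqrt(sa1^2 sa2^2) clamped to
    [-1, 1] (warning when the overshoot exceeds 0.01).
    """
    common = [i for i in y1.ids if i in set(y2.ids)]
    if len(common) < 30:
        raise ValueError("bivariate REML needs at least 30 shared individuals")
    idx = grm.index_of(common)
    sub = grm.subset(idx)
    d, U = sub.eigen()
    v1 = y1.align(common)
    v2 = y2.align(common)
    # collinear traits make the restricted likelihood unbounded at the
    # boundary (singular covariances): return the boundary estimate directly
    corr = float(np.corrcoef(v1, v2)[0, 1])
    if abs(corr) > 1.0 - 1e-10:
        warnings.warn(
            "bivariate REML on collinear traits: boundary estimate r_g = +-1 returned",
            stacklevel=2,
        )
        f = reml_univariate(AdjustedPhenotype(np.array(common, dtype=object), v1, y1.trait), sub)
        sgn = np.sign(corr)
        scale = float(np.std(v2) / np.std(v1))
        return VarComp(
            traits=(y1.trait, y2.trait),
            sigma_a2=(f.sigma_a2, f.sigma_a2 * scale**2),
            sigma_e2=(f.sigma_e2, f.sigma_e2 * scale**2),
            sigma_a12=float(sgn * f.sigma_a2 * scale),
            sigma_e12=float(sgn * f.sigma_e2 * scale),
            h2=(f.h2, f.h2),
            r_g=float(sgn),
            converged=f.converged,
            loglik=f.loglik,
        )
    y1t = U.T @ v1
    y2t = U.T @ v2
    xt = U.T @ np.ones(len(common))

    # warm start from univariate marginals + phenotypic covariance split
    f1 = reml_univariate(AdjustedPhenotype(np.array(common, dtype=object), v1, y1.trait), sub)
    f2 = reml_univariate(AdjustedPhenotype(np.array(common, dtype=object), v2, y2.trait), sub)
    # split the phenotypic covariance between components in proportion to h2
    cp = float(np.cov(v1, v2)[0, 1])
    ca_max = 0.9 * np.sqrt(f1.sigma_a2 * f2.sigma_a2)
    ce_max = 0.9 * np.sqrt(f1.sigma_e2 * f2.sigma_e2)
    ca0 = float(np.clip(cp * np.sqrt(f1.h2 * f2.h2), -ca_max, ca_max))
    ce0 = float(np.clip(cp - ca0, -ce_max, ce_max))

    def theta_of(v11, v12, v22):
        L = np.linalg.cholesky(np.array([[v11, v12], [v12, v22]]))
        return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])

    theta0 = np.concatenate(
        [
            theta_of(max(f1.sigma_a2, 1e-6), ca0, max(f2.sigma_a2, 1e-6)),
            theta_of(max(f1.sigma_e2, 1e-6), ce0, max(f2.sigma_e2, 1e-6)),
        ]
    )
    res = optimize.minimize(
        _neg_reml_bivariate,
        theta0,
        args=(d, y1t, y2t, xt),
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol},
    )
    La = _chol_from_theta(res.x[:3])
    Le = _chol_from_theta(res.x[3:])
    Sa = La @ La.T
    Se = Le @ Le.T

    r_g = Sa[0, 1] / np.sqrt(Sa[0, 0] * Sa[1, 1])
    if abs(r_g) > 1.0:
        if abs(r_g) - 1.0 > 0.01:
            warnings.warn(f"genetic correlation overshoot |r_g|={abs(r_g):.3f}", stacklevel=2)
        r_g = float(np.clip(r_g, -1.0, 1.0))

    h2 = (
        Sa[0, 0] / (Sa[0, 0] + Se[0, 0]),
        Sa[1, 1] / (Sa[1, 1] + Se[1, 1]),
    )
    return VarComp(
        traits=(y1.trait, y2.trait),
        sigma_a2=(float(Sa[0, 0]), float(Sa[1, 1])),
        sigma_e2=(float(Se[0, 0]), float(Se[1, 1])),
        sigma_a12=float(Sa[0, 1]),
        sigma_e12=float(Se[0, 1]),
        h2=(float(h2[0]), float(h2[1])),
        r_g=float(r_g),
        converged=bool(res.success),
        loglik=-0.5 * float(res.fun),
    )
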