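"""Fatty-acid trait construction and fixed-effect adjustment.

Twenty-one individual fatty acids, each expressed as a percentage of
total fatty acid methyl esters, are combined into the standard group
traits (SFA, MUFA, PUFA, the omega-3 and omega-6 subsets, their ratios,
and the atherogenicity-based health index).  Phenotypes are adjusted
for non-genetic structure (gender, farm, year; slaughter age, days to
extraction, hot carcass weight, marbling score) by ordinary least
squares before any genomic model sees them, so that the downstream
mixed models carry the only polygenic term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "AdjustedPhenotype",
    "SFA_COMPONENTS",
    "MUFA_COMPONENTS",
    "PUFA_COMPONENTS",
    "N3_COMPONENTS",
    "N6_COMPONENTS",
    "GROUP_TRAITS",
    "compute_groups",
    "summarize_trait",
    "adjust_phenotypes",
]

SFA_COMPONENTS = ["C14:0", "C16:0", "C18:0", "C20:0", "C22:0", "C24:0"]
MUFA_COMPONENTS = ["C14:1 cis-9", "C16:1 cis-9", "C18:1 cis-9", "C20:1 cis-11"]
PUFA_COMPONENTS = [
    "C18:2 n-6",
    "C18:2 t-9c-11",
    "C18:2 t-12c-10",
    "C18:3 n-6",
    "C18:3 n-3",
    "C20:2 n-6",
    "C20:3 n-3",
    "C20:4 n-6",
    "C20:5 n-3",
    "C22:5 n-3",
    "C22:6 n-3",
]
N3_COMPONENTS = ["C18:3 n-3", "C20:3 n-3", "C20:5 n-3", "C22:5 n-3", "C22:6 n-3"]
N6_COMPONENTS = ["C18:2 n-6", "C18:3 n-6", "C20:2 n-6", "C20:4 n-6"]

#: All 21 measured fatty acids.
FATTY_ACIDS = SFA_COMPONENTS + MUFA_COMPONENTS + PUFA_COMPONENTS

#: Derived group traits, in reporting order.
GROUP_TRAITS = ["SFA", "MUFA", "PUFA", "PUFA/SFA", "n-3", "n-6", "n-6/n-3", "HI"]

DEFAULT_FACTORS = ["gender", "farm", "year"]
DEFAULT_COVARIATES = [
    "slaughter_age",
    "days_to_extraction",
    "hot_carcass_weight",
    "marbling_score",
]


@dataclass
class TraitTable:
    """Phenotype table: one row per individual (``id`` column required).

    ``trait_columns`` name the measured/derived traits; ``factor_columns``
    and ``covariate_columns`` name the non-genetic adjustment terms.
    """

    data: pd.DataFrame
    trait_columns: list = field(default_factory=list)
    factor_columns: list = field(default_factory=lambda: list(DEFAULT_FACTORS))
    covariate_columns: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))

    def __post_init__(self) -> None:
        if "id" not in self.data.columns:
            raise ValueError("TraitTable data must contain an 'id' column")
        if self.data["id"].duplicated().any():
            raise ValueError("individual IDs must be unique")

    @property
    def ids(self) -> np.ndarray:
        return self.data["id"].to_numpy(dtype=object)


@dataclass
class AdjustedPhenotype:
    """Trait values with fixed effects and covariates regressed out.

    ``y_adj`` is the OLS residual re-centered to the trait's grand mean,
    so the downstream overall mean stays on the original trait scale.
    """

    ids: np.ndarray
    y_adj: np.ndarray
    trait: str

    def align(self, target_ids) -> np.ndarray:
        """Return y_adj reordered to ``target_ids`` (all must be present)."""
        lookup = {i: k for k, i in enumerate(self.ids)}
        try:
            idx = np.array([lookup[i] for i in target_ids])
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} has no adjusted phenotype") from exc
        return self.y_adj[idx]


def _ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    out = num / den
    return out.mask(den == 0, np.nan)


def compute_groups(traits: TraitTable) -> TraitTable:
    """Append the eight fatty-acid group traits to the table.

    SFA/MUFA/PUFA and the omega subsets are component sums; ratios with a
    zero denominator are flagged missing.  The health index is
    HI = (MUFA + PUFA) / (4 x C14:0 + C16:0).
    """
    df = traits.data
    missing = [c for c in FATTY_ACIDS if c not in df.columns]
    if missing:
        raise KeyError(f"missing fatty-acid component columns: {missing}")

    out = df.copy()
    out["SFA"] = df[SFA_COMPONENTS].sum(axis=1)
    out["MUFA"] = df[MUFA_COMPONENTS].sum(axis=1)
    out["PUFA"] = df[PUFA_COMPONENTS].sum(axis=1)
    out["n-3"] = df[N3_COMPONENTS].sum(axis=1)
    out["n-6"] = df[N6_COMPONENTS].sum(axis=1)
    out["PUFA/SFA"] = _ratio(out["PUFA"], out["SFA"])
    out["n-6/n-3"] = _ratio(out["n-6"], out["n-3"])
    out["HI"] = _ratio(out["MUFA"] + out["PUFA"], 4.0 * df["C14:0"] + df["C16:0"])

    trait_cols = list(dict.fromkeys(traits.trait_columns + GROUP_TRAITS))
    return TraitTable(
        data=out,
        trait_columns=trait_cols,
        factor_columns=traits.factor_columns,
        covariate_columns=traits.covariate_columns,
    )


def summarize_trait(values) -> tuple[float, float, float]:
    """Mean, sample SD (n-1) and CV% = 100*SD/mean of a trait vector.

    A zero mean flags the CV as NaN; a constant vector gives CV = 0.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need at least two non-missing values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if mean == 0.0:
        return mean, sd, float("nan")
    return mean, sd, 100.0 * sd / mean


def _design_matrix(df: pd.DataFrame, factors, covariates) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for fac in factors:
        dummies = pd.get_dummies(df[fac].astype("category"), prefix=fac, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    for cov in covariates:
        cols.append(pd.to_numeric(df[cov]).to_numpy(dtype=float))
        names.append(cov)
    return np.column_stack(cols), names


def adjust_phenotypes(
    traits: TraitTable,
    trait: str,
    factors=None,
    covariates=None,
    return_coefs: bool = False,
):
    """OLS adjustment of a trait for fixed factors and covariates.

    Fits trait ~ intercept + factor dummies + covariates, drops rows with a
    missing trait value, and returns the residual shifted back to the grand
    mean.  Rank-deficient designs are resolved by the minimum-norm
    least-squares solution (aliased columns effectively dropped, warning
    emitted).
    """
    factors = traits.factor_columns if factors is None else list(factors)
    covariates = traits.covariate_columns if covariates is None else list(covariates)
    if trait not in traits.data.columns:
        raise KeyError(f"unknown trait {trait!r}")

    df = traits.data.loc[traits.data[trait].notna()].reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    X, names = _design_matrix(df, factors, covariates)

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"adjustment design for {trait!r} is rank deficient "
            f"({rank}/{X.shape[1]}); aliased columns dropped",
            stacklevel=2,
        )
    resid = y - X @ beta
    adjusted = AdjustedPhenotype(
        ids=df["id"].to_numpy(dtype=object), y_adj=resid + float(np.mean(y)), trait=trait
    )
    if return_coefs:
        return adjusted, dict(zip(names, beta))
    return adjusted
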