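"""Post hoc life-history comparison between decline-timing groups.

Taxa are split into two groups by when their period-wise posterior median
growth rate dropped most (period 1 -> 2 vs period 2 -> 3), then each trait
is compared between groups with a Gaussian linear mixed model carrying a
random intercept per subfamily (a coarse phylogenetic correction), fitted
by maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist, norm

__all__ = [
    "assign_groups",
    "rank_transform",
    "fit_trait_model",
    "TraitFitResult",
    "load_example_traits",
    "compare_traits",
]

ORDINAL_TRAITS = ("longevity_class", "fecundity_class")
CONTINUOUS_TRAITS = ("max_total_length", "female_age_maturation")


def load_example_traits() -> pd.DataFrame:
    """Schema-example trait table for an eight-taxon community.

    Ships with the package to document the expected columns; substitute
    real measurements for real analyses.
    """
    with resources.files("cpue_ssm.data").joinpath("example_traits.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def assign_groups(growth_summary: pd.DataFrame, threshold: float | None = None) -> pd.Series:
    """Label each taxon by decline timing.

    Group 1: the posterior-median growth rate dropped more from period 1 to
    period 2 than from period 2 to period 3.  Group 2 otherwise (ties go to
    group 2, the later decline).  With ``threshold`` set, group 1 is instead
    any taxon whose period 1 -> 2 drop is at least ``threshold``.
    """
    med = growth_summary.pivot(index="taxon", columns="period", values="median")
    for p in (1, 2, 3):
        if p not in med.columns or med[p].isna().any():
            raise ValueError(f"growth summary lacks a period-{p} median for some taxon")
    drop12 = med[1] - med[2]
    drop23 = med[2] - med[3]
    if threshold is None:
        labels = np.where(drop12 > drop23, 1, 2)
    else:
        labels = np.where(drop12 >= threshold, 1, 2)
    return pd.Series(labels, index=med.index, name="group")


def rank_transform(values) -> np.ndarray:
    """Average ranks (mid-ranks for ties); order preserving."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty sequence")
    return rankdata(arr)


@dataclass
class TraitFitResult:
    """Fixed group effect of one trait from the mixed model."""

    coef: float
    se: float
    pvalue: float
    re_variance: float
    singular: bool
    n: int
    method: str

    def as_dict(self) -> dict:
        return {
            "group_coef": self.coef,
            "se": self.se,
            "pvalue": self.pvalue,
            "re_variance": self.re_variance,
            "singular": self.singular,
            "n": self.n,
            "method": self.method,
        }


def fit_trait_model(
    trait,
    groups,
    subfamily,
    force_zero_variance: bool = False,
    pvalue_method: str = "t",
) -> TraitFitResult:
    """Gaussian mixed model ``trait ~ group + (1 | subfamily)`` via ML.

    The reported p-value uses a t reference on the REML-rescaled standard
    error, with residual degrees of freedom debited for the variance
    component whenever it is estimated above the boundary
    (``pvalue_method="t"``, default; calibrated to ~5% type-I error at
    these tiny sample sizes), or the plain Wald normal approximation on
    the ML standard error (``pvalue_method="normal"``).  A boundary fit
    (random-effect variance at zero) is returned with ``singular=True``,
    not an error.  ``force_zero_variance`` pins the variance component at
    the boundary, reducing the fit to ordinary regression.
    """
    import statsmodels.api as sm

    y = np.asarray(trait, dtype=float)
    g = np.asarray(groups)
    fam = np.asarray(subfamily)
    if len(set(g)) < 2:
        raise ValueError("need both groups represented")
    n = len(y)
    # group indicator: 1 for group 2 (or the lexically larger label)
    levels = sorted(set(g))
    x = (g == levels[1]).astype(float)
    exog = np.column_stack([np.ones(n), x])
    p_fixed = exog.shape[1]
    n_levels = len(set(fam))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=fam)
        if force_zero_variance:
            # evaluate the model's own GLS profile at a pinned (numerically
            # zero) variance component; exact zero is singular internally
            eps = 1e-10 * max(float(np.var(y)), 1.0)
            cov_re = eps * np.eye(1)
            vcomp = np.empty(0)
            fe, _ = model.get_fe_params(cov_re, vcomp)
            scale = float(model.get_scale(fe, cov_re, vcomp))
            coef = float(fe[1])
            xtx_inv = np.linalg.inv(exog.T @ exog)
            se_ml = float(np.sqrt(scale * xtx_inv[1, 1]))
            re_var = 0.0
        else:
            res = model.fit(reml=False)
            coef = float(res.fe_params[1])
            se_ml = float(res.bse_fe[1])
            re_var = float(np.squeeze(res.cov_re))
    var_tol = 1e-8 * max(float(np.var(y)), 1e-12)
    singular = re_var <= var_tol
    if singular:
        re_var = 0.0

    if pvalue_method == "t":
        # ML scale is biased low by (n - p)/n; rescale and use a t reference
        se = se_ml * np.sqrt(n / (n - p_fixed))
        df = n - p_fixed - (0 if singular else n_levels - 1)
        df = max(df, 1)
        stat = coef / se if se > 0 else np.inf * np.sign(coef)
        pval = 2.0 * t_dist.sf(abs(stat), df)
    elif pvalue_method == "normal":
        se = se_ml
        stat = coef / se if se > 0 else np.inf * np.sign(coef)
        pval = 2.0 * norm.sf(abs(stat))
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    return TraitFitResult(
        coef=coef,
        se=float(se),
        pvalue=float(pval),
        re_variance=re_var,
        singular=bool(singular),
        n=n,
        method=pvalue_method,
    )


def compare_traits(
    traits: pd.DataFrame,
    groups: pd.Series,
    trait_columns: tuple[str, ...] = CONTINUOUS_TRAITS + ORDINAL_TRAITS,
    pvalue_method: str = "t",
) -> pd.DataFrame:
    """Run the group comparison for each trait column.

    Ordinal trait columns (``*_class``) are rank-converted first.
    """
    df = traits.set_index("taxon_id").loc[groups.index]
    rows = []
    for col in trait_columns:
        if col not in df.columns:
            continue
        vals = df[col].to_numpy(dtype=float)
        if col in ORDINAL_TRAITS:
            vals = rank_transform(vals)
        res = fit_trait_model(
            vals, groups.to_numpy(), df["subfamily"].to_numpy(), pvalue_method=pvalue_method
        )
        rows.append({"trait": col, **res.as_dict()})
    return pd.DataFrame(rows)
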