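"""Longitudinal group comparison of caregiver-report scales via GEE.

Marginal linear models (identity link, Gaussian family) are estimated with
generalized estimating equations, nesting the annual assessments at ages
2-5 within subjects under an exchangeable working correlation (AR(1) and
independence available).  Inference uses robust (sandwich) standard errors;
the overall four-group difference is a 3-df Wald test and the six pairwise
group contrasts are reported a priori without multiplicity adjustment.
Subjects with missing waves contribute their observed waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import GROUPS, WAVES

GROUP_TERMS = [f"group_{g}" for g in GROUPS[1:]]
_CORR = {
    "exchangeable": sm.cov_struct.Exchangeable,
    "ar1": sm.cov_struct.Autoregressive,
    "independence": sm.cov_struct.Independence,
}


@dataclass
class GEEFit:
    """A fitted marginal model for one scale.

    ``cov`` is the robust sandwich covariance; ``cov_naive`` the model-based
    one.  ``working_corr`` is the estimated exchangeable (or AR(1))
    correlation parameter.
    """

    scale: str
    params: pd.Series
    cov: pd.DataFrame
    cov_naive: pd.DataFrame
    working_corr: float
    corr_structure: str
    n_subjects: int
    n_observations: int
    overall_chi2: float
    overall_df: int
    overall_p: float
    alpha: float = 0.05
    _results: object = field(default=None, repr=False)

    def contrast(self, g1: str, g2: str) -> tuple[float, float, float, float]:
        """Estimate, robust SE, z and p for the mean difference g1 - g2."""
        L = pd.Series(0.0, index=self.params.index)
        for g, sign in ((g1, 1.0), (g2, -1.0)):
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if g != GROUPS[0]:
                L[f"group_{g}"] += sign
        est = float(L @ self.params)
        var = float(L @ self.cov @ L)
        if g1 == g2:
            return 0.0, 0.0, 0.0, 1.0
        if var <= 0:
            raise ValueError(f"contrast {g1} - {g2} is not estimable")
        se = np.sqrt(var)
        z = est / se
        return est, se, z, float(2 * stats.norm.sf(abs(z)))

    def pairwise_contrasts(self) -> pd.DataFrame:
        """All six pairwise group differences, unadjusted p-values."""
        rows = []
        for g1, g2 in combinations(GROUPS, 2):
            est, se, z, p = self.contrast(g2, g1)
            rows.append({"contrast": f"{g2} - {g1}", "estimate": est, "se": se, "z": z, "p": p})
        return pd.DataFrame(rows)

    def group_means(self) -> pd.Series:
        """Model-implied group means at reference covariates, first wave."""
        base = float(self.params.get("const", 0.0))
        return pd.Series(
            {g: base + (float(self.params[f"group_{g}"]) if g != GROUPS[0] else 0.0)
             for g in GROUPS}
        )

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        z = self.params.to_numpy() / se
        return pd.DataFrame(
            {"coef": self.params, "robust_se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z))}
        )


def _build_design(
    panel: pd.DataFrame,
    subjects: pd.DataFrame,
    scale: str,
    covariates: Sequence[str],
) -> pd.DataFrame:
    rows = panel[panel["scale"] == scale]
    if rows.empty:
        raise ValueError(f"panel has no observations for scale {scale!r}")
    df = rows.merge(subjects, on="subject_id", how="left", validate="many_to_one")
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates not present: {missing}")
    df = df.sort_values(["subject_id", "wave"]).reset_index(drop=True)
    df["const"] = 1.0
    for g, term in zip(GROUPS[1:], GROUP_TERMS):
        df[term] = (df["group"].astype(str) == g).astype(float)
    for w in WAVES[1:]:
        df[f"wave_{w}"] = (df["wave"] == w).astype(float)
    return df


def fit_gee(
    panel: pd.DataFrame,
    subjects: pd.DataFrame,
    scale: str,
    covariates: Sequence[str] = (),
    corr: str = "exchangeable",
    alpha: float = 0.05,
) -> GEEFit:
    """Fit the marginal group-comparison model for one scale.

    Design: intercept + exposure-group indicators (reference ``neither``) +
    wave indicators (reference age 2) + optional subject-level covariates.
    The overall group effect is the robust 3-df Wald test that all three
    group coefficients vanish.
    """
    if corr not in _CORR:
        raise ValueError(f"corr must be one of {sorted(_CORR)}")
    df = _build_design(panel, subjects, scale, covariates)
    exog_cols = ["const", *GROUP_TERMS, *[f"wave_{w}" for w in WAVES[1:]], *covariates]
    sizes = df.groupby("subject_id").size()
    if (sizes <= 1).all():
        warnings.warn(
            "all subjects contribute a single wave; GEE reduces to robust OLS",
            UserWarning, stacklevel=2,
        )
    cov_struct = _CORR[corr]()
    model = sm.GEE(
        df["value"].to_numpy(dtype=float),
        df[exog_cols].astype(float),
        groups=df["subject_id"].to_numpy(),
        family=sm.families.Gaussian(),
        cov_struct=cov_struct,
    )
    res = model.fit()
    constraint = np.zeros((3, len(exog_cols)))
    for i, term in enumerate(GROUP_TERMS):
        constraint[i, exog_cols.index(term)] = 1.0
    wt = res.wald_test(constraint, scalar=True)
    if corr == "independence":
        working = 0.0
    else:
        dep = np.atleast_1d(np.asarray(cov_struct.dep_params, dtype=float))
        working = float(dep.ravel()[0])
    return GEEFit(
        scale=scale,
        params=res.params.copy(),
        cov=pd.DataFrame(res.cov_params(), index=exog_cols, columns=exog_cols),
        cov_naive=pd.DataFrame(res.cov_naive, index=exog_cols, columns=exog_cols),
        working_corr=working,
        corr_structure=corr,
        n_subjects=int(df["subject_id"].nunique()),
        n_observations=len(df),
        overall_chi2=float(wt.statistic),
        overall_df=3,
        overall_p=float(wt.pvalue),
        alpha=alpha,
        _results=res,
    )


def pairwise_contrasts(fit: GEEFit) -> pd.DataFrame:
    """The six a-priori pairwise group comparisons for a fitted scale."""
    return fit.pairwise_contrasts()


class PanelGEE:
    """Model-style wrapper: ``PanelGEE(panel, subjects, scale).fit()``."""

    def __init__(
        self,
        panel: pd.DataFrame,
        subjects: pd.DataFrame,
        scale: str,
        covariates: Sequence[str] = (),
        corr: str = "exchangeable",
    ):
        self.panel = panel
        self.subjects = subjects
        self.scale = scale
        self.covariates = list(covariates)
        self.corr = corr

    def fit(self, alpha: float = 0.05) -> GEEFit:
        return fit_gee(
            self.panel, self.subjects, self.scale,
            covariates=self.covariates, corr=self.corr, alpha=alpha,
        )
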