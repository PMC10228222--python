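"""Hierarchical (staged) Cox modelling with block likelihood-ratio tests.

Covariate blocks are entered cumulatively — confounders first, then the
postnatal-environment scales, then the 3-df exposure-group factor — and each
transition is tested with a likelihood-ratio chi-square on the number of
parameters added (Wald block tests are available as an option).  Stage-level
p-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import COVARIATES
from .survival import GROUP_TERMS, CoxFit, fit_cox

#: Placeholder term that expands to the reference-coded group indicators.
GROUP_FACTOR = "group"

DEFAULT_ENVIRONMENT_TERMS = ("postnatal_family_stress", "social_support")


@dataclass
class StageSpec:
    """Ordered, disjoint covariate blocks entered cumulatively."""

    blocks: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, terms in self.blocks:
            dup = seen & set(terms)
            if dup:
                raise ValueError(f"stage spec is not nested: block {name!r} repeats {sorted(dup)}")
            seen |= set(terms)

    @classmethod
    def default(cls) -> "StageSpec":
        """Confounders, then postnatal environment, then the exposure factor."""
        return cls(
            blocks=[
                ("confounders", list(COVARIATES)),
                ("postnatal_environment", list(DEFAULT_ENVIRONMENT_TERMS)),
                ("exposure_group", [GROUP_FACTOR]),
            ]
        )

    def stage_terms(self) -> list[tuple[str, list[str]]]:
        """Cumulative design terms per stage, with the group factor expanded."""
        out = []
        acc: list[str] = []
        for name, terms in self.blocks:
            expanded = []
            for t in terms:
                expanded.extend(GROUP_TERMS if t == GROUP_FACTOR else [t])
            acc = acc + expanded
            out.append((name, list(acc)))
        return out


@dataclass
class StageResult:
    name: str
    n_params: int
    loglik: float
    model_chi2: float
    model_df: int
    model_p: float
    delta_chi2: float
    delta_df: int
    delta_p: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    fit: CoxFit | None = field(default=None, repr=False)


@dataclass
class StagedFitResult:
    """Per-stage fits plus the transition (block) tests."""

    stages: list[StageResult]
    loglik_null: float

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.stages)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_params": s.n_params,
                    "loglik": s.loglik,
                    "model_chi2": s.model_chi2,
                    "model_df": s.model_df,
                    "model_p": s.model_p,
                    "delta_chi2": s.delta_chi2,
                    "delta_df": s.delta_df,
                    "delta_p": s.delta_p,
                    "converged": s.converged,
                }
                for s in self.stages
            ]
        )


def staged_lr_tests(data: pd.DataFrame, spec: StageSpec, wald: bool = False) -> StagedFitResult:
    """Fit the cumulative Cox model at each stage and test each transition.

    The transition statistic is the likelihood-ratio
    ``delta_chi2 = 2 * (loglik_k - loglik_{k-1})`` on the number of added
    parameters (or, with ``wald=True``, the Wald chi-square of the added
    block).  An empty block contributes ``delta_chi2 = 0`` with 0 df.  If a
    stage fails to converge, that stage and all later ones are flagged.
    """
    stages: list[StageResult] = []
    prev_ll: float | None = None
    prev_df = 0
    loglik_null = np.nan
    carried_flag = False
    for name, terms in spec.stage_terms():
        include_group = any(t in GROUP_TERMS for t in terms)
        covs = [t for t in terms if t not in GROUP_TERMS]
        missing = [t for t in covs if t not in data.columns]
        if missing:
            raise ValueError(f"stage {name!r}: terms not present in data: {missing}")
        if not terms:
            fit = None
            ll = prev_ll if prev_ll is not None else np.nan
            npar = prev_df
            conv = not carried_flag
            flags: list[str] = []
        else:
            fit = fit_cox(data, covariates=covs, include_group=include_group)
            ll = fit.loglik
            npar = len(fit.params)
            conv = fit.converged and not carried_flag
            flags = list(fit.flags)
        if np.isnan(loglik_null) and fit is not None:
            loglik_null = fit.loglik_null
        base_ll = loglik_null if prev_ll is None else prev_ll
        model_chi2 = max(2.0 * (ll - loglik_null), 0.0) if not np.isnan(ll) else np.nan
        if wald and fit is not None and npar > prev_df:
            added = fit.params.index[~fit.params.index.isin(
                stages[-1].fit.params.index if stages and stages[-1].fit is not None else []
            )]
            b = fit.params[added].to_numpy()
            V = fit.cov.loc[added, added].to_numpy()
            delta_chi2 = float(b @ np.linalg.solve(V, b))
        else:
            delta_chi2 = max(2.0 * (ll - base_ll), 0.0) if not np.isnan(ll) else np.nan
        delta_df = npar - prev_df
        if carried_flag:
            flags.append("earlier stage failed to converge")
        stages.append(
            StageResult(
                name=name,
                n_params=npar,
                loglik=ll,
                model_chi2=model_chi2,
                model_df=npar,
                model_p=float(stats.chi2.sf(model_chi2, npar)) if npar else 1.0,
                delta_chi2=delta_chi2,
                delta_df=delta_df,
                delta_p=float(stats.chi2.sf(delta_chi2, delta_df)) if delta_df else 1.0,
                converged=conv,
                flags=flags,
                fit=fit,
            )
        )
        carried_flag = carried_flag or not conv
        prev_ll, prev_df = ll, npar
    return StagedFitResult(stages=stages, loglik_null=loglik_null)


class StagedCox:
    """Model-style wrapper: ``StagedCox(data, spec).fit()`` -> results."""

    def __init__(self, data: pd.DataFrame, spec: StageSpec | None = None):
        self.data = data
        self.spec = spec if spec is not None else StageSpec.default()

    def fit(self, wald: bool = False) -> StagedFitResult:
        return staged_lr_tests(self.data, self.spec, wald=wald)
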