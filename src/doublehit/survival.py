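"""Survival-analysis core: cumulative lifetime risk, strata equality, Cox
proportional-hazards fits and proportional-hazards diagnostics.

Lifetime risk is estimated with the product-limit (Kaplan-Meier) estimator
applied to retrospectively reported onset ages, right-censored at the age of
the diagnostic interview.  Group contrasts come from a Cox model with the
four-level exposure-group factor reference-coded against ``neither``.
Partial-likelihood maximisation is delegated to :mod:`lifelines` (Efron tie
handling); when simultaneous event and censoring times occur, events are
conventionally treated as preceding censorings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .config import GROUPS

#: Reference-coded indicator columns for the exposure-group factor.
GROUP_TERMS = [f"group_{g}" for g in GROUPS[1:]]


def encode_group(data: pd.DataFrame) -> pd.DataFrame:
    """Append reference-coded group indicators (reference = 'neither')."""
    out = data.copy()
    for g, term in zip(GROUPS[1:], GROUP_TERMS):
        out[term] = (data["group"].astype(str) == g).astype(float)
    return out


@dataclass
class KMEstimate:
    """Product-limit estimate for one stratum.

    Arrays are aligned on the distinct observed event times.  ``survival`` is
    right-continuous: ``survival[k]`` is S(t) just after ``event_times[k]``.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    label: str | None = None
    n_subjects: int = 0

    @property
    def cumulative_risk(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def risk_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)

    def plot(self, ax=None, **kw):
        """Step plot of cumulative risk against age in months."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.event_times])
        r = np.concatenate([[0.0], self.cumulative_risk])
        ax.step(t, r, where="post", label=self.label, **kw)
        ax.set_xlabel("age (months)")
        ax.set_ylabel("cumulative risk")
        return ax


def km_estimate(
    data: pd.DataFrame, by_group: bool = True
) -> dict[str, KMEstimate] | KMEstimate:
    """Kaplan-Meier cumulative lifetime risk, optionally per exposure group.

    ``data`` needs columns ``time_months`` (> 0) and ``event``; ``group`` as
    well when ``by_group``.  Ties are handled by processing all events at a
    time point together (the product-limit convention).
    """
    if data.empty:
        raise ValueError("empty survival dataset")
    if (data["time_months"] <= 0).any():
        raise ValueError("time_months must be positive")
    if not by_group:
        return _km_single(data, label=None)
    return {
        str(g): _km_single(sub, label=str(g))
        for g, sub in data.groupby("group", observed=True)
    }


def _km_single(data: pd.DataFrame, label: str | None) -> KMEstimate:
    kmf = KaplanMeierFitter().fit(data["time_months"], data["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = np.array([kmf.survival_function_at_times(t).iloc[0] for t in times])
    return KMEstimate(
        event_times=times,
        at_risk=ev["at_risk"].to_numpy(),
        n_events=ev["observed"].to_numpy(),
        survival=surv,
        label=label,
        n_subjects=len(data),
    )


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank_test(data: pd.DataFrame) -> LogRankResult:
    """K-sample log-rank test of equality of the group survival curves."""
    groups = data["group"].astype(str)
    k = groups.nunique()
    if k < 2:
        raise ValueError("logrank_test requires at least two groups")
    res = multivariate_logrank_test(data["time_months"], groups, data["event"])
    return LogRankResult(chi2=float(res.test_statistic), df=k - 1, p=float(res.p_value))


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``params`` are log hazard ratios; ``cov`` their estimated covariance.
    ``summary`` carries HRs with Wald confidence limits and two-sided
    p-values.  ``flags`` records non-convergence and monotone-likelihood
    (zero-event group) conditions rather than failing silently.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    summary: pd.DataFrame
    converged: bool
    flags: list[str] = field(default_factory=list)
    alpha: float = 0.05
    _fitter: CoxPHFitter | None = field(default=None, repr=False)
    _design: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def lr_test(self) -> tuple[float, int, float]:
        """Likelihood-ratio test of the full model against the null model."""
        chi2 = max(2.0 * (self.loglik - self.loglik_null), 0.0)
        df = len(self.params)
        return chi2, df, float(stats.chi2.sf(chi2, df))

    def group_block(self) -> tuple[np.ndarray, np.ndarray]:
        """(beta, cov) for the three exposure-group terms, in the order
        cb_only, ss_only, both — raises if the fit has no group factor."""
        missing = [t for t in GROUP_TERMS if t not in self.params.index]
        if missing:
            raise ValueError(f"fit does not include group terms {missing}")
        beta = self.params[GROUP_TERMS].to_numpy()
        cov = self.cov.loc[GROUP_TERMS, GROUP_TERMS].to_numpy()
        return beta, cov


def fit_cox(
    data: pd.DataFrame,
    covariates: Sequence[str] = (),
    include_group: bool = True,
    alpha: float = 0.05,
    penalizer: float = 0.0,
) -> CoxFit:
    """Fit a Cox model with the exposure-group factor plus covariates.

    The four-level group enters as three indicators against ``neither``.
    Non-convergence and groups with zero events (monotone partial likelihood,
    the estimate diverges) are flagged on the result, not silently ignored.
    """
    if data.empty:
        raise ValueError("empty survival dataset")
    if (data["time_months"] <= 0).any():
        raise ValueError("time_months must be positive")
    if int(data["event"].sum()) == 0:
        raise ValueError("no events in dataset; Cox model is not estimable")

    terms = list(covariates)
    df = data.copy()
    if include_group:
        df = encode_group(df)
        present = set(data["group"].astype(str))
        terms = [t for g, t in zip(GROUPS[1:], GROUP_TERMS) if g in present] + terms
    design = df[["time_months", "event", *terms]].astype(float)

    flags: list[str] = []
    if include_group:
        ev = data.groupby(data["group"].astype(str), observed=True)["event"].sum()
        zero = [g for g in GROUPS if g in ev.index and ev[g] == 0]
        if zero:
            flags.append(
                f"monotone likelihood: zero events in group(s) {zero}; "
                "the corresponding hazard-ratio estimate diverges"
            )

    converged = True
    cph = CoxPHFitter(penalizer=penalizer, alpha=alpha)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit_options = {"precision": 1e-8, "max_steps": 500}
        try:
            cph.fit(design, duration_col="time_months", event_col="event",
                    fit_options=fit_options)
        except ConvergenceError as err:
            converged = False
            flags.append(f"non-convergence: {err}")
            # retry with a small ridge penalty so diagnostics stay available
            cph = CoxPHFitter(penalizer=max(penalizer, 0.1), alpha=alpha)
            cph.fit(design, duration_col="time_months", event_col="event",
                    fit_options=fit_options)
            flags.append("refit with ridge penalizer 0.1")
    seen = set()
    for w in caught:
        msg = str(w.message)
        key = msg.lower()
        if any(s in key for s in ("convergence", "ill-conditioned", "collinear", "complete separation")):
            converged = False
            if key[:40] not in seen:  # de-duplicate repeated solver warnings
                flags.append(f"convergence warning: {msg}")
                seen.add(key[:40])

    lrt = cph.log_likelihood_ratio_test()
    pct = f"{100 * (1 - alpha):g}%"
    summary = cph.summary[
        ["coef", "exp(coef)", "se(coef)",
         f"exp(coef) lower {pct}", f"exp(coef) upper {pct}", "p"]
    ].rename(
        columns={
            "exp(coef)": "hr",
            "se(coef)": "se",
            f"exp(coef) lower {pct}": "hr_ci_low",
            f"exp(coef) upper {pct}": "hr_ci_high",
        }
    )
    return CoxFit(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        loglik=float(cph.log_likelihood_),
        loglik_null=float(cph.log_likelihood_ - lrt.test_statistic / 2.0),
        n=len(design),
        n_events=int(design["event"].sum()),
        summary=summary,
        converged=converged,
        flags=flags,
        alpha=alpha,
        _fitter=cph,
        _design=design,
    )


@dataclass
class PHTestResult:
    """Grambsch-Therneau test of the proportional-hazards assumption."""

    table: pd.DataFrame  # per-term: stat, p
    global_chi2: float
    global_df: int
    global_p: float
    transform: str


_TRANSFORMS = ("identity", "rank", "km", "log")


def schoenfeld_ph_test(fit: CoxFit, transform: str = "identity") -> PHTestResult:
    """Test proportional hazards via scaled Schoenfeld residuals.

    Regresses the Schoenfeld residuals on a transform g(t) of event time
    (identity by default; 'rank', 'km' and 'log' available) and forms the
    Grambsch-Therneau score statistics.  With unscaled residuals r_k, scaled
    residuals s_k = d * V r_k (V the coefficient covariance, d the event
    count) and w = sum_k (g_k - gbar) s_k, the per-term statistic is
    ``chi2_j = w_j^2 / (d * V_jj * sum((g-gbar)^2))`` and the global one
    ``chi2 = w' V^{-1} w / (d * sum((g-gbar)^2))``, each referred to a
    chi-square with 1 and p degrees of freedom.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}")
    if fit._fitter is None or fit._design is None:
        raise ValueError("fit does not carry its training data")
    if fit.n_events == 0:
        raise ValueError("no events; Schoenfeld residuals undefined")

    resid = fit._fitter.compute_residuals(fit._design, kind="schoenfeld")
    times = fit._design.loc[resid.index, "time_months"].to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    r = resid.to_numpy(dtype=float)[order]
    d = len(times)

    if transform == "identity":
        g = times
    elif transform == "rank":
        g = stats.rankdata(times)
    elif transform == "log":
        g = np.log(times)
    else:  # km: 1 - left-continuous KM survival at the event times
        km = _km_single(fit._design.rename(columns={}), label=None)
        g = np.array([1.0 - km.survival_at(t - 1e-12) for t in times])

    gc = g - g.mean()
    denom = float(gc @ gc)
    u = gc @ r  # length p
    V = fit.cov.to_numpy()
    w = d * (V @ u)  # = sum_k (g_k - gbar) * scaled residual s_k
    per_term = w**2 / (d * np.diag(V) * denom)
    global_chi2 = float(d * u @ V @ u / denom)
    p_terms = stats.chi2.sf(per_term, 1)
    table = pd.DataFrame({"stat": per_term, "p": p_terms}, index=fit.params.index)
    gdf = len(u)
    return PHTestResult(
        table=table,
        global_chi2=global_chi2,
        global_df=gdf,
        global_p=float(stats.chi2.sf(global_chi2, gdf)),
        transform=transform,
    )
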