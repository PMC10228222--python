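"""The double-hit analysis as a model object.

``DoubleHitModel`` bundles a cohort (and optionally its longitudinal panel)
with the analysis plan; ``fit()`` runs, per disorder, the proportional-
hazards diagnostic, Kaplan-Meier cumulative lifetime risk by exposure
group, the four-group log-rank test, the three-stage hierarchical Cox
model, the covariate-adjusted group hazard ratios and the synergy-index Z
test; and, per panel scale, the GEE group comparison.  The returned
``DoubleHitResults`` carries every stage and renders the field's customary
summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import COVARIATES, GROUPS
from .gee import GEEFit, fit_gee
from .simulate import Cohort, read_panel_csv
from .staged import DEFAULT_ENVIRONMENT_TERMS, StagedFitResult, StageSpec, staged_lr_tests
from .survival import CoxFit, KMEstimate, PHTestResult, fit_cox, km_estimate, logrank_test, schoenfeld_ph_test
from .synergy import (
    SynergyResult,
    SynergyTable,
    SynergyUndefinedError,
    ZeroCellError,
    synergy_from_cox,
    synergy_from_table,
)


@dataclass
class DisorderAnalysis:
    """Everything computed for one disorder outcome."""

    disorder: str
    km: dict[str, KMEstimate]
    logrank: object
    ph_test: PHTestResult | None
    staged: StagedFitResult | None
    cox: CoxFit
    synergy: SynergyResult | None
    synergy_unadjusted: SynergyResult | None
    table: SynergyTable
    errors: dict[str, str] = field(default_factory=dict)

    def cumulative_rates(self, horizon: float = 60.0) -> pd.Series:
        """KM cumulative lifetime risk per group at `horizon` months."""
        return pd.Series({g: est.risk_at(horizon) for g, est in self.km.items()})


@dataclass
class DoubleHitResults:
    """Fitted results across disorders and panel scales."""

    analyses: dict[str, DisorderAnalysis]
    gee_fits: dict[str, GEEFit]
    descriptives: dict
    alpha: float

    def risk_table(self, horizon: float = 60.0) -> pd.DataFrame:
        """Per disorder: group cumulative rates, adjusted HRs with CI and p,
        and the synergy index with its two-sided p."""
        rows = []
        for name, an in self.analyses.items():
            row: dict = {"disorder": name}
            rates = an.cumulative_rates(horizon)
            for g in GROUPS:
                row[f"rate_{g}"] = rates.get(g, np.nan)
            for g in GROUPS[1:]:
                term = f"group_{g}"
                if term in an.cox.summary.index:
                    s = an.cox.summary.loc[term]
                    row[f"hr_{g}"] = s["hr"]
                    row[f"hr_{g}_ci_low"] = s["hr_ci_low"]
                    row[f"hr_{g}_ci_high"] = s["hr_ci_high"]
                    row[f"hr_{g}_p"] = s["p"]
            if an.synergy is not None:
                row["si"] = an.synergy.si
                row["si_p"] = an.synergy.p
                row["si_synergistic"] = an.synergy.synergistic
                row["si_appreciable"] = an.synergy.appreciable
            else:
                row["si"] = np.nan
                row["si_p"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def staged_table(self) -> pd.DataFrame:
        """Stage chi-squares per disorder (rows) in the three-step layout."""
        rows = []
        for name, an in self.analyses.items():
            if an.staged is None:
                rows.append({"disorder": name, "error": an.errors.get("staged", "failed")})
                continue
            row = {"disorder": name}
            for s in an.staged.stages:
                row[f"{s.name}_chi2"] = s.model_chi2
                row[f"{s.name}_delta_chi2"] = s.delta_chi2
                row[f"{s.name}_delta_df"] = s.delta_df
                row[f"{s.name}_delta_p"] = s.delta_p
            row["logrank_chi2"] = an.logrank.chi2
            row["logrank_p"] = an.logrank.p
            rows.append(row)
        return pd.DataFrame(rows)

    def gee_table(self) -> pd.DataFrame:
        """Per scale: group means, overall group test, significant contrasts."""
        rows = []
        for scale, fit in self.gee_fits.items():
            row = {"scale": scale}
            means = fit.group_means()
            for g in GROUPS:
                row[f"mean_{g}"] = means[g]
            row["overall_chi2"] = fit.overall_chi2
            row["overall_p"] = fit.overall_p
            sig = fit.pairwise_contrasts().query("p < @fit.alpha")["contrast"].tolist()
            row["significant_contrasts"] = "; ".join(sig)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self, horizon: float = 60.0) -> str:
        lines = ["Double-hit analysis summary", "=" * 29, ""]
        d = self.descriptives
        lines.append(
            f"N = {d['n_total']}; storm-exposed {d['ss_exposed_pct']}%, "
            f"cannabis-exposed {d['cb_exposed_pct']}%, both {d['dual_exposed_pct']}%"
        )
        lines.append("")
        for name, an in self.analyses.items():
            lines.append(f"[{name}] log-rank chi2({an.logrank.df}) = "
                         f"{an.logrank.chi2:.2f}, p = {an.logrank.p:.4g}")
            if an.synergy is not None:
                s = an.synergy
                flag = " (synergistic)" if s.synergistic else ""
                lines.append(
                    f"  SI = {s.si:.2f}, z = {s.z:.2f}, p = {s.p:.4g}{flag}"
                )
            elif "synergy" in an.errors:
                lines.append(f"  SI undefined: {an.errors['synergy']}")
        return "\n".join(lines)


class DoubleHitModel:
    """Configure and run the full dual-exposure analysis.

    Parameters
    ----------
    cohort
        A :class:`~doublehit.simulate.Cohort` (simulated or loaded).
    panel
        Optional long panel DataFrame (subject_id, wave, scale, value).
        When present, subject-mean parenting stress and social support are
        added as the stage-2 postnatal-environment block, and GEE models are
        fitted per scale.
    covariates
        Confounder block; defaults to the canonical eleven.
    """

    def __init__(
        self,
        cohort: Cohort,
        panel: pd.DataFrame | None = None,
        disorders: Sequence[str] | None = None,
        covariates: Sequence[str] = COVARIATES,
        stage_spec: StageSpec | None = None,
        alpha: float = 0.05,
        stress_scale: str = "psi_total",
        support_scale: str = "mos_total",
    ):
        self.cohort = cohort
        self.panel = panel
        self.disorders = list(disorders) if disorders is not None else cohort.disorders
        self.covariates = list(covariates)
        self.alpha = alpha
        self.stress_scale = stress_scale
        self.support_scale = support_scale
        if stage_spec is not None:
            self.stage_spec = stage_spec
        elif panel is not None:
            self.stage_spec = StageSpec.default()
        else:
            self.stage_spec = StageSpec(
                blocks=[("confounders", list(covariates)), ("exposure_group", ["group"])]
            )

    @classmethod
    def from_csv(cls, cohort_csv: str | Path, panel_csv: str | Path | None = None, **kw):
        cohort = Cohort.from_csv(cohort_csv)
        panel = read_panel_csv(panel_csv) if panel_csv is not None else None
        return cls(cohort, panel=panel, **kw)

    # ------------------------------------------------------------------
    def _environment_scores(self) -> pd.DataFrame | None:
        """Subject-level means of the two postnatal-environment scales."""
        if self.panel is None:
            return None
        out = pd.DataFrame({"subject_id": self.cohort.subjects["subject_id"]})
        for scale, col in (
            (self.stress_scale, DEFAULT_ENVIRONMENT_TERMS[0]),
            (self.support_scale, DEFAULT_ENVIRONMENT_TERMS[1]),
        ):
            sub = self.panel[self.panel["scale"] == scale]
            means = sub.groupby("subject_id")["value"].mean().rename(col)
            out = out.merge(means, on="subject_id", how="left")
            filler = means.mean() if len(means) else 0.0
            out[col] = out[col].fillna(filler)
        return out

    def fit(self) -> DoubleHitResults:
        from .pipeline import descriptives  # cheap, avoids a module cycle

        env = self._environment_scores()
        analyses: dict[str, DisorderAnalysis] = {}
        for disorder in self.disorders:
            data = self.cohort.survival_data(disorder)
            if env is not None:
                data = data.merge(env, on="subject_id", how="left")
            errors: dict[str, str] = {}

            km = km_estimate(data, by_group=True)
            lr = logrank_test(data)

            adj = self.covariates + (
                list(DEFAULT_ENVIRONMENT_TERMS) if env is not None else []
            )
            cox = fit_cox(data, covariates=adj, alpha=self.alpha)

            try:
                ph = schoenfeld_ph_test(cox)
            except ValueError as e:
                ph, errors["ph_test"] = None, str(e)

            try:
                staged = staged_lr_tests(data, self.stage_spec)
            except ValueError as e:
                staged, errors["staged"] = None, str(e)

            table = SynergyTable.from_cohort(self.cohort, disorder)
            try:
                syn = synergy_from_cox(cox, alpha=self.alpha)
            except (SynergyUndefinedError, ValueError) as e:
                syn, errors["synergy"] = None, str(e)
            try:
                syn_u = synergy_from_table(table, alpha=self.alpha)
            except (SynergyUndefinedError, ZeroCellError, ValueError) as e:
                syn_u, errors["synergy_unadjusted"] = None, str(e)

            analyses[disorder] = DisorderAnalysis(
                disorder=disorder, km=km, logrank=lr, ph_test=ph, staged=staged,
                cox=cox, synergy=syn, synergy_unadjusted=syn_u, table=table,
                errors=errors,
            )

        gee_fits: dict[str, GEEFit] = {}
        if self.panel is not None:
            for scale in sorted(self.panel["scale"].unique()):
                gee_fits[scale] = fit_gee(
                    self.panel, self.cohort.subjects, scale,
                    covariates=self.covariates, alpha=self.alpha,
                )

        return DoubleHitResults(
            analyses=analyses,
            gee_fits=gee_fits,
            descriptives=descriptives(self.cohort),
            alpha=self.alpha,
        )
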