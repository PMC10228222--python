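"""Run configuration, descriptive bookkeeping and report assembly.

``run_pipeline`` executes the full analysis — simulate or load the cohort
and panel, descriptive exposure percentages, Kaplan-Meier and log-rank per
disorder, the staged Cox model, adjusted hazard ratios with the synergy
test, and the GEE panel comparison — and writes every table as CSV plus a
JSON summary and a log recording the seed.  Stage failures produce partial
output plus a machine-readable error manifest instead of aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import GROUPS, ConfigError, ScenarioConfig, default_scenario
from .model import DoubleHitModel, DoubleHitResults
from .simulate import Cohort, generate_cohort, generate_panel, read_panel_csv
from .staged import StageSpec

logger = logging.getLogger("doublehit")


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (reporting convention)."""
    if total == 0:
        return 0.0
    raw = Decimal(100 * count) / Decimal(total)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def descriptives(cohort: Cohort) -> dict:
    """Group counts and marginal exposure percentages for a cohort.

    Percentages are rounded half-up to one decimal; empty groups yield 0.0.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    subj = cohort.subjects
    n = len(subj)
    counts = {g: int((subj["group"].astype(str) == g).sum()) for g in GROUPS}
    ss = int(subj["exposure_ss"].sum())
    cb = int(subj["exposure_cb"].sum())
    dual = counts["both"]
    return {
        "n_total": n,
        "group_counts": counts,
        "group_pct": {g: _pct(c, n) for g, c in counts.items()},
        "ss_exposed_n": ss,
        "ss_exposed_pct": _pct(ss, n),
        "ss_unexposed_n": n - ss,
        "ss_unexposed_pct": _pct(n - ss, n),
        "cb_exposed_n": cb,
        "cb_exposed_pct": _pct(cb, n),
        "dual_exposed_n": dual,
        "dual_exposed_pct": _pct(dual, n),
    }


@dataclass
class RunConfig:
    """One analysis run: data source, analysis plan, outputs.

    ``cohort_csv`` may be the literal string ``"simulate"`` (the default) to
    draw the cohort and panel from ``scenario``.
    """

    cohort_csv: str = "simulate"
    panel_csv: str | None = None
    scenario: ScenarioConfig = field(default_factory=default_scenario)
    disorders: list[str] | None = None
    alpha: float = 0.05
    outdir: str = "doublehit_output"
    seed: int | None = None

    def validate(self) -> "RunConfig":
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.cohort_csv != "simulate":
            if not Path(self.cohort_csv).exists():
                raise ConfigError(f"cohort_csv does not exist: {self.cohort_csv}")
            if self.panel_csv is not None and not Path(self.panel_csv).exists():
                raise ConfigError(f"panel_csv does not exist: {self.panel_csv}")
        if self.cohort_csv == "simulate":
            self.scenario.validate()
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "scenario" in data:
            data["scenario"] = ScenarioConfig.from_dict(data["scenario"])
        return cls(**data).validate()

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["scenario"] = self.scenario.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class ReportBundle:
    outdir: Path
    results: DoubleHitResults
    errors: dict

    @property
    def ok(self) -> bool:
        return not self.errors


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Outputs: cohort.csv, panel.csv, descriptives.json, km_curves.csv,
    logrank.csv, staged_cox.csv, risk_table.csv, gee_table.csv,
    summary.json, run.log and (when any stage failed) errors.json.
    Identical configs (including seed) produce identical bundles.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    errors: dict[str, str] = {}
    try:
        scenario = config.scenario
        if config.seed is not None:
            scenario = scenario.replace(seed=config.seed)
        logger.info("doublehit %s; seed=%s", __version__, scenario.seed)

        if config.cohort_csv == "simulate":
            cohort = generate_cohort(scenario)
            panel = generate_panel(cohort, scenario) if scenario.panel_scales else None
            logger.info("simulated cohort n=%d, panel rows=%s",
                        cohort.n, len(panel) if panel is not None else 0)
        else:
            cohort = Cohort.from_csv(config.cohort_csv)
            panel = read_panel_csv(config.panel_csv) if config.panel_csv else None
            logger.info("loaded cohort n=%d from %s", cohort.n, config.cohort_csv)

        cohort.to_csv(outdir / "cohort.csv")
        if panel is not None:
            panel.to_csv(outdir / "panel.csv", index=False)

        model = DoubleHitModel(
            cohort, panel=panel, disorders=config.disorders, alpha=config.alpha
        )
        results = model.fit()

        desc = results.descriptives
        (outdir / "descriptives.json").write_text(json.dumps(desc, indent=2))

        km_rows = []
        for name, an in results.analyses.items():
            for g, est in an.km.items():
                for t, r, s in zip(est.event_times, est.cumulative_risk, est.survival):
                    km_rows.append(
                        {"disorder": name, "group": g, "time_months": t,
                         "cumulative_risk": r, "survival": s}
                    )
            for key, msg in an.errors.items():
                errors[f"{name}.{key}"] = msg
        pd.DataFrame(km_rows).to_csv(outdir / "km_curves.csv", index=False)
        pd.DataFrame(
            [{"disorder": n, "chi2": a.logrank.chi2, "df": a.logrank.df, "p": a.logrank.p}
             for n, a in results.analyses.items()]
        ).to_csv(outdir / "logrank.csv", index=False)
        results.staged_table().to_csv(outdir / "staged_cox.csv", index=False)
        results.risk_table().to_csv(outdir / "risk_table.csv", index=False)
        if results.gee_fits:
            results.gee_table().to_csv(outdir / "gee_table.csv", index=False)

        summary = {
            "version": __version__,
            "seed": scenario.seed if config.cohort_csv == "simulate" else None,
            "alpha": config.alpha,
            "descriptives": desc,
            "disorders": {
                name: {
                    "logrank_chi2": an.logrank.chi2,
                    "logrank_p": an.logrank.p,
                    "si": None if an.synergy is None else an.synergy.si,
                    "si_p": None if an.synergy is None else an.synergy.p,
                    "synergistic": bool(an.synergy.synergistic) if an.synergy else None,
                    "cox_converged": an.cox.converged,
                    "flags": an.cox.flags,
                }
                for name, an in results.analyses.items()
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as e:  # partial output + manifest, never a silent loss
        errors["pipeline"] = f"{type(e).__name__}: {e}"
        logger.exception("pipeline failure")
        results = None
        raise
    finally:
        if errors:
            (outdir / "errors.json").write_text(json.dumps(errors, indent=2))
        logger.removeHandler(handler)
        handler.close()
    return ReportBundle(outdir=outdir, results=results, errors=errors)
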