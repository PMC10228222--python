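"""Synthetic dual-exposure cohorts and longitudinal panels.

Generates subject-level cohorts with two binary exposures (four groups),
eleven confounders, per-disorder onset ages under a proportional-hazards
law with right-censoring at a simulated interview age, and a long-format
panel of caregiver-report scales at ages 2-5 with exchangeable
within-subject correlation and wave-level missingness.

The onset-time law is exponential by default (constant hazard per month),
optionally piecewise-constant over age bands.  All randomness flows through
``numpy.random.default_rng(config.seed)``, so a config fully determines its
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import COVARIATES, GROUPS, WAVES, ConfigError, ScenarioConfig

SUBJECT_COLUMNS = ["subject_id", "group", "exposure_ss", "exposure_cb", *COVARIATES]
EVENT_COLUMNS = ["subject_id", "disorder", "time_months", "event"]


def group_label(exposure_ss: int, exposure_cb: int) -> str:
    """Deterministic four-level group from the two exposure flags."""
    return GROUPS[2 * int(bool(exposure_ss)) + int(bool(exposure_cb))]


@dataclass
class Cohort:
    """A simulated or loaded cohort.

    ``subjects`` has one row per child (exposures + 11 confounders);
    ``events`` one row per child per disorder (onset or censoring age in
    months, event flag).
    """

    subjects: pd.DataFrame
    events: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def disorders(self) -> list[str]:
        return list(self.events["disorder"].unique())

    def survival_data(self, disorder: str) -> pd.DataFrame:
        """Per-subject rows (time_months, event, group, covariates) for one disorder."""
        ev = self.events[self.events["disorder"] == disorder]
        if ev.empty:
            raise KeyError(f"no events recorded for disorder {disorder!r}")
        return ev.drop(columns="disorder").merge(self.subjects, on="subject_id")

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per subject per disorder, with covariates."""
        return self.events.merge(self.subjects, on="subject_id")[
            ["subject_id", "group", "exposure_ss", "exposure_cb", *COVARIATES,
             "disorder", "time_months", "event"]
        ]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        long = pd.read_csv(path)
        missing = set(SUBJECT_COLUMNS + ["disorder", "time_months", "event"]) - set(long.columns)
        if missing:
            raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
        subjects = (
            long[SUBJECT_COLUMNS].drop_duplicates("subject_id").reset_index(drop=True)
        )
        events = long[EVENT_COLUMNS].reset_index(drop=True)
        return cls(subjects=subjects, events=events)


def _draw_groups(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Group index per subject: exact counts when sizes are given."""
    if config.group_sizes is not None:
        idx = np.repeat(np.arange(4), config.group_sizes)
    else:
        idx = rng.choice(4, size=config.n_total, p=np.asarray(config.group_probs))
    return rng.permutation(idx)


def _draw_covariates(
    n: int, group_idx: np.ndarray, assoc: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Independent confounder draws; `assoc` shifts the two storm-severity
    scores for storm-exposed groups (optional confounding knob, default off)."""
    ss_exposed = np.isin(group_idx, (2, 3)).astype(float)
    cov = pd.DataFrame(
        {
            "child_sex": rng.binomial(1, 0.534, n),
            "child_race": rng.choice(4, n, p=[0.41, 0.19, 0.09, 0.31]),
            "child_ethnicity": rng.binomial(1, 0.577, n),
            "maternal_age": rng.normal(0.0, 1.0, n),
            "marital_status": rng.binomial(1, 0.5, n),
            "parity": np.minimum(rng.poisson(1.2, n), 5),
            "ses_class": rng.choice(3, n, p=[0.40, 0.35, 0.25]),
            "normative_stress": rng.choice(3, n, p=[0.50, 0.30, 0.20]),
            "prenatal_substance_use": rng.binomial(1, 0.25, n),
            "ss_objective_severity": rng.normal(0.0, 1.0, n) + assoc * ss_exposed,
            "ss_subjective_ptsd": rng.normal(0.0, 1.0, n) + assoc * ss_exposed,
        }
    )
    return cov[list(COVARIATES)]


def _piecewise_onset(
    rates: np.ndarray, breakpoints: np.ndarray, scale: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample onset times under a piecewise-constant hazard ``rates * scale_i``
    by inverting the cumulative hazard at a unit-exponential draw."""
    e = rng.exponential(1.0, size=len(scale))
    bounds = np.concatenate([[0.0], breakpoints, [np.inf]])
    widths = np.diff(bounds)[:-1]  # finite band widths
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * widths)])  # per unit scale
    target = e / scale
    band = np.searchsorted(cum, target, side="right") - 1
    band = np.clip(band, 0, len(rates) - 1)
    return bounds[band] + (target - cum[band]) / rates[band]


def generate_cohort(config: ScenarioConfig) -> Cohort:
    """Simulate a cohort under ``config``.

    Onset age for disorder *d* of subject *i* in group *g* is drawn from the
    hazard ``lambda_d(t) * HR_{d,g} * exp(x_i . beta)`` and right-censored at
    an interview age uniform over ``followup_age_months``.  With
    ``round_to_month`` times are rounded up to whole months.
    """
    config.validate()
    if not config.disorders:
        raise ConfigError("disorders: generate_cohort requires at least one disorder")
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    gidx = _draw_groups(config, rng)
    subjects = _draw_covariates(n, gidx, config.exposure_covariate_assoc, rng)
    subjects.insert(0, "exposure_cb", np.isin(gidx, (1, 3)).astype(int))
    subjects.insert(0, "exposure_ss", np.isin(gidx, (2, 3)).astype(int))
    subjects.insert(0, "group", pd.Categorical.from_codes(gidx, categories=list(GROUPS)))
    subjects.insert(0, "subject_id", np.arange(1, n + 1))

    lin = subjects[list(COVARIATES)].to_numpy(dtype=float) @ config.covariate_effects
    frailty_scale = np.exp(lin)
    censor = rng.uniform(*config.followup_age_months, size=n)

    frames = []
    for name, spec in config.disorders.items():
        scale = spec.hazard_ratios[gidx] * frailty_scale
        rates = spec.rates
        if len(rates) == 1:
            onset = rng.exponential(1.0, size=n) / (rates[0] * scale)
        else:
            onset = _piecewise_onset(rates, np.asarray(spec.breakpoints), scale, rng)
        time = np.minimum(onset, censor)
        event = (onset <= censor).astype(int)
        if config.round_to_month:
            time = np.ceil(time)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subjects["subject_id"],
                    "disorder": name,
                    "time_months": time,
                    "event": event,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    return Cohort(subjects=subjects, events=events)


def generate_panel(cohort: Cohort, config: ScenarioConfig) -> pd.DataFrame:
    """Simulate the ages-2-5 panel of caregiver-report scales.

    For each subject and scale, score at wave *w* is
    ``mean[group, w] + b_i + e_iw`` with ``b_i ~ N(0, rho * sd^2)`` and
    ``e_iw ~ N(0, (1-rho) * sd^2)`` — an exchangeable within-subject
    correlation of ``rho``.  Whole waves go missing independently with
    probability ``missing_rate`` (a missed annual visit drops all scales),
    and scores are clipped to each instrument's range.

    Returns a long DataFrame with columns subject_id, wave, scale, value.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    config.validate()
    if not config.panel_scales:
        raise ConfigError("panel_scales: generate_panel requires at least one scale")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = cohort.n
    gidx = np.asarray(cohort.subjects["group"].cat.codes if
                      isinstance(cohort.subjects["group"].dtype, pd.CategoricalDtype)
                      else [GROUPS.index(g) for g in cohort.subjects["group"]])
    rho = config.within_subject_corr
    present = rng.random((n, len(WAVES))) >= config.missing_rate

    frames = []
    for scale_name, spec in config.panel_scales.items():
        mm = spec.mean_matrix()  # 4 x n_waves
        b = rng.normal(0.0, spec.sd * np.sqrt(rho), size=n)
        e = rng.normal(0.0, spec.sd * np.sqrt(1.0 - rho), size=(n, len(WAVES)))
        values = mm[gidx, :] + b[:, None] + e
        values = np.clip(values, spec.lo, spec.hi)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(cohort.subjects["subject_id"].to_numpy(), len(WAVES)),
                    "wave": np.tile(WAVES, n),
                    "scale": scale_name,
                    "value": values.ravel(),
                    "_present": present.ravel(),
                }
            )
        )
    panel = pd.concat(frames, ignore_index=True)
    panel = panel[panel.pop("_present")].reset_index(drop=True)
    return panel


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    missing = {"subject_id", "wave", "scale", "value"} - set(panel.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    return panel
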