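"""Scenario and run configuration for dual-exposure cohort studies.

A scenario describes a four-group cohort defined by two binary early-life
exposures — prenatal disaster-related stress ("SS") and perinatal maternal
cannabis use ("CB") — together with the generative model for retrospectively
dated disorder onsets and for the longitudinal family-environment panel.
Group order throughout the package is ``(neither, cb_only, ss_only, both)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

#: Canonical exposure-group labels, in the order used everywhere.
GROUPS: tuple[str, ...] = ("neither", "cb_only", "ss_only", "both")

#: The eleven subject-level confounders carried by every cohort.
COVARIATES: tuple[str, ...] = (
    "child_sex",
    "child_race",
    "child_ethnicity",
    "maternal_age",
    "marital_status",
    "parity",
    "ses_class",
    "normative_stress",
    "prenatal_substance_use",
    "ss_objective_severity",
    "ss_subjective_ptsd",
)

#: Panel waves: child age in years at each annual assessment.
WAVES: tuple[int, ...] = (2, 3, 4, 5)


class ConfigError(ValueError):
    """A configuration field violates its invariant; the message names it."""


@dataclass
class DisorderSpec:
    """Generative onset model for one lifetime disorder.

    Parameters
    ----------
    baseline_hazard
        Event rate per person-month in the unexposed group, either a single
        constant (exponential onsets) or one rate per age band when
        ``breakpoints`` is given (piecewise-constant hazard).
    hr_ss, hr_cb, hr_both
        Hazard ratios of the three exposed groups versus ``neither``.
    breakpoints
        Ascending interior band boundaries in months; ``len(baseline_hazard)``
        must equal ``len(breakpoints) + 1``.
    """

    baseline_hazard: float | Sequence[float]
    hr_ss: float = 1.0
    hr_cb: float = 1.0
    hr_both: float = 1.0
    breakpoints: tuple[float, ...] = ()

    @property
    def hazard_ratios(self) -> np.ndarray:
        """HRs in group order (neither, cb_only, ss_only, both)."""
        return np.array([1.0, self.hr_cb, self.hr_ss, self.hr_both])

    @property
    def rates(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.baseline_hazard, dtype=float))

    def validate(self, name: str = "disorder") -> None:
        rates = self.rates
        if np.any(rates <= 0):
            raise ConfigError(f"{name}.baseline_hazard must be positive")
        if len(rates) != len(self.breakpoints) + 1:
            raise ConfigError(
                f"{name}.baseline_hazard needs len(breakpoints)+1 rates, "
                f"got {len(rates)} rates for {len(self.breakpoints)} breakpoints"
            )
        if list(self.breakpoints) != sorted(self.breakpoints) or any(
            b <= 0 for b in self.breakpoints
        ):
            raise ConfigError(f"{name}.breakpoints must be positive and ascending")
        for attr in ("hr_ss", "hr_cb", "hr_both"):
            if getattr(self, attr) <= 0:
                raise ConfigError(f"{name}.{attr} must be > 0")


@dataclass
class PanelScaleSpec:
    """Generative model for one caregiver-report scale across waves.

    ``means`` is a 4x4 (group x wave) matrix, or one value per group which is
    held constant over waves.  Simulated scores are clipped to the
    instrument's printed range ``(lo, hi)``.
    """

    means: Sequence[Sequence[float]] | Sequence[float]
    sd: float
    lo: float
    hi: float

    def mean_matrix(self) -> np.ndarray:
        m = np.asarray(self.means, dtype=float)
        if m.ndim == 1:
            m = np.tile(m[:, None], (1, len(WAVES)))
        return m

    def validate(self, name: str = "scale") -> None:
        m = np.asarray(self.means, dtype=float)
        if m.shape not in ((4,), (4, len(WAVES))):
            raise ConfigError(
                f"{name}.means must have shape (4,) or (4, {len(WAVES)}), got {m.shape}"
            )
        if self.sd < 0:
            raise ConfigError(f"{name}.sd must be >= 0")
        if not self.lo < self.hi:
            raise ConfigError(f"{name}: lo must be < hi")
        mm = self.mean_matrix()
        if np.any(mm < self.lo) or np.any(mm > self.hi):
            raise ConfigError(f"{name}.means fall outside the instrument range")


@dataclass
class ScenarioConfig:
    """Everything needed to simulate one cohort plus its panel.

    Either ``group_sizes`` (exact counts summing to ``n_total``) or
    ``group_probs`` (multinomial sampling) fixes the exposure-group split.
    ``covariate_effects`` are shared log-hazard coefficients for the eleven
    confounders, applied to every disorder.
    """

    n_total: int = 163
    group_sizes: tuple[int, int, int, int] | None = (70, 27, 53, 13)
    group_probs: tuple[float, float, float, float] | None = None
    disorders: dict[str, DisorderSpec] = field(default_factory=dict)
    covariate_effects: Sequence[float] = field(
        default_factory=lambda: np.zeros(len(COVARIATES))
    )
    followup_age_months: tuple[float, float] = (24.0, 60.0)
    panel_scales: dict[str, PanelScaleSpec] = field(default_factory=dict)
    within_subject_corr: float = 0.5
    missing_rate: float = 0.15
    exposure_covariate_assoc: float = 0.0
    round_to_month: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)

    # -- validation -----------------------------------------------------
    def validate(self) -> "ScenarioConfig":
        if self.n_total <= 0:
            raise ConfigError("n_total must be positive")
        if self.group_sizes is None and self.group_probs is None:
            raise ConfigError("one of group_sizes or group_probs is required")
        if self.group_sizes is not None:
            if len(self.group_sizes) != 4 or any(s < 0 for s in self.group_sizes):
                raise ConfigError("group_sizes must be four non-negative counts")
            if sum(self.group_sizes) != self.n_total:
                raise ConfigError(
                    f"group_sizes sum to {sum(self.group_sizes)}, not n_total={self.n_total}"
                )
        if self.group_probs is not None:
            p = np.asarray(self.group_probs, dtype=float)
            if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ConfigError("group_probs must be four probabilities summing to 1")
        if not self.disorders and not self.panel_scales:
            raise ConfigError("disorders: at least one disorder or panel scale required")
        for name, spec in self.disorders.items():
            spec.validate(f"disorders[{name}]")
        if len(self.covariate_effects) != len(COVARIATES):
            raise ConfigError(
                f"covariate_effects must have length {len(COVARIATES)}, "
                f"got {len(self.covariate_effects)}"
            )
        lo, hi = self.followup_age_months
        if not 0 < lo <= hi:
            raise ConfigError("followup_age_months must satisfy 0 < lo <= hi")
        if not 0 <= self.within_subject_corr < 1:
            raise ConfigError("within_subject_corr must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        for name, spec in self.panel_scales.items():
            spec.validate(f"panel_scales[{name}]")
        return self

    def replace(self, **kw) -> "ScenarioConfig":
        """Return a copy with fields replaced (disorders/panel deep-copied)."""
        new = dataclasses.replace(self, **kw)
        if "disorders" not in kw:
            new.disorders = {k: dataclasses.replace(v) for k, v in self.disorders.items()}
        if "panel_scales" not in kw:
            new.panel_scales = {
                k: dataclasses.replace(v) for k, v in self.panel_scales.items()
            }
        return new

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple, np.ndarray)):
                return [plain(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        d["disorders"] = {
            k: v if isinstance(v, DisorderSpec) else DisorderSpec(**v)
            for k, v in d.get("disorders", {}).items()
        }
        d["panel_scales"] = {
            k: v if isinstance(v, PanelScaleSpec) else PanelScaleSpec(**v)
            for k, v in d.get("panel_scales", {}).items()
        }
        for key in ("group_sizes", "group_probs", "followup_age_months"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load from a YAML or JSON file mirroring the field names."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        return cls.from_dict(data).validate()

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


def additive_null_config(base: ScenarioConfig) -> ScenarioConfig:
    """Impose exact additivity of excess hazards on every disorder.

    Sets ``hr_both = hr_ss + hr_cb - 1`` so that the synergy index
    ``(hr_both - 1) / (hr_ss + hr_cb - 2)`` equals 1 exactly.  This is the
    null scenario for type-I-error studies of the synergy Z test.

    Raises
    ------
    ConfigError
        If ``hr_ss + hr_cb <= 2`` for any disorder: the synergy index has a
        non-positive denominator there and no additivity null exists.
    """
    new = base.replace()
    for name, spec in new.disorders.items():
        if spec.hr_ss + spec.hr_cb <= 2:
            raise ConfigError(
                f"disorders[{name}]: hr_ss + hr_cb must exceed 2 to define the "
                f"additive null (got {spec.hr_ss} + {spec.hr_cb})"
            )
        spec.hr_both = spec.hr_ss + spec.hr_cb - 1
    return new


def _rate_for(cum_risk: float, horizon: float = 60.0) -> float:
    """Constant monthly hazard giving the target cumulative risk by `horizon`."""
    return -np.log1p(-cum_risk) / horizon


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The study-sized default: N=163 split 70/27/53/13.

    Two composite disorder outcomes are configured.  Group hazard ratios for
    disruptive behavioural disorders are (SS 6.4, CB 9.4, both 31.2) and for
    anxiety disorders (SS 3.3, CB 2.35, both 7.89); baseline hazards give
    reference-group cumulative risks of about 2.9% and 20% by age 60 months.
    Confounder effects default to zero (no confounding), and the panel scales
    emulate the observed ordering: dual-exposure families have the highest
    parenting stress and the lowest social support, single-storm-exposure
    families resemble the reference group.
    """
    disorders = {
        "any_dbd": DisorderSpec(
            baseline_hazard=_rate_for(0.029), hr_ss=6.4, hr_cb=9.4, hr_both=31.2
        ),
        "any_anxiety": DisorderSpec(
            baseline_hazard=_rate_for(0.20), hr_ss=3.3, hr_cb=2.35, hr_both=7.89
        ),
    }
    # group order: neither, cb_only, ss_only, both
    panel = {
        "psi_total": PanelScaleSpec([64.0, 72.0, 65.0, 78.0], sd=12.0, lo=36, hi=138),
        "psi_parental_distress": PanelScaleSpec([22.0, 25.0, 22.5, 27.0], sd=5.0, lo=12, hi=56),
        "psi_difficult_child": PanelScaleSpec([21.0, 24.0, 21.5, 26.0], sd=5.0, lo=12, hi=57),
        "psi_dysfunctional_interaction": PanelScaleSpec([21.0, 23.0, 21.0, 25.0], sd=5.0, lo=12, hi=50),
        "mos_total": PanelScaleSpec([3.9, 3.5, 3.85, 3.1], sd=0.6, lo=1, hi=5),
        "mos_emotional": PanelScaleSpec([3.9, 3.5, 3.85, 3.1], sd=0.7, lo=1, hi=5),
        "mos_tangible": PanelScaleSpec([3.8, 3.4, 3.75, 3.0], sd=0.7, lo=1, hi=5),
        "mos_affectionate": PanelScaleSpec([4.0, 3.7, 3.95, 3.3], sd=0.7, lo=1, hi=5),
        "mos_positive_interaction": PanelScaleSpec([3.9, 3.6, 3.85, 3.2], sd=0.7, lo=1, hi=5),
    }
    return ScenarioConfig(disorders=disorders, panel_scales=panel, seed=seed).validate()
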