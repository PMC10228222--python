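"""Rothman's synergy index for additive interaction between two exposures.

Two exposures A and B act *additively* when the excess risk of joint
exposure equals the sum of the single-exposure excess risks.  The synergy
index quantifies departure from additivity on the ratio scale:

    SI = (RR_AB - 1) / ((RR_A - 1) + (RR_B - 1))

where RR_A, RR_B and RR_AB are the risk (here: hazard) ratios of the two
singly-exposed groups and the doubly-exposed group against the unexposed
reference.  SI = 1 is exact additivity, SI > 1 superadditivity (the
"double-hit" signature), and SI > 2 is conventionally read as appreciable
synergistic acceleration of risk.

Inference is on the log scale: the delta method propagates the covariance of
(ln RR_A, ln RR_B, ln RR_AB) to a standard error for ln SI, and
Z = ln SI / se(ln SI) is referred to the standard normal.  The covariance
may come from a fitted Cox model (the primary, covariate-adjusted path) or
be reconstructed from the 4x2 table of case/control counts in the four
exposure groups (unadjusted log-odds-ratio path).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .config import GROUPS

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Cohort
    from .survival import CoxFit


class SynergyUndefinedError(ValueError):
    """The synergy index is undefined for the supplied inputs."""


class ZeroCellError(ValueError):
    """A 4x2 table cell is zero, so a log odds ratio is infinite."""


def synergy_index(hr_a: float, hr_b: float, hr_ab: float) -> float:
    """SI = (hr_ab - 1) / (hr_a + hr_b - 2).

    Requires ``hr_ab > 1`` and ``hr_a + hr_b > 2`` (net excess risk in both
    the joint and the combined single exposures); otherwise the index is
    undefined and a :class:`SynergyUndefinedError` names the violated
    condition.
    """
    for name, v in (("hr_a", hr_a), ("hr_b", hr_b), ("hr_ab", hr_ab)):
        if not np.isfinite(v) or v <= 0:
            raise SynergyUndefinedError(f"{name} must be a positive finite ratio, got {v}")
    denom = hr_a + hr_b - 2.0
    if denom <= 0:
        raise SynergyUndefinedError(
            f"denominator hr_a + hr_b - 2 = {denom:g} is not positive"
        )
    if hr_ab <= 1:
        raise SynergyUndefinedError(f"numerator hr_ab - 1 = {hr_ab - 1:g} is not positive")
    return (hr_ab - 1.0) / denom


def reri(hr_a: float, hr_b: float, hr_ab: float) -> float:
    """Relative excess risk due to interaction: hr_ab - hr_a - hr_b + 1."""
    return hr_ab - hr_a - hr_b + 1.0


def attributable_proportion(hr_a: float, hr_b: float, hr_ab: float) -> float:
    """Proportion of the joint-exposure risk attributable to interaction."""
    return reri(hr_a, hr_b, hr_ab) / hr_ab


def si_gradient(betas: np.ndarray) -> np.ndarray:
    """Gradient of ln SI in (b_a, b_b, b_ab) = log hazard ratios."""
    ea, eb, eab = np.exp(betas)
    d = ea + eb - 2.0
    return np.array([-ea / d, -eb / d, eab / (eab - 1.0)])


def se_ln_si(betas, cov) -> float:
    """Delta-method standard error of ln SI.

    ``betas`` are the log hazard ratios (ln hr_a, ln hr_b, ln hr_ab) and
    ``cov`` their 3x3 covariance.  With D = e^{b_a} + e^{b_b} - 2 the
    gradient of ln SI is ``(-e^{b_a}/D, -e^{b_b}/D, e^{b_ab}/(e^{b_ab}-1))``
    and ``se = sqrt(h' cov h)``.
    """
    betas = np.asarray(betas, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if betas.shape != (3,) or cov.shape != (3, 3):
        raise ValueError("betas must be length 3 and cov 3x3")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("cov must be symmetric")
    synergy_index(*np.exp(betas))  # raises if SI undefined at betas
    h = si_gradient(betas)
    var = float(h @ cov @ h)
    return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class SynergyTable:
    """Case/control counts per exposure group (rows ordered as GROUPS).

    ``counts[g, 0]`` are cases (disorder present) and ``counts[g, 1]``
    controls for group g in (neither, cb_only, ss_only, both).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (4, 2):
            raise ValueError(f"counts must be 4x2, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_cohort(cls, cohort: "Cohort", disorder: str) -> "SynergyTable":
        data = cohort.survival_data(disorder)
        counts = np.zeros((4, 2))
        for i, g in enumerate(GROUPS):
            sub = data[data["group"].astype(str) == g]
            counts[i, 0] = int(sub["event"].sum())
            counts[i, 1] = len(sub) - counts[i, 0]
        return cls(counts)

    @property
    def group_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def odds_ratios(self) -> np.ndarray:
        """Odds ratios of the three exposed groups versus the reference,
        in the order (cb_only, ss_only, both)."""
        a0, b0 = self.counts[0]
        if np.any(self.counts == 0):
            raise ZeroCellError(
                "table has a zero cell; odds ratios are infinite "
                "(consider continuity_correction=True to add 0.5 to every cell)"
            )
        return (self.counts[1:, 0] * b0) / (self.counts[1:, 1] * a0)

    def corrected(self) -> "SynergyTable":
        """Haldane-Anscombe continuity correction: add 0.5 to every cell."""
        return SynergyTable(self.counts + 0.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(GROUPS), columns=["cases", "controls"])


def table_log_or_cov(table: SynergyTable) -> tuple[np.ndarray, np.ndarray]:
    """Log odds ratios vs reference and their 3x3 covariance from cell counts.

    For exposed group k with cases/controls (a_k, b_k) and reference
    (a_0, b_0): ``var(beta_k) = 1/a_k + 1/b_k + 1/a_0 + 1/b_0`` and, because
    every contrast shares the reference cells,
    ``cov(beta_j, beta_k) = 1/a_0 + 1/b_0``.
    """
    if np.any(table.counts == 0):
        raise ZeroCellError(
            "table has a zero cell; the log-odds-ratio covariance is undefined "
            "(consider continuity_correction=True to add 0.5 to every cell)"
        )
    a0, b0 = table.counts[0]
    betas = np.log(table.odds_ratios())
    shared = 1.0 / a0 + 1.0 / b0
    own = 1.0 / table.counts[1:, 0] + 1.0 / table.counts[1:, 1]
    cov = np.full((3, 3), shared) + np.diag(own)
    return betas, cov


def se_ln_si_from_table(table: SynergyTable, continuity_correction: bool = False) -> float:
    """Delta-method se(ln SI) with the covariance rebuilt from a 4x2 table.

    Here the group ratios entering SI are the case/control odds ratios, the
    cells (a_k, b_k) are ordered by the exposure pattern, and the
    (cb_only, ss_only) contrasts play the roles of the two single exposures.
    """
    if continuity_correction:
        table = table.corrected()
    betas, cov = table_log_or_cov(table)
    # reorder (cb, ss, both) -> (a=ss, b=cb, ab=both); symmetric in a and b
    order = [1, 0, 2]
    return se_ln_si(betas[order], cov[np.ix_(order, order)])


@dataclass
class SynergyResult:
    """Synergy index with its delta-method Z test.

    ``source`` records whether the ratio inputs came from an adjusted Cox
    fit ("cox") or from the unadjusted 4x2 count table ("table").
    """

    si: float
    ln_si: float
    se_ln_si: float
    z: float
    p: float
    hr_a: float
    hr_b: float
    hr_ab: float
    alpha: float = 0.05
    source: str = "cox"
    table: SynergyTable | None = None

    @property
    def ci(self) -> tuple[float, float]:
        """Wald confidence interval for SI on the log scale."""
        zq = stats.norm.ppf(1 - self.alpha / 2)
        return (
            float(np.exp(self.ln_si - zq * self.se_ln_si)),
            float(np.exp(self.ln_si + zq * self.se_ln_si)),
        )

    @property
    def synergistic(self) -> bool:
        """Superadditive and significant at level alpha."""
        return self.si > 1 and self.p < self.alpha

    @property
    def appreciable(self) -> bool:
        """SI above 2: appreciable synergistic acceleration of risk."""
        return self.si > 2

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "SI": self.si,
                "ln_SI": self.ln_si,
                "se_ln_SI": self.se_ln_si,
                "z": self.z,
                "p": self.p,
                "ci_low": self.ci[0],
                "ci_high": self.ci[1],
                "hr_a": self.hr_a,
                "hr_b": self.hr_b,
                "hr_ab": self.hr_ab,
                "source": self.source,
            }
        )


def synergy_test(
    betas,
    cov,
    alpha: float = 0.05,
    source: str = "cox",
    table: SynergyTable | None = None,
) -> SynergyResult:
    """Z test of H0: SI = 1 from log hazard ratios and their covariance.

    ``z = ln SI / se(ln SI)`` is asymptotically standard normal under the
    additive null; the two-sided p-value is ``2 * Phi(-|z|)``.
    """
    betas = np.asarray(betas, dtype=float)
    hr_a, hr_b, hr_ab = np.exp(betas)
    si = synergy_index(hr_a, hr_b, hr_ab)
    ln_si = float(np.log(si))
    se = se_ln_si(betas, cov)
    if se == 0.0:
        if ln_si != 0.0:
            raise ValueError("se(ln SI) = 0 with SI != 1: Z test undefined")
        z = 0.0
    else:
        z = ln_si / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SynergyResult(
        si=si, ln_si=ln_si, se_ln_si=se, z=z, p=p,
        hr_a=hr_a, hr_b=hr_b, hr_ab=hr_ab,
        alpha=alpha, source=source, table=table,
    )


def synergy_from_cox(fit: "CoxFit", alpha: float = 0.05) -> SynergyResult:
    """Synergy test from the exposure-group block of a fitted Cox model.

    A = storm exposure (ss_only), B = cannabis exposure (cb_only), AB = both;
    the covariance is the corresponding 3x3 block of the coefficient
    covariance (SI is symmetric in A and B).
    """
    beta, cov = fit.group_block()  # order: cb_only, ss_only, both
    order = [1, 0, 2]
    return synergy_test(beta[order], cov[np.ix_(order, order)], alpha=alpha, source="cox")


def synergy_from_table(
    table: SynergyTable, alpha: float = 0.05, continuity_correction: bool = False
) -> SynergyResult:
    """Synergy test with odds ratios and covariance taken from a 4x2 table.

    This is the unadjusted fallback path; the primary path uses the
    covariate-adjusted Cox fit (:func:`synergy_from_cox`).
    """
    if continuity_correction:
        table = table.corrected()
    betas, cov = table_log_or_cov(table)
    order = [1, 0, 2]
    return synergy_test(
        betas[order], cov[np.ix_(order, order)],
        alpha=alpha, source="table", table=table,
    )
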