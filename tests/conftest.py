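"""Shared fixtures: small scenario builders used across the suite."""

import numpy as np
import pytest

from doublehit import DisorderSpec, PanelScaleSpec, ScenarioConfig, default_scenario


def make_scenario(
    n=163,
    sizes=(70, 27, 53, 13),
    probs=None,
    hr_ss=2.0,
    hr_cb=3.0,
    hr_both=4.0,
    baseline=0.004,
    seed=0,
    panel=False,
    **kw,
):
    """One-disorder scenario with optional single panel scale."""
    scales = {}
    if panel:
        scales["psi_total"] = PanelScaleSpec([64.0, 72.0, 65.0, 78.0], sd=12.0, lo=36, hi=138)
    return ScenarioConfig(
        n_total=n,
        group_sizes=sizes,
        group_probs=probs,
        disorders={
            "dx": DisorderSpec(
                baseline_hazard=baseline, hr_ss=hr_ss, hr_cb=hr_cb, hr_both=hr_both
            )
        },
        panel_scales=scales,
        seed=seed,
        **kw,
    ).validate()


STUDY_PROBS = tuple(np.array([70, 27, 53, 13]) / 163.0)


@pytest.fixture
def study_scenario():
    """The full study-sized default: N=163, two disorders, nine panel scales."""
    return default_scenario(seed=11)


@pytest.fixture
def simple_scenario():
    return make_scenario(seed=5)
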