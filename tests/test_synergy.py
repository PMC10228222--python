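"""The synergy index, its delta-method standard error (Cox-covariance and
count-table paths) and the Z test, against hand arithmetic, a numerical
gradient and a parametric bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import approx_fprime

from doublehit.synergy import (
    SynergyTable,
    SynergyUndefinedError,
    ZeroCellError,
    attributable_proportion,
    reri,
    se_ln_si,
    se_ln_si_from_table,
    si_gradient,
    synergy_from_table,
    synergy_index,
    synergy_test,
    table_log_or_cov,
)

hr_excess = st.floats(min_value=0.05, max_value=50.0)


def test_exact_additivity_gives_unit_index():
    """Excess risks 1 + 1 equal the joint excess 2: SI is exactly 1."""
    assert synergy_index(2.0, 2.0, 3.0) == 1.0


def test_printed_hr_triple_arithmetic():
    """HR_A 6.4, HR_B 9.4, HR_AB 31.2: SI = 30.2 / 13.8."""
    assert synergy_index(6.4, 9.4, 31.2) == pytest.approx(30.2 / 13.8)
    assert synergy_index(6.4, 9.4, 31.2) == pytest.approx(2.18841, abs=1e-5)


@pytest.mark.parametrize(
    "hr_a, hr_b, hr_ab, fragment",
    [
        (1.0, 1.0, 5.0, "denominator"),
        (0.5, 1.2, 5.0, "denominator"),
        (2.0, 2.0, 1.0, "numerator"),
        (2.0, 2.0, 0.5, "numerator"),
        (-1.0, 2.0, 3.0, "hr_a"),
    ],
)
def test_undefined_regions_raise_naming_the_condition(hr_a, hr_b, hr_ab, fragment):
    with pytest.raises(SynergyUndefinedError, match=fragment):
        synergy_index(hr_a, hr_b, hr_ab)


@settings(max_examples=200, deadline=None)
@given(a=hr_excess, b=hr_excess, si=st.floats(0.05, 20.0), c=st.floats(0.05, 20.0))
def test_scale_free_invariance(a, b, si, c):
    """Scaling every excess part hr -> 1 + c*(hr-1) leaves SI unchanged."""
    hr_a, hr_b = 1 + a, 1 + b
    hr_ab = 1 + si * (a + b)
    base = synergy_index(hr_a, hr_b, hr_ab)
    scaled = synergy_index(1 + c * a, 1 + c * b, 1 + c * si * (a + b))
    assert scaled == pytest.approx(base, rel=1e-9)
    assert base == pytest.approx(si, rel=1e-9)


@settings(max_examples=200, deadline=None)
@given(a=hr_excess, b=hr_excess, ab=st.floats(0.1, 100.0), eps=st.floats(0.01, 1.0))
def test_strict_monotonicity(a, b, ab, eps):
    """SI increases in hr_ab and decreases in each marginal HR."""
    hr_a, hr_b, hr_ab = 1 + a, 1 + b, 1 + ab
    base = synergy_index(hr_a, hr_b, hr_ab)
    assert synergy_index(hr_a, hr_b, hr_ab + eps) > base
    assert synergy_index(hr_a + eps, hr_b, hr_ab) < base
    assert synergy_index(hr_a, hr_b + eps, hr_ab) < base


def test_reri_and_attributable_proportion():
    assert reri(2.0, 3.0, 4.0) == pytest.approx(0.0)
    assert reri(2.0, 3.0, 6.0) == pytest.approx(2.0)
    assert attributable_proportion(2.0, 3.0, 6.0) == pytest.approx(2.0 / 6.0)


# ----------------------------------------------------- delta-method SE ----


def test_se_zero_covariance_gives_zero():
    betas = np.log([2.0, 3.0, 8.0])
    assert se_ln_si(betas, np.zeros((3, 3))) == 0.0


def test_gradient_symmetry_under_exchangeable_inputs():
    betas = np.log([2.5, 2.5, 9.0])
    h = si_gradient(betas)
    assert h[0] == pytest.approx(h[1])


def test_gradient_matches_numerical_differentiation():
    betas = np.log([2.0, 3.5, 12.0])

    def ln_si(b):
        return np.log(synergy_index(*np.exp(b)))

    numeric = approx_fprime(betas, ln_si, 1e-7)
    np.testing.assert_allclose(si_gradient(betas), numeric, rtol=1e-5)


def test_se_matches_explicit_quadratic_form():
    betas = np.log([2.0, 3.0, 8.0])
    cov = np.array([[0.04, 0.01, 0.01], [0.01, 0.05, 0.01], [0.01, 0.01, 0.06]])
    h = si_gradient(betas)
    assert se_ln_si(betas, cov) == pytest.approx(np.sqrt(h @ cov @ h))


def test_se_rejects_undefined_si_and_bad_cov():
    with pytest.raises(SynergyUndefinedError):
        se_ln_si(np.log([1.0, 1.0, 3.0]), np.eye(3) * 0.01)
    with pytest.raises(ValueError):
        se_ln_si(np.zeros(2), np.eye(3))


# ----------------------------------------------------------- 4x2 table ----


def test_table_covariance_hand_arithmetic_equal_cells():
    """All cells 25: var(beta_k) = 1/25*4 = 4/25, shared cov = 2/25."""
    table = SynergyTable(np.full((4, 2), 25.0))
    _, cov = table_log_or_cov(table)
    np.testing.assert_allclose(np.diag(cov), [4 / 25] * 3)
    off = cov[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, 2 / 25)


def test_table_se_frozen_hand_value():
    """Explicit matrix arithmetic for an elevated-risk table."""
    counts = np.array([[10.0, 90.0], [20.0, 80.0], [25.0, 75.0], [45.0, 55.0]])
    table = SynergyTable(counts)
    ors = table.odds_ratios()  # cb, ss, both
    np.testing.assert_allclose(ors, [20 * 90 / (80 * 10), 25 * 90 / (75 * 10), 45 * 90 / (55 * 10)])
    betas, cov = table_log_or_cov(table)
    h = si_gradient(np.array([betas[1], betas[0], betas[2]]))
    order = [1, 0, 2]
    expected = np.sqrt(h @ cov[np.ix_(order, order)] @ h)
    assert se_ln_si_from_table(table) == pytest.approx(expected)
    assert se_ln_si_from_table(table) == pytest.approx(0.3909365, abs=1e-6)


def test_table_se_shrinks_with_counts():
    base = SynergyTable(np.array([[10.0, 90.0], [20.0, 80.0], [25.0, 75.0], [45.0, 55.0]]))
    big = SynergyTable(base.counts * 100)
    assert se_ln_si_from_table(big) == pytest.approx(se_ln_si_from_table(base) / 10)


def test_zero_cell_raises_with_correction_hint():
    counts = np.array([[10.0, 90.0], [0.0, 100.0], [25.0, 75.0], [45.0, 55.0]])
    with pytest.raises(ZeroCellError, match="continuity"):
        se_ln_si_from_table(SynergyTable(counts))
    # the correction makes the path usable
    assert se_ln_si_from_table(SynergyTable(counts), continuity_correction=True) > 0


def test_table_se_agrees_with_parametric_bootstrap():
    """Delta-method se(ln SI) within 10% of a parametric bootstrap on a
    well-populated table (every cell >= 20)."""
    counts = np.array([[30.0, 170.0], [55.0, 145.0], [60.0, 140.0], [110.0, 90.0]])
    table = SynergyTable(counts)
    se = se_ln_si_from_table(table)
    boot = _bootstrap_sd_ln_si(table, n_boot=4000, seed=2)
    assert se == pytest.approx(boot, rel=0.10)


def _bootstrap_sd_ln_si(table, n_boot, seed):
    rng = np.random.default_rng(seed)
    n_g = table.group_sizes.astype(int)
    p_g = table.counts[:, 0] / table.group_sizes
    cases = rng.binomial(n_g, p_g, size=(n_boot, 4)).astype(float)
    controls = n_g - cases
    a0, b0 = cases[:, 0], controls[:, 0]
    keep = (cases > 0).all(axis=1) & (controls > 0).all(axis=1)
    ors = (cases[:, 1:] * b0[:, None]) / (controls[:, 1:] * a0[:, None])
    or_cb, or_ss, or_both = ors[:, 0], ors[:, 1], ors[:, 2]
    valid = keep & (or_both > 1) & (or_ss + or_cb > 2)
    ln_si = np.log((or_both[valid] - 1) / (or_ss[valid] + or_cb[valid] - 2))
    return ln_si.std(ddof=1)


# --------------------------------------------------------------- Z test ----


def test_unit_index_gives_null_z():
    betas = np.log([2.0, 2.0, 3.0])  # SI exactly 1
    res = synergy_test(betas, np.eye(3) * 0.04)
    assert res.si == pytest.approx(1.0)
    assert res.z == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert not res.synergistic


def test_zero_se_with_nonunit_si_is_an_error():
    with pytest.raises(ValueError, match="se"):
        synergy_test(np.log([2.0, 3.0, 9.0]), np.zeros((3, 3)))


def test_z_and_p_consistent_with_normal_tail():
    from scipy import stats

    betas = np.log([2.0, 3.0, 9.0])
    cov = np.eye(3) * 0.02
    res = synergy_test(betas, cov)
    assert res.z == pytest.approx(res.ln_si / res.se_ln_si)
    assert res.p == pytest.approx(2 * stats.norm.sf(abs(res.z)))
    lo, hi = res.ci
    assert lo < res.si < hi


def test_appreciable_and_synergistic_flags():
    betas = np.log([2.0, 3.0, 12.0])  # SI = 11/3
    res = synergy_test(betas, np.eye(3) * 0.01)
    assert res.si > 2 and res.appreciable
    assert res.synergistic  # p tiny with small covariance


def test_synergy_from_table_end_to_end():
    counts = np.array([[30.0, 170.0], [55.0, 145.0], [60.0, 140.0], [110.0, 90.0]])
    res = synergy_from_table(SynergyTable(counts))
    ors = SynergyTable(counts).odds_ratios()
    expected_si = (ors[2] - 1) / (ors[0] + ors[1] - 2)
    assert res.si == pytest.approx(expected_si)
    assert res.source == "table"
    assert res.table is not None
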