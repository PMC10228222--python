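"""Survival core: product-limit arithmetic, log-rank behaviour, Cox
parameter recovery against closed-form and independent oracles, and the
Schoenfeld proportional-hazards diagnostic."""

import numpy as np
import pandas as pd
import pytest

from doublehit import fit_cox, generate_cohort, km_estimate, logrank_test, schoenfeld_ph_test
from doublehit.config import GROUPS
from tests.conftest import make_scenario


def surv_frame(times, events, group=None, **cols):
    df = pd.DataFrame({"time_months": times, "event": events})
    if group is not None:
        df["group"] = group
    for k, v in cols.items():
        df[k] = v
    return df


# ----------------------------------------------------------------- KM ------


def test_km_hand_worked_product_limit():
    """Censor at 2, events at 3, 3, censor at 4, event at 5:
    S(3) = 1 * (1 - 2/4) = 0.5 and S(5) = 0."""
    est = km_estimate(surv_frame([2, 3, 3, 4, 5], [0, 1, 1, 0, 1]), by_group=False)
    np.testing.assert_allclose(est.event_times, [3.0, 5.0])
    np.testing.assert_allclose(est.at_risk, [4, 1])
    np.testing.assert_allclose(est.n_events, [2, 1])
    assert est.survival_at(3) == pytest.approx(0.5)
    assert est.risk_at(4.9) == pytest.approx(0.5)
    assert est.survival_at(5) == pytest.approx(0.0)


def test_km_all_events_reaches_unit_risk():
    est = km_estimate(surv_frame([1, 2, 3], [1, 1, 1]), by_group=False)
    assert est.survival_at(3) == pytest.approx(0.0)
    assert est.risk_at(3) == pytest.approx(1.0)


def test_km_no_events_zero_risk():
    est = km_estimate(surv_frame([5, 8, 13], [0, 0, 0]), by_group=False)
    assert est.risk_at(100) == 0.0
    assert est.event_times.size == 0


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(4)
    t = rng.exponential(10, size=300)
    est = km_estimate(surv_frame(t, np.ones_like(t)), by_group=False)
    for q in (5.0, 10.0, 20.0):
        assert est.survival_at(q) == pytest.approx((t > q).mean())


def test_km_rejects_empty_and_nonpositive_times():
    with pytest.raises(ValueError):
        km_estimate(surv_frame([], []), by_group=False)
    with pytest.raises(ValueError):
        km_estimate(surv_frame([0.0, 1.0], [1, 1]), by_group=False)


# ------------------------------------------------------------ log-rank ----


def test_logrank_identical_groups_is_null():
    base_t = [3, 5, 7, 9, 11, 13]
    base_e = [1, 0, 1, 1, 0, 1]
    df = surv_frame(base_t * 2, base_e * 2, group=["a"] * 6 + ["b"] * 6)
    res = logrank_test(df)
    assert res.chi2 == pytest.approx(0.0, abs=1e-10)
    assert res.p == pytest.approx(1.0)
    assert res.df == 1


def test_logrank_invariant_to_group_relabeling():
    cfg = make_scenario(n=400, sizes=(100, 100, 100, 100), seed=8)
    data = generate_cohort(cfg).survival_data("dx")
    res = logrank_test(data)
    relabeled = data.copy()
    mapping = dict(zip(GROUPS, ["d", "c", "b", "a"]))
    relabeled["group"] = relabeled["group"].astype(str).map(mapping)
    res2 = logrank_test(relabeled)
    assert res2.chi2 == pytest.approx(res.chi2)
    assert res2.df == res.df == 3


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError):
        logrank_test(surv_frame([1, 2, 3], [1, 1, 1], group=["a"] * 3))


def test_logrank_null_rejection_rate_near_nominal():
    """Equal hazards in all four groups: rejection at 0.05 stays within
    Monte-Carlo error of nominal."""
    cfg = make_scenario(n=120, sizes=(30, 30, 30, 30),
                        hr_ss=1.0, hr_cb=1.0, hr_both=1.0, baseline=0.01)
    rng = np.random.default_rng(100)
    reject = 0
    n_reps = 400
    for seed in rng.integers(0, 2**31 - 1, n_reps):
        data = generate_cohort(cfg.replace(seed=int(seed))).survival_data("dx")
        if logrank_test(data).p < 0.05:
            reject += 1
    rate = reject / n_reps
    assert 0.02 <= rate <= 0.09  # ~4 MC standard errors around 0.05


def test_logrank_detects_strong_separation():
    """HRs (1, 3, 6, 30) at n=400 give p < 0.001 essentially always."""
    for seed in range(5):
        cfg = make_scenario(n=400, sizes=(100, 100, 100, 100),
                            hr_cb=3.0, hr_ss=6.0, hr_both=30.0,
                            baseline=0.004, seed=seed)
        data = generate_cohort(cfg).survival_data("dx")
        assert logrank_test(data).p < 0.001


# ---------------------------------------------------------------- Cox ------


def test_cox_null_covariate_recovers_zero():
    cfg = make_scenario(n=5000, sizes=None, probs=(0.25,) * 4, seed=15)
    data = generate_cohort(cfg).survival_data("dx")
    fit = fit_cox(data, covariates=["maternal_age"])  # true effect 0
    beta = fit.params["maternal_age"]
    se = fit.summary.loc["maternal_age", "se"]
    assert abs(beta) < 3 * se
    assert fit.converged


def test_cox_two_group_hr_matches_exponential_mle():
    """With exponential data the closed-form MLE of the rate ratio is
    (d1/PT1)/(d0/PT0); the Cox HR must sit beside it and near truth 2."""
    rng = np.random.default_rng(23)
    n = 5000
    grp = rng.random(n) < 0.5
    lam = np.where(grp, 0.04, 0.02)
    t = rng.exponential(1 / lam)
    c = rng.uniform(60, 120, n)  # long follow-up: ~2000 events per arm
    data = surv_frame(np.minimum(t, c), (t <= c).astype(int),
                      group=np.where(grp, "ss_only", "neither"))
    fit = fit_cox(data)
    hr = fit.hazard_ratios["group_ss_only"]
    d1, d0 = data[grp]["event"].sum(), data[~grp]["event"].sum()
    pt1, pt0 = data[grp]["time_months"].sum(), data[~grp]["time_months"].sum()
    mle = (d1 / pt1) / (d0 / pt0)
    assert 1.8 <= hr <= 2.2
    assert hr == pytest.approx(mle, rel=0.03)
    # and within 3 standard errors of the generative truth
    assert abs(np.log(hr) - np.log(2.0)) < 3 * np.sqrt(1 / d1 + 1 / d0)


def test_cox_matches_independent_implementation():
    """Coefficient agreement with scikit-survival's Cox solver to 1e-4 on
    random small datasets (continuous times, so tie handling is moot)."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    rng = np.random.default_rng(99)
    for _ in range(20):
        n = int(rng.integers(40, 90))
        x = rng.normal(size=(n, 3))
        beta = rng.normal(scale=0.5, size=3)
        t = rng.exponential(1.0 / (0.05 * np.exp(x @ beta)))
        c = rng.exponential(25.0, size=n)
        data = surv_frame(np.minimum(t, c), (t <= c).astype(int),
                          x0=x[:, 0], x1=x[:, 1], x2=x[:, 2])
        if data["event"].sum() < 5:
            continue
        ours = fit_cox(data, covariates=["x0", "x1", "x2"], include_group=False)
        y = np.array([(bool(e), tt) for e, tt in zip(data["event"], data["time_months"])],
                     dtype=[("event", "?"), ("time", "f8")])
        ref = CoxPHSurvivalAnalysis(tol=1e-12, n_iter=200).fit(x, y)
        np.testing.assert_allclose(
            ours.params[["x0", "x1", "x2"]].to_numpy(), ref.coef_, atol=1e-4
        )


def test_cox_flags_zero_event_group_as_monotone_likelihood():
    cfg = make_scenario(n=400, sizes=(100, 100, 100, 100),
                        hr_ss=1.0, hr_cb=1.0, hr_both=1.0, baseline=0.01, seed=2)
    data = generate_cohort(cfg).survival_data("dx")
    data.loc[data["group"].astype(str) == "both", "event"] = 0
    fit = fit_cox(data)
    assert any("monotone" in f for f in fit.flags)


def test_cox_requires_events_and_positive_times():
    with pytest.raises(ValueError):
        fit_cox(surv_frame([1, 2], [0, 0], group=["neither", "both"]))


def test_cox_partial_likelihood_exceeds_null():
    cfg = make_scenario(n=800, sizes=(200, 200, 200, 200), seed=31)
    data = generate_cohort(cfg).survival_data("dx")
    fit = fit_cox(data)
    assert fit.loglik >= fit.loglik_null
    chi2, df, p = fit.lr_test()
    assert chi2 >= 0 and df == 3 and 0 <= p <= 1


# ----------------------------------------------------------- Schoenfeld ----


def test_schoenfeld_per_term_matches_lifelines():
    from lifelines.statistics import proportional_hazard_test

    cfg = make_scenario(n=500, sizes=None, probs=(0.25,) * 4, seed=44)
    data = generate_cohort(cfg).survival_data("dx")
    fit = fit_cox(data, covariates=["maternal_age"])
    ours = schoenfeld_ph_test(fit, transform="identity")
    ref = proportional_hazard_test(fit._fitter, fit._design, time_transform="identity")
    ref_stats = ref.summary["test_statistic"]
    for term in ours.table.index:
        assert ours.table.loc[term, "stat"] == pytest.approx(ref_stats[term], rel=1e-8)


def test_schoenfeld_null_global_rejection_near_nominal():
    """Proportional-hazards data: the global test rejects at about 5%."""
    cfg = make_scenario(n=300, sizes=None, probs=(0.25,) * 4, baseline=0.006)
    rng = np.random.default_rng(7)
    n_reps, reject = 150, 0
    for seed in rng.integers(0, 2**31 - 1, n_reps):
        data = generate_cohort(cfg.replace(seed=int(seed))).survival_data("dx")
        fit = fit_cox(data)
        if schoenfeld_ph_test(fit).global_p < 0.05:
            reject += 1
    assert 0.01 <= reject / n_reps <= 0.11


def test_schoenfeld_detects_sign_reversing_effect():
    """A covariate effect that flips sign midway violates proportionality
    and is flagged by the global test in most replicates at n=2000."""
    rng = np.random.default_rng(55)
    n, switch, beta = 2000, 20.0, 1.0
    hits = 0
    n_reps = 12
    for _ in range(n_reps):
        x = rng.random(n) < 0.5
        lam1 = 0.02 * np.exp(beta * x)
        t1 = rng.exponential(1 / lam1)
        lam2 = 0.02 * np.exp(-beta * x)
        t = np.where(t1 <= switch, t1, switch + rng.exponential(1 / lam2))
        c = rng.uniform(30, 60, n)
        data = surv_frame(np.minimum(t, c), (t <= c).astype(int), x=x.astype(float))
        fit = fit_cox(data, covariates=["x"], include_group=False)
        if schoenfeld_ph_test(fit).global_p < 0.05:
            hits += 1
    assert hits >= 0.8 * n_reps
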