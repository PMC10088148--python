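"""Cox partial-likelihood solver against independent oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mdswgs.coxph import (
    cox_score_test,
    efron_loglik,
    fit_cox,
    fit_cox_scalar_batch,
)


def reference_partial_loglik(beta, x, time, event):
    """Independent Efron partial log-likelihood: explicit loops, no shared code.

    Evaluated in extended precision (long double) so that a derivative-free
    search can localise the maximum beyond the float64 sqrt(eps) limit.
    """
    beta = np.longdouble(beta)
    ll = np.longdouble(0.0)
    for t in sorted(set(time[event])):
        deaths = [i for i in range(len(time)) if event[i] and time[i] == t]
        risk = [i for i in range(len(time)) if time[i] >= t]
        d = len(deaths)
        sum_risk = sum(np.exp(beta * np.longdouble(x[i])) for i in risk)
        sum_deaths = sum(np.exp(beta * np.longdouble(x[i])) for i in deaths)
        for i in deaths:
            ll += beta * np.longdouble(x[i])
        for ell in range(d):
            ll -= np.log(sum_risk - np.longdouble(ell / d) * sum_deaths)
    return ll


def golden_section_maximum(f, lo, hi, tol=np.longdouble(1e-11)):
    """Derivative-free maximisation by golden-section search."""
    phi = (np.sqrt(np.longdouble(5)) - 1) / 2
    lo, hi = np.longdouble(lo), np.longdouble(hi)
    c, d = hi - phi * (hi - lo), lo + phi * (hi - lo)
    fc, fd = f(c), f(d)
    while hi - lo > tol:
        if fc > fd:
            hi, d, fd = d, c, fc
            c = hi - phi * (hi - lo)
            fc = f(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + phi * (hi - lo)
            fd = f(d)
    return (lo + hi) / 2


@pytest.fixture
def six_patient_fixture():
    # carriers fail at times 2 and 5: a finite interior maximum (a carrier set
    # failing strictly first would make the likelihood monotone in beta)
    time = np.arange(1.0, 7.0)
    event = np.ones(6, dtype=bool)
    x = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 0.0])
    return x, time, event


def test_beta_matches_grid_maximised_partial_likelihood(six_patient_fixture):
    """Newton solution equals brute-force maximisation of the reference likelihood."""
    x, time, event = six_patient_fixture
    # coarse grid to bracket the maximum, then golden-section refinement
    grid = np.linspace(-5, 5, 1001)
    vals = [reference_partial_loglik(b, x, time, event) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    b_star = golden_section_maximum(
        lambda b: reference_partial_loglik(b, x, time, event), b0 - 0.02, b0 + 0.02
    )
    fit = fit_cox(x, time, event)
    assert fit.converged
    assert fit.beta[0] == pytest.approx(float(b_star), abs=1e-8)
    # and the package's own likelihood agrees with the reference at the optimum
    assert efron_loglik(fit.beta, x, time, event) == pytest.approx(
        reference_partial_loglik(fit.beta[0], x, time, event), abs=1e-10
    )


@pytest.mark.parametrize("seed,censor,round_times", [(1, 0.7, True), (2, 1.0, False), (3, 0.5, True)])
def test_multivariate_fit_matches_lifelines(seed, censor, round_times):
    """Coefficients, SEs and log-likelihood agree with lifelines (Efron ties)."""
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(seed)
    n = 150
    X = np.column_stack([rng.binomial(1, 0.3, n), rng.normal(size=n)])
    t = rng.exponential(np.exp(-(0.6 * X[:, 0] - 0.2 * X[:, 1])))
    if round_times:
        t = np.round(t, 1) + 0.05  # induce ties
    e = rng.random(n) < censor
    fit = fit_cox(X, t, e)
    df = pd.DataFrame({"t": t, "e": e.astype(int), "x0": X[:, 0], "x1": X[:, 1]})
    ref = CoxPHFitter().fit(df, "t", "e")
    # lifelines iterates to a looser score tolerance; agreement to 1e-4 is its limit
    np.testing.assert_allclose(fit.beta, ref.params_.values, atol=1e-4)
    np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-4)
    assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-5)


def test_invariance_to_patient_order_and_time_scale():
    rng = np.random.default_rng(7)
    n = 120
    x = rng.binomial(1, 0.25, n).astype(float)
    t = rng.exponential(np.exp(-0.5 * x))
    e = rng.random(n) < 0.8
    fit = fit_cox(x, t, e)
    perm = rng.permutation(n)
    fit_perm = fit_cox(x[perm], t[perm], e[perm])
    assert fit_perm.beta[0] == pytest.approx(fit.beta[0], abs=1e-10)
    fit_scaled = fit_cox(x, 12.0 * t, e)  # months instead of years
    assert fit_scaled.beta[0] == pytest.approx(fit.beta[0], abs=1e-9)


def test_score_test_equals_logrank_without_censoring():
    """Classical identity: Cox score chi2 == log-rank statistic (binary group, no ties)."""
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(11)
    n = 80
    x = rng.binomial(1, 0.4, n).astype(float)
    t = rng.exponential(np.exp(-0.4 * x))
    e = np.ones(n, dtype=bool)
    U, V, _ = cox_score_test(x, t, e)
    ref = logrank_test(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
    assert U[0] ** 2 / V[0] == pytest.approx(ref.test_statistic, abs=1e-8)


def test_monotone_likelihood_flagged_not_raised():
    # carriers all fail first: likelihood is monotone in beta
    time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    event = np.ones(6, dtype=bool)
    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    fit = fit_cox(x, time, event)
    assert fit.separation
    assert not fit.converged


def test_lrt_statistic_is_chi2_distributed_under_null():
    rng = np.random.default_rng(5)
    stats_ = []
    for _ in range(200):
        x = rng.binomial(1, 0.3, 60).astype(float)
        t = rng.exponential(1.0, 60)
        fit = fit_cox(x, t, np.ones(60, bool))
        stats_.append(fit.lrt_stat)
    p = stats.kstest(stats_, stats.chi2(df=1).cdf).pvalue
    assert p > 0.01


def test_batch_fitter_identical_to_per_region_fits():
    rng = np.random.default_rng(9)
    n = 200
    t = np.round(rng.exponential(1.0, n), 1) + 0.05
    e = rng.random(n) < 0.7
    C = rng.binomial(1, 0.15, (n, 25)).astype(float)
    beta, se, ll, ll0, conv, sep = fit_cox_scalar_batch(C, t, e)
    for j in range(25):
        f = fit_cox(C[:, j], t, e)
        assert beta[j] == pytest.approx(f.beta[0], abs=1e-8)
        assert se[j] == pytest.approx(f.se[0], abs=1e-8)
        assert ll[j] == pytest.approx(f.loglik, abs=1e-7)
        assert conv[j] == f.converged


def test_no_events_is_an_error():
    with pytest.raises(ValueError, match="no events"):
        fit_cox(np.array([0.0, 1.0]), np.array([1.0, 2.0]), np.array([False, False]))
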