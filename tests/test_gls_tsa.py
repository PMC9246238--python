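"""GLS-ARMA estimation, Granger causality and volatility diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

from dendroflux.gls_tsa import (
    ArmaOrder,
    acf_squared_residuals,
    bonferroni_flags,
    build_design,
    fit_garch11,
    fit_gls_arma,
    granger_test,
    lag_scan,
    predict_missing_coefficients,
    rh_conditional_tests,
    rma_slope,
    select_arima_order,
    split_and_recombine,
    subseries_df,
)

AR22 = [0.55, -0.12]
MA22 = [0.22, 0.10]


def arma_noise(rng, n, sd=2.0, ar=AR22, ma=MA22, burn=200):
    z = rng.normal(0.0, sd, n + burn)
    return signal.lfilter(np.r_[1.0, ma], np.r_[1.0, -np.asarray(ar)], z)[burn:]


def simulate_garch(rng, n, omega, alpha, beta):
    s2 = np.empty(n)
    e = np.empty(n)
    s2[0] = omega / (1 - alpha - beta)
    e[0] = rng.normal(0, np.sqrt(s2[0]))
    for t in range(1, n):
        s2[t] = omega + alpha * e[t - 1] ** 2 + beta * s2[t - 1]
        e[t] = rng.normal(0, np.sqrt(s2[t]))
    return e


# --------------------------------------------------------------- GLS-ARMA core

def test_order_00_equals_ols_on_random_instances(rng):
    """With white-noise errors the GLS profile degenerates to OLS exactly."""
    import statsmodels.api as sm

    for _ in range(25):
        n = 200
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n) + X @ rng.normal(size=2)
        fit = fit_gls_arma(y, X, ArmaOrder(0, 0))
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.coef, ols.params, rtol=1e-8)
        np.testing.assert_allclose(fit.se, ols.bse, rtol=1e-8)
        np.testing.assert_allclose(fit.p_values, ols.pvalues, rtol=1e-6)


def test_ar1_errors_match_whitened_regression_oracle(rng):
    """With AR(1) errors at known phi, GLS equals the quasi-differenced OLS."""
    n, phi = 200, 0.6
    x = rng.normal(size=n)
    eps = signal.lfilter([1.0], [1.0, -phi], rng.normal(0, 1, n + 100))[100:]
    y = 1.0 + 0.8 * x + eps
    fit = fit_gls_arma(y, x, ArmaOrder(1, 0))
    phi_hat = fit.ar_params[0]
    # Prais-Winsten style oracle at the fitted phi
    ys = np.r_[np.sqrt(1 - phi_hat ** 2) * y[0], y[1:] - phi_hat * y[:-1]]
    Xf = np.column_stack([np.ones(n), x])
    Xs = np.vstack([np.sqrt(1 - phi_hat ** 2) * Xf[0], Xf[1:] - phi_hat * Xf[:-1]])
    beta_oracle = np.linalg.lstsq(Xs, ys, rcond=None)[0]
    np.testing.assert_allclose(fit.coef, beta_oracle, rtol=1e-6)
    assert abs(phi_hat - phi) < 0.2


def test_exact_likelihood_matches_statsmodels_arima(rng):
    """Independent oracle: same model maximised by the state-space ARIMA."""
    from statsmodels.tsa.arima.model import ARIMA

    n = 300
    x = rng.normal(size=(n, 2))
    y = 1.0 + x @ [0.7, -0.4] + arma_noise(rng, n, sd=1.5)
    fit = fit_gls_arma(y, x, ArmaOrder(2, 2))
    ref = ARIMA(y, exog=x, order=(2, 0, 2), trend="c").fit()
    assert fit.loglik == pytest.approx(ref.llf, abs=0.05)
    np.testing.assert_allclose(fit.coef, ref.params[:3], atol=0.02)


def test_likelihood_at_optimum_beats_truth(rng):
    n = 400
    x = rng.normal(size=n)
    y = 0.5 + 0.8 * x + arma_noise(rng, n)

    fit = fit_gls_arma(y, x, ArmaOrder(2, 2))
    # evaluate exact likelihood at the true generating parameters
    from dendroflux.gls_tsa import _gls_profile

    X = np.column_stack([np.ones(n), x])
    _, rss, logdet, _, _ = _gls_profile(y, X, np.asarray(AR22), np.asarray(MA22))
    ll_true = -0.5 * (n * np.log(2 * np.pi * rss / n) + n + logdet)
    assert fit.loglik >= ll_true - 1e-6


def test_missing_values_rejected():
    y = np.r_[np.ones(50), np.nan]
    with pytest.raises(ValueError, match="missing values"):
        fit_gls_arma(y, np.ones((51, 1)), ArmaOrder(1, 0))


def test_short_series_guard():
    with pytest.raises(ValueError, match="too short"):
        select_arima_order(np.random.default_rng(0).normal(size=20), max_p=2, max_q=2)


def test_order_selection_modal_orders(rng):
    """AIC selection finds (2,2) for ARMA(2,2) noise and (0,0) for white noise."""
    picks_arma, picks_wn = [], []
    for r in range(12):
        rr = np.random.default_rng(300 + r)
        x = rr.normal(size=500)
        y = 0.5 + 0.8 * x + arma_noise(rr, 500, ar=[0.6, -0.25], ma=[0.4, 0.25])
        o = select_arima_order(y, x, allow_d=(0,))
        picks_arma.append((o.p, o.q))
        y2 = 0.5 + 0.8 * x + rr.normal(0, 1, 500)
        o2 = select_arima_order(y2, x, allow_d=(0,))
        picks_wn.append((o2.p, o2.q))
    modal = max(set(picks_arma), key=picks_arma.count)
    modal_wn = max(set(picks_wn), key=picks_wn.count)
    assert modal == (2, 2)
    assert modal_wn == (0, 0)


def test_lag_scan_finds_planted_lag(rng):
    hits = 0
    reps = 10
    for r in range(reps):
        rr = np.random.default_rng(40 + r)
        n = 400
        x = signal.lfilter([1.0], [1.0, -0.5], rr.normal(0, 1, n))  # persistent regressor
        y = np.zeros(n)
        y[1:] = 1.2 * x[:-1]
        y += arma_noise(rr, n, sd=1.0)
        table = lag_scan(y, x, order=ArmaOrder(2, 2))
        hits += table.loc[table["t"].abs().idxmax(), "lag"] == 1
    assert hits >= 9


def test_bonferroni_flags():
    flags = bonferroni_flags([0.002, 0.003, 0.04], m=18)
    np.testing.assert_array_equal(flags, [True, False, False])
    assert bonferroni_flags([0.04], m=1)[0]


# ------------------------------------------------------------------- Granger

def test_granger_matches_partitioned_rss_oracle(rng):
    """F equals the textbook restricted/unrestricted OLS computation."""
    for _ in range(25):
        n = 150
        y = arma_noise(rng, n, sd=1.0, ar=[0.4, 0.0], ma=[0.0, 0.0])
        x = arma_noise(rng, n, sd=1.0, ar=[0.5, 0.0], ma=[0.0, 0.0])
        res = granger_test(y, x, p=2)
        yt = y[2:]
        Xr = np.column_stack([np.ones(n - 2), y[1:-1], y[:-2]])
        Xu = np.column_stack([Xr, x[1:-1], x[:-2]])
        rss = []
        for X in (Xr, Xu):
            b = np.linalg.lstsq(X, yt, rcond=None)[0]
            r = yt - X @ b
            rss.append(r @ r)
        f = ((rss[0] - rss[1]) / 2) / (rss[1] / (n - 2 - 5))
        assert res.f_stat == pytest.approx(f, rel=1e-10)
        assert res.df2 == n - 2 - 5
        assert res.p_value == pytest.approx(stats.f.sf(f, 2, n - 7), rel=1e-10)


def test_granger_constant_x_rejected():
    y = np.random.default_rng(0).normal(size=100)
    with pytest.raises(ValueError, match="constant"):
        granger_test(y, np.ones(100))


def test_granger_detects_planted_effect(rng):
    n = 300
    x = signal.lfilter([1.0], [1.0, -0.5], rng.normal(0, 1, n))
    y = np.zeros(n)
    y[1:] = 0.8 * x[:-1]
    y += rng.normal(0, 1, n)
    assert granger_test(y, x).p_value < 1e-4


# ---------------------------------------------------------- volatility checks

def test_acf_squared_verdicts(rng):
    garch_resid = simulate_garch(rng, 1000, 0.1, 0.25, 0.65)
    assert acf_squared_residuals(garch_resid).verdict == "strong"
    assert acf_squared_residuals(rng.normal(size=1000)).verdict in ("none", "weak")
    with pytest.raises(ValueError, match="constant"):
        acf_squared_residuals(np.ones(100))


def test_garch11_recovers_parameters():
    ests = []
    for r in range(6):
        rng = np.random.default_rng(900 + r)
        e = simulate_garch(rng, 2000, 0.1, 0.15, 0.7)
        f = fit_garch11(e)
        ests.append([f.omega, f.alpha, f.beta])
    mean_est = np.mean(ests, axis=0)
    np.testing.assert_allclose(mean_est, [0.1, 0.15, 0.7], atol=0.12)
    assert abs(mean_est[0] - 0.1) < 0.06 and abs(mean_est[1] - 0.15) < 0.06
    assert all(e[1] + e[2] < 1 for e in ests)


def test_garch11_warns_on_short_series(rng):
    with pytest.warns(UserWarning, match="poorly determined"):
        fit_garch11(rng.normal(size=80))


def test_garch11_homoscedastic_input_low_persistence(rng):
    f = fit_garch11(rng.normal(0, 1.0, 1500))
    assert f.alpha < 0.1


# ------------------------------------------------------- subseries recombining

def test_subseries_df_reproduces_printed_value():
    assert subseries_df(550, 3) == pytest.approx(181.3, abs=0.05)


def test_split_and_recombine_identical_parts(rng):
    n = 300
    x = np.tile(rng.normal(size=100), 3)
    y = np.tile(1.0 + 0.5 * x[:100] + rng.normal(0, 0.3, 100), 3)
    summ = split_and_recombine(y, x, ArmaOrder(0, 0), parts=3, terms=["x"])
    p1 = summ.part_fits[0]
    np.testing.assert_allclose(summ.combined["coef"], p1.coef, rtol=1e-8)
    np.testing.assert_allclose(summ.combined["se"], p1.se, rtol=1e-8)
    assert summ.df == pytest.approx(98.0)


def test_split_and_recombine_consistent_with_full_fit(rng):
    n = 540
    x = rng.normal(size=n)
    y = 1.0 + 0.8 * x + arma_noise(rng, n, sd=1.0)
    full = fit_gls_arma(y, x, ArmaOrder(2, 2))
    summ = split_and_recombine(y, x, ArmaOrder(2, 2), parts=3)
    comb = summ.combined.set_index("term")
    diff = abs(comb.loc["x1", "coef"] - full.coef[1])
    assert diff < 2.5 * comb.loc["x1", "se"]


# --------------------------------------------------- coefficient-level helpers

def test_predict_missing_coefficients_collinear_and_loo(rng):
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = 0.5 - 2.0 * x
    out = predict_missing_coefficients(y, x, np.array([2.5]))
    assert out["predicted_scaled"][0] == pytest.approx(0.5 - 5.0)
    # residual variance is zero; only leverage terms remain
    assert out["prediction_se"][0] == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError, match=">= 3"):
        predict_missing_coefficients(y[:2], x[:2], np.array([1.0]))
    # leave-one-out coverage on noisy synthetic trees
    n, hits, trials = 12, 0, 40
    for r in range(trials):
        rr = np.random.default_rng(600 + r)
        gmax = rr.uniform(2, 15, n)
        coefs = 1.0 - 0.4 * gmax + rr.normal(0, 0.5, n)
        i = r % n
        keep = np.arange(n) != i
        pred = predict_missing_coefficients(coefs[keep], gmax[keep], np.array([gmax[i]]))
        t95 = stats.t.ppf(0.975, n - 1 - 2)
        hits += abs(coefs[i] - pred["predicted_scaled"][0]) < t95 * pred["prediction_se"][0]
    assert hits / trials >= 0.8


def test_predict_missing_backscaling():
    x = np.array([1.0, 2.0, 3.0])
    y = 2.0 * x
    out = predict_missing_coefficients(y, x, np.array([2.0]), target_gbh=np.array([100.0]))
    assert out["predicted"][0] == pytest.approx(out["predicted_scaled"][0] * 2.0)


@pytest.mark.parametrize(
    "x, y, slope, intercept",
    [(np.arange(10.0), np.arange(10.0), 1.0, 0.0),
     (np.arange(10.0), 2.0 * np.arange(10.0), 2.0, 0.0)],
)
def test_rma_slope_simple(x, y, slope, intercept):
    s, i = rma_slope(x, y)
    assert s == pytest.approx(slope) and i == pytest.approx(intercept, abs=1e-10)


def test_rma_slope_matches_moment_definition(rng):
    x = rng.normal(2, 3, 100)
    y = -1.5 * x + rng.normal(0, 1, 100)
    s, i = rma_slope(x, y)
    r = np.corrcoef(x, y)[0, 1]
    assert s == pytest.approx(np.sign(r) * y.std(ddof=1) / x.std(ddof=1), rel=1e-12)
    assert i == pytest.approx(y.mean() - s * x.mean(), rel=1e-10)


def test_rh_conditional_tests_null_and_planted(rng):
    n = 400
    tdry = rng.normal(30.0, 0.8, n)
    rh = 180.0 - 5.0 * tdry + rng.normal(0, 2.0, n)
    # null: gthi depends on temperature only
    gthi = 0.5 * tdry + arma_noise(rng, n, sd=1.0)
    res = rh_conditional_tests(gthi, tdry, rh, order=ArmaOrder(1, 1))
    assert res["rh_residual_fit"]["rh_resid"]["P"] > 0.01
    # planted humidity effect detected with matching sign in (a) and (b)
    gthi2 = 0.5 * tdry + 0.8 * (rh - (180.0 - 5.0 * tdry)) + arma_noise(rng, n, sd=1.0)
    res2 = rh_conditional_tests(gthi2, tdry, rh, order=ArmaOrder(1, 1))
    a = res2["rh_residual_fit"]["rh_resid"]
    b = res2["nested_interaction_fit"]["tdry14:rh14"]
    assert a["P"] < 0.01
    assert np.sign(a["coef"]) == np.sign(b["coef"])
    # slices frame has a row per configured slice
    assert len(res2["temperature_slices"]) == 3


def test_build_design_lags_and_interaction(rng):
    y = rng.normal(size=20)
    a = np.arange(20.0)
    b = rng.normal(size=20)
    yy, X, names = build_design(y, [("a", a, 1), ("b", b, 0)])
    assert len(yy) == 19  # first row lost to the lag
    np.testing.assert_allclose(X[:, 0], a[:-1])
    yy2, X2, names2 = build_design(y, [("a", a, 0), ("b", b, 0)], interaction=True)
    assert names2[-1] == "a:b"
    assert abs(X2[:, 0].mean()) < 1e-9  # centred
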