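"""GLS regression with ARMA errors and time-series diagnostics.

The response is the daily girth increment ``gthi`` (cm·10⁻³/day) of one
band; predictors are soil moisture potential (transformed -sqrt(|SMP|),
usually lagged one day), logger temperature at 14:00, running rainfall
totals, or humidity residuals.  Day-to-day dependence of the errors is
modelled as a stationary, invertible Gaussian ARMA(p, q) process —
(p, q) = (2, 2) by default, guided by restricted ARIMA order selection.

Estimation maximises the exact Gaussian likelihood: for a candidate set
of ARMA parameters the error autocovariance is assembled into a Toeplitz
matrix, the regression coefficients are profiled out by generalised
least squares through its Cholesky factor, and the innovation variance
is concentrated.  Standard errors come from the GLS covariance at the
fitted ARMA parameters; t-ratios use n - k degrees of freedom.

Also provided: Granger causality (restricted-vs-unrestricted OLS F),
squared-residual ACF and GARCH(1,1) non-stationarity diagnostics, the
three-way subseries split-and-recombine summary used when a band shows a
volatility episode, Bonferroni flags, reduced-major-axis slopes, and
prediction of missing coefficients from diurnal girth-change maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from statsmodels.tsa.innovations.arma_innovations import arma_innovations
from statsmodels.tsa.statespace.tools import constrain_stationary_univariate
from statsmodels.tsa.stattools import acf as sample_acf


@dataclass(frozen=True)
class ArmaOrder:
    p: int = 2
    q: int = 2
    d: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 3 and 0 <= self.q <= 2 and self.d in (0, 1)):
            raise ValueError(f"unsupported ARMA order {self}")


@dataclass
class GlsFit:
    """Result of one GLS regression with ARMA(p, q) errors."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_values: np.ndarray
    ar_params: np.ndarray
    ma_params: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    n: int
    order: ArmaOrder
    converged: bool
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "coef": self.coef, "se": self.se,
             "t": self.t, "P": self.p_values}
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {"coef": self.coef[i], "se": self.se[i],
                "t": self.t[i], "P": self.p_values[i]}


@dataclass(frozen=True)
class GrangerResult:
    f_stat: float
    df1: int
    df2: int
    p_value: float
    lag_order: int


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def lagged(values: np.ndarray, lag: int) -> np.ndarray:
    """Shift a series so index i holds the value lag days earlier."""
    values = np.asarray(values, dtype=float)
    if lag == 0:
        return values.copy()
    if lag < 0:
        raise ValueError("lag must be >= 0")
    out = np.full(len(values), np.nan)
    out[lag:] = values[:-lag]
    return out


def build_design(response: np.ndarray,
                 terms: list[tuple[str, np.ndarray, int]],
                 interaction: bool = False) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align response and lagged predictors, dropping incomplete rows.

    ``terms`` are (name, daily series, lag).  With ``interaction`` the two
    (and only two) predictors are centred and their product appended —
    centring tames the collinearity a raw product would introduce.
    Returns (y, X-without-intercept, names).
    """
    y = np.asarray(response, dtype=float)
    cols, names = [], []
    for name, values, lag in terms:
        col = lagged(values, lag)
        if len(col) != len(y):
            raise ValueError(f"term {name}: length mismatch")
        suffix = "" if lag == 0 else f"_m{lag}"
        names.append(name + suffix)
        cols.append(col)
    if interaction:
        if len(cols) != 2:
            raise ValueError("interaction requires exactly two predictors")
        mask = ~np.isnan(np.column_stack([y] + cols)).any(axis=1)
        a = cols[0] - np.nanmean(cols[0][mask])
        b = cols[1] - np.nanmean(cols[1][mask])
        cols = [a, b, a * b]
        names = [names[0] + "_c", names[1] + "_c", f"{names[0]}:{names[1]}"]
    X = np.column_stack(cols)
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    return y[keep], X[keep], names


# ---------------------------------------------------------------------------
# exact-likelihood GLS-ARMA core
# ---------------------------------------------------------------------------

def _to_arma(params: np.ndarray, p: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained reals onto stationary AR / invertible MA blocks."""
    ar = constrain_stationary_univariate(params[:p]) if p else np.empty(0)
    ma = -constrain_stationary_univariate(params[p:p + q]) if q else np.empty(0)
    return ar, ma


def _gls_profile(y: np.ndarray, X: np.ndarray, ar: np.ndarray, ma: np.ndarray):
    """Profile beta and sigma2 at fixed ARMA params; return pieces.

    The exact ARMA(p, q) covariance is applied through the innovations
    algorithm (O(n) per column): whitening y and the design columns by
    the one-step prediction errors is identical to solving with the
    Cholesky factor of the Toeplitz autocovariance matrix, and the sum
    of log prediction-error variances is its log-determinant.
    """
    stacked = np.column_stack([y, X])
    innov, mse = arma_innovations(stacked, ar_params=ar, ma_params=ma, sigma2=1.0)
    w = innov / np.sqrt(mse)[:, None]
    z, W = w[:, 0], w[:, 1:]
    beta, _, rank, _ = np.linalg.lstsq(W, z, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design not of full rank")
    resid_w = z - W @ beta
    rss = float(resid_w @ resid_w)
    logdet = float(np.log(mse).sum())
    return beta, rss, logdet, W, None


# deterministic jitter offsets for optimizer restarts (no seed needed)
_RESTART_JITTER = (0.0, 0.3, -0.3, 0.7, -0.7, 1.2)


def fit_gls_arma(y: np.ndarray, X: np.ndarray, order: ArmaOrder = ArmaOrder(2, 2),
                 terms: list[str] | None = None,
                 add_intercept: bool = True,
                 fallback_on_failure: bool = True) -> GlsFit:
    """Fit y = X b + e with stationary ARMA(p, q) Gaussian errors.

    Exact maximum likelihood: ARMA parameters are optimised on an
    unconstrained scale (partial-autocorrelation transform keeps every
    iterate stationary and invertible) while b and the innovation
    variance are profiled out.  ``order`` (0, 0) reduces to OLS exactly.
    On persistent optimizer failure the fit is retried at q - 1, the
    remedy that also resolves the occasional non-invertible coefficient
    matrix in practice.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values inside the fitted span; impute upstream")
    n = len(y)
    if terms is None:
        terms = [f"x{i + 1}" for i in range(X.shape[1])]
    terms = list(terms)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        terms = ["intercept"] + terms
    k = X.shape[1]
    if n <= k + order.p + order.q + 1:
        raise ValueError(f"series of length {n} too short for this model")
    p, q = order.p, order.q

    def neg_loglik(params: np.ndarray) -> float:
        try:
            ar, ma = _to_arma(params, p, q)
            _, rss, logdet, _, _ = _gls_profile(y, X, ar, ma)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        if rss <= 0:
            return 1e12
        s2 = rss / n
        return 0.5 * (n * np.log(2.0 * np.pi * s2) + n + logdet)

    converged = True
    if p + q == 0:
        params = np.empty(0)
    else:
        best = None
        for jit in _RESTART_JITTER:
            x0 = np.full(p + q, jit)
            res = optimize.minimize(neg_loglik, x0, method="L-BFGS-B",
                                    options={"maxiter": 200})
            if res.fun < 1e11:
                # short simplex polish; gradient-free, robust near kinks
                res = optimize.minimize(neg_loglik, res.x, method="Nelder-Mead",
                                        options={"xatol": 1e-5, "fatol": 1e-8,
                                                 "maxiter": 400})
            if res.fun < 1e11 and (best is None or res.fun < best.fun):
                best = res
            if best is not None and best.fun < 1e11 and jit == 0.0:
                break
        if best is None or best.fun >= 1e11:
            if fallback_on_failure and q > 0:
                return fit_gls_arma(y, X[:, 1:] if add_intercept else X,
                                    ArmaOrder(p, q - 1, order.d),
                                    terms=terms[1:] if add_intercept else terms,
                                    add_intercept=add_intercept)
            raise RuntimeError("GLS-ARMA optimizer failed at every restart")
        params = best.x
        converged = bool(best.success or best.fun < 1e11)

    ar, ma = _to_arma(params, p, q)
    beta, rss, logdet, W, _ = _gls_profile(y, X, ar, ma)
    s2_ml = rss / n
    loglik = -0.5 * (n * np.log(2.0 * np.pi * s2_ml) + n + logdet)
    n_params = k + p + q + 1  # + innovation variance
    aic = -2.0 * loglik + 2.0 * n_params
    s2 = rss / (n - k)
    cov = s2 * np.linalg.inv(W.T @ W)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)
    return GlsFit(
        terms=terms, coef=beta, se=se, t=tvals, p_values=pvals,
        ar_params=ar, ma_params=ma, sigma2=s2_ml, loglik=loglik, aic=aic,
        n=n, order=order, converged=converged,
        residuals=y - X @ beta,
    )


def select_arima_order(y: np.ndarray, x: np.ndarray | None = None,
                       max_p: int = 2, max_q: int = 2,
                       allow_d: tuple[int, ...] = (0, 1)) -> ArmaOrder:
    """Minimum-AIC (p, d, q) over a restricted grid, with x as regressor.

    All candidates are scored on the same effective sample (the series
    less its first value, differenced when d = 1) so AICs are
    comparable.  Ties break towards smaller p + q, then smaller q.
    Non-converging grid points are skipped.
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= 10 * (max_p + max_q):
        raise ValueError(
            f"series of length {len(y)} too short for order selection "
            f"up to ({max_p}, {max_q})"
        )
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    candidates = []
    for d in allow_d:
        yd = np.diff(y, n=d) if d else y[1:]
        xd = None
        if x is not None:
            xd = np.diff(x, n=d, axis=0) if d else x[1:]
        for p in range(max_p + 1):
            for q in range(max_q + 1):
                try:
                    fit = fit_gls_arma(yd, xd if xd is not None else np.empty((len(yd), 0)),
                                       ArmaOrder(p, q, d),
                                       add_intercept=True,
                                       fallback_on_failure=False)
                except (RuntimeError, ValueError, np.linalg.LinAlgError):
                    continue
                candidates.append((fit.aic, p + q, q, ArmaOrder(p, q, d)))
    if not candidates:
        raise RuntimeError("no grid point converged in order selection")
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    return candidates[0][3]


def lag_scan(gthi: np.ndarray, variable: np.ndarray, lags=(0, 1, 2),
             order: ArmaOrder = ArmaOrder(2, 2), name: str = "x") -> pd.DataFrame:
    """Single-term GLS-ARMA fit per lag, on a common response span.

    All fits drop the first max(lags) days so every lag sees the same
    response values, making t-ratios comparable across lags.
    """
    gthi = np.asarray(gthi, dtype=float)
    variable = np.asarray(variable, dtype=float)
    max_lag = max(lags)
    rows = []
    for lag in lags:
        y, X, names = build_design(gthi[max_lag:],
                                   [(name, variable[max_lag - lag:len(variable) - lag], 0)])
        fit = fit_gls_arma(y, X, order, terms=[f"{name}_m{lag}"])
        term = fit[fit.terms[1]]
        rows.append({"lag": lag, "term": fit.terms[1], "coef": term["coef"],
                     "se": term["se"], "t": term["t"], "P": term["P"],
                     "n": fit.n, "aic": fit.aic})
    return pd.DataFrame(rows)


def bonferroni_flags(p_values, m: int, alpha: float = 0.05) -> np.ndarray:
    """Significance at the Bonferroni-adjusted level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.asarray(p_values, dtype=float) < alpha / m


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

def granger_test(y: np.ndarray, x: np.ndarray, p: int = 2) -> GrangerResult:
    """Does x Granger-cause y?  Restricted-vs-unrestricted OLS F-test.

    Restricted model: y_t on its own p lags (plus constant); the
    unrestricted model adds p lags of x.  F = ((RSS_r - RSS_u)/p) /
    (RSS_u/(n - 2p - 1)) with P from F(p, n - 2p - 1).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("series lengths differ")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing values not allowed")
    if np.std(x) == 0.0:
        raise ValueError("x is constant: lagged design singular")
    n_eff = len(y) - p
    if n_eff <= 2 * p + 1:
        raise ValueError("series too short for the requested lag order")
    yt = y[p:]
    y_lags = np.column_stack([y[p - j:len(y) - j] for j in range(1, p + 1)])
    x_lags = np.column_stack([x[p - j:len(x) - j] for j in range(1, p + 1)])
    const = np.ones(n_eff)
    Xr = np.column_stack([const, y_lags])
    Xu = np.column_stack([const, y_lags, x_lags])

    def rss(X):
        b, _, rank, _ = np.linalg.lstsq(X, yt, rcond=None)
        if rank < X.shape[1]:
            raise ValueError("lagged design singular")
        r = yt - X @ b
        return float(r @ r)

    rss_r, rss_u = rss(Xr), rss(Xu)
    df2 = n_eff - (2 * p + 1)
    f = ((rss_r - rss_u) / p) / (rss_u / df2)
    return GrangerResult(f_stat=float(f), df1=p, df2=df2,
                         p_value=float(stats.f.sf(f, p, df2)), lag_order=p)


# ---------------------------------------------------------------------------
# non-stationarity diagnostics
# ---------------------------------------------------------------------------

@dataclass
class AcfSquaredResult:
    acf: np.ndarray  # lags 1..max_lag
    bound: float
    outside: np.ndarray
    ljung_box_p: float
    verdict: str  # none | weak | strong


def acf_squared_residuals(resid: np.ndarray, max_lag: int = 10,
                          strong_p: float = 0.01) -> AcfSquaredResult:
    """ACF of squared residuals, screening for variance non-stationarity.

    Bounds are +-1.96/sqrt(n).  The verdict is ``strong`` when at least
    two of lags 1-3 sit outside the bounds and the Ljung-Box P at lag 3
    is below ``strong_p``; ``weak`` when any of lags 1-3 is outside;
    else ``none``.
    """
    resid = np.asarray(resid, dtype=float)
    if np.isnan(resid).any():
        raise ValueError("residuals contain missing values")
    sq = resid ** 2
    if np.var(sq) == 0.0:
        raise ValueError("squared residuals are constant; ACF undefined")
    n = len(sq)
    rho = sample_acf(sq, nlags=max_lag, fft=True)[1:]
    bound = 1.96 / np.sqrt(n)
    outside = np.abs(rho) > bound
    # Ljung-Box over the first 3 lags, the range emphasised diagnostically
    m = min(3, max_lag)
    lb = n * (n + 2) * np.sum(rho[:m] ** 2 / (n - np.arange(1, m + 1)))
    lb_p = float(stats.chi2.sf(lb, df=m))
    if outside[:3].sum() >= 2 and lb_p < strong_p:
        verdict = "strong"
    elif outside[:3].any():
        verdict = "weak"
    else:
        verdict = "none"
    return AcfSquaredResult(acf=rho, bound=float(bound), outside=outside,
                            ljung_box_p=lb_p, verdict=verdict)


@dataclass
class Garch11Fit:
    omega: float
    alpha: float
    beta: float
    loglik: float
    converged: bool

    @property
    def persistence(self) -> float:
        return self.alpha + self.beta


def _garch11_sigma2(eps2: np.ndarray, omega: float, alpha: float,
                    beta: float, s2_init: float) -> np.ndarray:
    """Conditional variance recursion, vectorised through an IIR filter."""
    n = len(eps2)
    drive = omega + alpha * eps2[:-1]
    zi = np.array([beta * s2_init])
    tail, _ = signal.lfilter([1.0], [1.0, -beta], drive, zi=zi)
    return np.r_[s2_init, tail] if n > 1 else np.array([s2_init])


def fit_garch11(resid: np.ndarray) -> Garch11Fit:
    """Gaussian quasi-ML GARCH(1,1): s2_t = w + a e2_{t-1} + b s2_{t-1}.

    Constraints w > 0, a, b >= 0, a + b < 1; the recursion starts at the
    sample variance.  The mean is removed first.
    """
    resid = np.asarray(resid, dtype=float)
    if np.isnan(resid).any():
        raise ValueError("residuals contain missing values")
    n = len(resid)
    if n < 100:
        warnings.warn(f"GARCH(1,1) on only {n} observations is poorly determined")
    eps = resid - resid.mean()
    eps2 = eps ** 2
    var = float(eps2.mean())
    if var == 0.0:
        raise ValueError("residuals are constant")

    def nll(params):
        omega, alpha, beta = params
        if omega <= 0 or alpha < 0 or beta < 0 or alpha + beta >= 0.999:
            return 1e12
        s2 = _garch11_sigma2(eps2, omega, alpha, beta, var)
        if np.any(s2 <= 0):
            return 1e12
        return 0.5 * float(np.sum(np.log(s2) + eps2 / s2))

    x0 = np.array([0.1 * var, 0.1, 0.8])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
    omega, alpha, beta = res.x
    return Garch11Fit(omega=float(omega), alpha=float(max(alpha, 0.0)),
                      beta=float(max(beta, 0.0)), loglik=-float(res.fun),
                      converged=bool(res.success))


# ---------------------------------------------------------------------------
# subseries split-and-recombine
# ---------------------------------------------------------------------------

@dataclass
class SubseriesSummary:
    part_fits: list[GlsFit]
    combined: pd.DataFrame
    df: float
    parts: int
    combine_parts: tuple[int, ...]


def subseries_df(n: int, parts: int = 3) -> float:
    """Degrees of freedom used for recombined subseries t-tests: n/parts - 2."""
    df = n / parts - 2.0
    if df <= 0:
        raise ValueError("series too short for subseries recombination")
    return df


def split_and_recombine(y: np.ndarray, X: np.ndarray,
                        order: ArmaOrder = ArmaOrder(2, 2),
                        parts: int = 3,
                        breakpoints: list[int] | None = None,
                        combine_parts: tuple[int, ...] = (0, 2),
                        terms: list[str] | None = None) -> SubseriesSummary:
    """Fit GLS-ARMA per subseries and recombine the outer parts.

    A band with a volatility episode in its middle is split into a
    normal / volatile / normal triple (equal thirds by default, or at
    custom ``breakpoints``); the reported coefficient is the mean of the
    parts in ``combine_parts`` (first and third by default), the SE is
    the root-mean-square of their SEs, the t the mean of their t-values,
    and the P comes from Student-t with n/parts - 2 df.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if breakpoints is None:
        edges = [round(i * n / parts) for i in range(parts + 1)]
    else:
        edges = [0] + list(breakpoints) + [n]
        if len(edges) != parts + 1 or sorted(edges) != edges:
            raise ValueError("breakpoints must be increasing and define `parts` parts")
    fits = []
    for a, b in zip(edges[:-1], edges[1:]):
        fits.append(fit_gls_arma(y[a:b], X[a:b], order, terms=terms))
    df = subseries_df(n, parts)
    sel = [fits[i] for i in combine_parts]
    coef = np.mean([f.coef for f in sel], axis=0)
    se = np.sqrt(np.mean([f.se ** 2 for f in sel], axis=0))
    tval = np.mean([f.t for f in sel], axis=0)
    pval = 2.0 * stats.t.sf(np.abs(tval), df=df)
    combined = pd.DataFrame({"term": fits[0].terms, "coef": coef, "se": se,
                             "t": tval, "P": pval})
    return SubseriesSummary(part_fits=fits, combined=combined, df=df,
                            parts=parts, combine_parts=tuple(combine_parts))


# ---------------------------------------------------------------------------
# coefficient-level analyses
# ---------------------------------------------------------------------------

def predict_missing_coefficients(known_scaled: np.ndarray,
                                 known_gthch_max: np.ndarray,
                                 target_gthch_max: np.ndarray,
                                 target_gbh: np.ndarray | None = None,
                                 reference_gbh: float = 50.0) -> pd.DataFrame:
    """Predict missing (scaled) response coefficients from gthch_max.

    A simple linear regression of size-standardised coefficient on the
    diurnal girth-change maximum, over trees with both, yields
    predictions (with prediction SEs, including the residual component)
    for trees lacking a time-series fit.  When ``target_gbh`` is given
    the predictions are also back-scaled to each tree's own size.
    """
    xk = np.asarray(known_gthch_max, dtype=float)
    yk = np.asarray(known_scaled, dtype=float)
    if len(xk) != len(yk):
        raise ValueError("known arrays differ in length")
    if len(xk) < 3:
        raise ValueError(f"need >= 3 known trees, got {len(xk)}")
    x0 = np.atleast_1d(np.asarray(target_gthch_max, dtype=float))
    n = len(xk)
    xbar = xk.mean()
    sxx = float(((xk - xbar) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("gthch_max has no variation among known trees")
    slope = float(((xk - xbar) * (yk - yk.mean())).sum() / sxx)
    intercept = float(yk.mean() - slope * xbar)
    fitted = intercept + slope * xk
    resid = yk - fitted
    s2 = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    pred = intercept + slope * x0
    pred_se = np.sqrt(s2 * (1.0 + 1.0 / n + (x0 - xbar) ** 2 / sxx))
    out = pd.DataFrame({"gthch_max": x0, "predicted_scaled": pred,
                        "prediction_se": pred_se})
    if target_gbh is not None:
        gbh = np.atleast_1d(np.asarray(target_gbh, dtype=float))
        out["predicted"] = out["predicted_scaled"] * gbh / reference_gbh
        out["prediction_se_backscaled"] = out["prediction_se"] * gbh / reference_gbh
    return out


def rma_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Reduced-major-axis slope and intercept of y on x.

    slope = sign(r) * SD(y)/SD(x); intercept = mean(y) - slope*mean(x).
    Symmetric in the sense that swapping axes inverts the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0:
        raise ValueError("x has zero variance")
    r = np.corrcoef(x, y)[0, 1]
    sign = 1.0 if (r >= 0 or np.isnan(r)) else -1.0
    slope = sign * sy / sx
    return float(slope), float(y.mean() - slope * x.mean())


def rh_conditional_tests(gthi: np.ndarray, tdry14: np.ndarray, rh14: np.ndarray,
                         order: ArmaOrder = ArmaOrder(2, 2),
                         temp_slices: tuple[tuple[float, float], ...] = (
                             (29.3, 29.9), (30.0, 30.6), (30.7, 31.3)),
                         ) -> dict:
    """Three complementary checks for humidity effects on band readings.

    (a) regress RH14 on Tdry14 and use the residuals as the predictor of
    gthi in a GLS-ARMA fit — an effect of humidity beyond what
    temperature explains; (b) fit gthi ~ Tdry14 + Tdry14*RH14, where the
    interaction nests RH within temperature 'levels'; (c) within narrow
    temperature slices (default 0.7 °C wide around 29.3-31.3 °C)
    correlate gthi with RH14 directly.  Empty or tiny slices are skipped
    with a note.
    """
    gthi = np.asarray(gthi, dtype=float)
    tdry = np.asarray(tdry14, dtype=float)
    rh = np.asarray(rh14, dtype=float)
    mask = ~(np.isnan(gthi) | np.isnan(tdry) | np.isnan(rh))
    g, td, rhm = gthi[mask], tdry[mask], rh[mask]
    # (a) humidity residualised on temperature
    A = np.column_stack([np.ones(len(td)), td])
    bh, *_ = np.linalg.lstsq(A, rhm, rcond=None)
    rh_resid = rhm - A @ bh
    fit_resid = fit_gls_arma(g, rh_resid, order, terms=["rh_resid"])
    # (b) nested interaction
    fit_nested = fit_gls_arma(g, np.column_stack([td, td * rhm]), order,
                              terms=["tdry14", "tdry14:rh14"])
    # (c) temperature slices
    slices = []
    for lo, hi in temp_slices:
        sel = (td >= lo) & (td <= hi)
        n = int(sel.sum())
        if n < 3:
            slices.append({"lo": lo, "hi": hi, "n": n, "r": np.nan,
                           "P": np.nan, "note": "slice skipped: too few days"})
            continue
        r, p = stats.pearsonr(g[sel], rhm[sel])
        slices.append({"lo": lo, "hi": hi, "n": n, "r": float(r),
                       "P": float(p), "note": ""})
    return {"rh_residual_fit": fit_resid, "nested_interaction_fit": fit_nested,
            "temperature_slices": pd.DataFrame(slices)}
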