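"""End-to-end wiring: raw half-hourly series -> daily table -> GLS fits.

These helpers chain the per-module operations in the order the analysis
prescribes: align to the common frame, impute short half-hour gaps,
compute complete-day means, impute short day-level gaps, form next-day
increments, optionally residualise dry-period increments on rainfall,
and fit the GLS-ARMA regressions on the longest contiguous span.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gls_tsa, rain_adjustment, soil_climate, timeseries_core as tsc


def prepare_daily_series(series: tsc.HalfHourlyGirthSeries,
                         window: tsc.PeriodWindow,
                         max_halfhour_gap: int = 2,
                         max_day_gap: int = 2) -> tsc.DailyTreeSeries:
    """Half-hourly record -> daily gthm/gthi aligned to ``window``.

    Short gaps are filled at both resolutions (mean of the bounding
    values); a day only gets a mean when all 48 slots are present after
    imputation.  ``max_day_gap`` may be raised to bridge the longer
    band-outage gaps when a fully contiguous span is required.
    """
    aligned = tsc.align_to_frame(series, window)
    imputed = tsc.impute_short_gaps(aligned, max_gap=max_halfhour_gap)
    daily = tsc.daily_mean_girth(imputed, require_complete=True)
    daily = tsc.impute_short_gaps(daily, max_gap=max_day_gap)
    return tsc.daily_increment(daily)


def station_smp_series(sensors, window: tsc.PeriodWindow,
                       cleaning: str = "offset",
                       temp14: np.ndarray | None = None) -> pd.DataFrame:
    """Cleaned, station-averaged daily SMP over ``window``.

    The logger-temperature correction (when ``temp14`` is given) is
    applied before the offset/strict cleaning.  Returns a frame indexed
    by date with one column per station.
    """
    grid = window.dates()
    cleaned = []
    for s in sensors:
        sel = (s.dates >= grid[0]) & (s.dates <= grid[-1])
        sub = soil_climate.SensorSmpSeries(
            sensor_id=s.sensor_id, station=s.station,
            dates=s.dates[sel], smp=s.smp[sel.to_numpy() if hasattr(sel, "to_numpy") else sel],
        )
        if temp14 is not None:
            sub.smp = soil_climate.correct_smp_for_logger_temp(sub.smp, temp14[:len(sub.smp)])
        if cleaning == "offset":
            sub = soil_climate.offset_transform(sub)
        elif cleaning == "strict":
            sub = soil_climate.strict_transform(sub)
        elif cleaning != "raw":
            raise ValueError(f"unknown cleaning {cleaning!r}")
        cleaned.append(sub)
    return soil_climate.station_average_smp(cleaned).reindex(grid)


def fit_terms(gthi: np.ndarray, terms: list[tuple[str, np.ndarray, int]],
              order: gls_tsa.ArmaOrder = gls_tsa.ArmaOrder(2, 2),
              interaction: bool = False) -> gls_tsa.GlsFit:
    """GLS-ARMA fit of gthi on lagged terms, on the longest complete run."""
    y, X, names = _longest_run_design(np.asarray(gthi, dtype=float), terms)
    if interaction:
        y, X, names = gls_tsa.build_design(y, [(n, X[:, i], 0)
                                               for i, n in enumerate(names)],
                                           interaction=True)
    return gls_tsa.fit_gls_arma(y, X, order, terms=names)


def fit_band(daily: tsc.DailyTreeSeries, smp: np.ndarray, temp: np.ndarray,
             smp_lag: int = 1, temp_lag: int = 0,
             order: gls_tsa.ArmaOrder = gls_tsa.ArmaOrder(2, 2),
             two_term: bool = True,
             interaction: bool = False,
             rain: np.ndarray | None = None,
             rain_adjust_which: str = "current") -> gls_tsa.GlsFit:
    """Fit gthi ~ -sqrt(|SMP_-lag|) (+ TEMP) with ARMA(2,2) errors.

    ``smp`` and ``temp`` are daily series on the same date grid as
    ``daily``.  When ``rain`` is supplied (dry-period analysis) the
    increments are first residualised on ln(rainfall).  The fit uses
    the longest contiguous run of complete days.
    """
    gthi = daily.gthi.copy()
    if rain is not None:
        gthi, _ = rain_adjustment.rain_adjust(gthi, rain, band_id=daily.band_id,
                                              which_day=rain_adjust_which)
    x_s = soil_climate.smp_regression_transform(smp)
    terms = [("smp", x_s, smp_lag)]
    if two_term:
        terms.append(("temp", np.asarray(temp, dtype=float), temp_lag))
    return fit_terms(gthi, terms, order, interaction=interaction)


def _longest_run_design(gthi, terms):
    """Design rows and names from the longest contiguous run of usable days."""
    usable = ~np.isnan(gthi)
    lagged_cols, names = [], []
    for name, values, lag in terms:
        col = gls_tsa.lagged(np.asarray(values, dtype=float), lag)
        lagged_cols.append(col)
        names.append(name if lag == 0 else f"{name}_m{lag}")
        usable &= ~np.isnan(col)
    best_a = best_b = 0
    i, n = 0, len(usable)
    while i < n:
        if not usable[i]:
            i += 1
            continue
        j = i
        while j < n and usable[j]:
            j += 1
        if j - i > best_b - best_a:
            best_a, best_b = i, j
        i = j
    X = np.column_stack([c[best_a:best_b] for c in lagged_cols])
    return np.asarray(gthi[best_a:best_b], dtype=float), X, names


def coefficient_row(band_id: str, period: str, fit: gls_tsa.GlsFit,
                    gbh: float, term: str) -> dict:
    """One row of the tidy coefficients table for a fitted term."""
    est = fit[term]
    return {
        "band_id": band_id, "period": period, "term": term,
        "coef": est["coef"],
        "scaled_coef": tsc.scale_coefficient(est["coef"], gbh),
        "se": est["se"], "t": est["t"], "P": est["P"],
        "n": fit.n, "p": fit.order.p, "q": fit.order.q, "aic": fit.aic,
        "converged": fit.converged,
    }
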