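"""Rain-shower bark-swelling adjustment of dry-period girth increments.

In a dry period, showers transiently re-wet and swell the bark so the
band reads an apparent girth change that is not tree water status.  Per
band, a quadratic in ln(rainfall) is fitted by OLS to ``gthi`` on days
with >= 1 mm rain; on rain-free days the plain mean of ``gthi`` is
taken.  Residuals about the curve (rain days) and about the zero-rain
mean (dry days) then replace ``gthi`` downstream.  Fits are run with
current-day and with previous-day rainfall, since a minority of bands
respond to the previous day's showers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RainFit:
    """Per-band quadratic gthi ~ ln(rain) fit plus the zero-rain mean."""

    band_id: str
    which_day: str  # current | previous
    coefs: np.ndarray  # intercept, linear, quadratic in ln(rain)
    mean_gthi_at_zero: float
    n_rain_days: int
    n_zero_days: int
    f_stat: float
    p_value: float

    def curve(self, rain_mm) -> np.ndarray:
        """Fitted gthi at given rainfall (mm, must be >= the rain cutoff)."""
        lr = np.log(np.asarray(rain_mm, dtype=float))
        return self.coefs[0] + self.coefs[1] * lr + self.coefs[2] * lr ** 2


def _shift_rain(rain: np.ndarray, which_day: str) -> np.ndarray:
    if which_day == "current":
        return rain
    if which_day == "previous":
        out = np.full(len(rain), np.nan)
        out[1:] = rain[:-1]
        return out
    raise ValueError("which_day must be 'current' or 'previous'")


def fit_rain_response(gthi: np.ndarray, rain: np.ndarray,
                      which_day: str = "current",
                      band_id: str = "",
                      rain_cutoff: float = 1.0,
                      min_rain_days: int = 6,
                      min_zero_days: int = 3) -> RainFit:
    """OLS quadratic of gthi on ln(rain) over days with rain >= 1 mm.

    Days with rainfall below the cutoff (including trace rain < 1 mm)
    form the zero-rain pool, whose plain mean is estimated separately —
    pooling all days in one regression would be grossly heteroscedastic
    because most dry-period days have no rain at all.
    """
    gthi = np.asarray(gthi, dtype=float)
    rain = _shift_rain(np.asarray(rain, dtype=float), which_day)
    if len(gthi) != len(rain):
        raise ValueError("gthi and rain lengths differ")
    ok = ~(np.isnan(gthi) | np.isnan(rain))
    rain_days = ok & (rain >= rain_cutoff)
    zero_days = ok & (rain < rain_cutoff)
    n_rain, n_zero = int(rain_days.sum()), int(zero_days.sum())
    if n_rain < min_rain_days or n_zero < min_zero_days:
        raise ValueError(
            f"band {band_id}: insufficient days for rain fit "
            f"({n_rain} rain days, {n_zero} zero-rain days; "
            f"need >= {min_rain_days} and >= {min_zero_days})"
        )
    lr = np.log(rain[rain_days])
    X = np.column_stack([np.ones(n_rain), lr, lr ** 2])
    y = gthi[rain_days]
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_num, df_den = 2, n_rain - 3
    if df_den > 0 and rss > 0 and tss > rss:
        f = ((tss - rss) / df_num) / (rss / df_den)
        p = float(stats.f.sf(f, df_num, df_den))
    else:
        f, p = 0.0, 1.0
    return RainFit(
        band_id=band_id,
        which_day=which_day,
        coefs=coefs,
        mean_gthi_at_zero=float(gthi[zero_days].mean()),
        n_rain_days=n_rain,
        n_zero_days=n_zero,
        f_stat=float(f),
        p_value=p,
    )


def rain_residuals(gthi: np.ndarray, rain: np.ndarray, fit: RainFit,
                   rain_cutoff: float = 1.0) -> np.ndarray:
    """gthi residuals about the rain curve / zero-rain mean.

    Rain days (>= cutoff): gthi - fitted curve at ln(rain); zero-rain
    days: gthi - zero-rain mean.  The residual series replaces gthi in
    all downstream dry-period analyses.
    """
    gthi = np.asarray(gthi, dtype=float)
    rain = _shift_rain(np.asarray(rain, dtype=float), fit.which_day)
    out = np.full(len(gthi), np.nan)
    ok = ~(np.isnan(gthi) | np.isnan(rain))
    rain_days = ok & (rain >= rain_cutoff)
    zero_days = ok & (rain < rain_cutoff)
    out[rain_days] = gthi[rain_days] - fit.curve(rain[rain_days])
    out[zero_days] = gthi[zero_days] - fit.mean_gthi_at_zero
    return out


def rain_adjust(gthi: np.ndarray, rain: np.ndarray, band_id: str = "",
                which_day: str = "current", **kwargs) -> tuple[np.ndarray, RainFit]:
    """Convenience: fit then residualise in one step."""
    fit = fit_rain_response(gthi, rain, which_day=which_day, band_id=band_id, **kwargs)
    return rain_residuals(gthi, rain, fit), fit
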