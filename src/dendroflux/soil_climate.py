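"""Soil-moisture-potential cleaning and climate covariates.

Equitensiometer readings (kPa, physically <= 0; drier soil is more
negative) arrive with small positive offsets from the raw-signal
conversion and occasional implausibly low excursions.  Two cleaning
variants are used: an *offset* transform (subtract the per-sensor upper
0.95-quantile, clamp positives to zero) and a *strict* transform (clamp
to [-1000, 0] kPa).  Dry spells are maximal runs of more than three
consecutive days with station-averaged offset SMP at or below -150 kPa
(equivalently strict SMP <= -100 kPa).

Also here: the logger-temperature correction of SMP, trailing running
rainfall totals, the -sqrt(|SMP|) regression transform that tames the
strong left skew of SMP, and the SMP~rainfall-total correlation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries_core import PeriodWindow, window_length_days  # noqa: F401

#: dry-spell thresholds (kPa) for the two cleaning variants
OFFSET_DRY_THRESHOLD = -150.0
STRICT_DRY_THRESHOLD = -100.0
STRICT_FLOOR = -1000.0


@dataclass
class SensorSmpSeries:
    """One sensor's soil-moisture-potential record (kPa)."""

    sensor_id: str
    station: int
    dates: pd.DatetimeIndex
    smp: np.ndarray
    cleaned: str = "raw"  # raw | offset | strict

    def __post_init__(self) -> None:
        self.smp = np.asarray(self.smp, dtype=float)
        if len(self.dates) != len(self.smp):
            raise ValueError("dates and smp lengths differ")


@dataclass(frozen=True)
class DrySpell:
    start: date
    end: date
    mean_smp: float

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1


def correct_smp_for_logger_temp(smp_raw, temp):
    """Apply the logger-temperature correction -(T-20)/4 kPa.

    The equitensiometer conversion drifts linearly with logger internal
    temperature T (°C); at T = 30 °C the correction has magnitude 2.5 kPa
    (about 2% of a typical reading).
    """
    smp_raw = np.asarray(smp_raw, dtype=float)
    temp = np.asarray(temp, dtype=float)
    corrected = smp_raw + logger_temp_correction(temp)
    return corrected if corrected.ndim else float(corrected)


def logger_temp_correction(temp):
    """The correction term itself: -(T-20)/4 kPa."""
    temp = np.asarray(temp, dtype=float)
    corr = -(temp - 20.0) / 4.0
    return corr if corr.ndim else float(corr)


def offset_transform(sensor: SensorSmpSeries, quantile: float = 0.95,
                     min_obs: int = 20) -> SensorSmpSeries:
    """Subtract the per-sensor upper ``quantile`` and clamp positives to 0.

    Removes the small positive conversion offset individually per sensor.
    Refuses with fewer than ``min_obs`` observed values, where the
    quantile estimate is unstable.  Quantile estimator: linear
    interpolation of order statistics (type 7).
    """
    obs = sensor.smp[~np.isnan(sensor.smp)]
    if len(obs) < min_obs:
        raise ValueError(
            f"sensor {sensor.sensor_id}: {len(obs)} observed values "
            f"(< {min_obs}); quantile offset unstable"
        )
    q = np.quantile(obs, quantile)
    out = np.minimum(sensor.smp - q, 0.0)
    return dataclasses.replace(sensor, smp=out, cleaned="offset")


def strict_transform(sensor: SensorSmpSeries, floor: float = STRICT_FLOOR) -> SensorSmpSeries:
    """Clamp element-wise to [floor, 0] kPa (default floor -1000).

    Positives are measurement offsets; values below the floor (seen down
    to about -2 MPa on single sensors) are unrealistic at 20 cm depth.
    """
    out = np.clip(sensor.smp, floor, 0.0)
    return dataclasses.replace(sensor, smp=out, cleaned="strict")


def station_average_smp(sensors: list[SensorSmpSeries],
                        grouping: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-day unweighted mean SMP over sensors, grouped by station.

    ``grouping`` optionally maps station -> class label (e.g. lower-slope
    vs ridge), in which case averaging pools sensors per class.  A day is
    missing only where every contributing sensor is missing.
    """
    if not sensors:
        raise ValueError("no sensors supplied")
    frames = []
    for s in sensors:
        key = grouping[s.station] if grouping is not None else s.station
        frames.append(pd.DataFrame({"group": key, "date": s.dates, "smp": s.smp}))
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(index="date", columns="group", values="smp", aggfunc="mean")
    return wide


def detect_dry_spells(dates: pd.DatetimeIndex, smp: np.ndarray,
                      threshold: float = OFFSET_DRY_THRESHOLD,
                      min_run_days: int = 4) -> list[DrySpell]:
    """Maximal runs of >= ``min_run_days`` consecutive days with
    smp <= ``threshold``.

    The default threshold is for offset-cleaned series (-150 kPa); pass
    ``STRICT_DRY_THRESHOLD`` for strict series.  A missing day breaks a
    run.  Input days must be contiguous (daily grid).
    """
    smp = np.asarray(smp, dtype=float)
    if len(dates) != len(smp):
        raise ValueError("dates and smp lengths differ")
    if len(dates) > 1 and not (np.diff(dates.asi8) == 86400 * 10 ** 9).all():
        raise ValueError("dates must form a contiguous daily grid")
    below = (~np.isnan(smp)) & (smp <= threshold)
    spells: list[DrySpell] = []
    i = 0
    n = len(below)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if j - i >= min_run_days:
            spells.append(
                DrySpell(
                    start=dates[i].date(),
                    end=dates[j - 1].date(),
                    mean_smp=float(smp[i:j].mean()),
                )
            )
        i = j
    return spells


def running_rain_total(rain: np.ndarray, n: int) -> np.ndarray:
    """Trailing ``n``-day rainfall total including the current day (mm).

    The first n-1 entries are missing; a missing daily value propagates
    into every window containing it.
    """
    if n < 1:
        raise ValueError("window length must be >= 1")
    s = pd.Series(np.asarray(rain, dtype=float))
    return s.rolling(window=n, min_periods=n).sum().to_numpy()


def smp_regression_transform(smp):
    """Regression transform -sqrt(|SMP|), reducing the left skew of SMP.

    Monotone non-increasing in |SMP|; 0 maps to 0, -100 kPa to -10.
    """
    smp = np.asarray(smp, dtype=float)
    out = -np.sqrt(np.abs(smp))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    n: int
    p: float


def smp_rain_correlation(smp: np.ndarray, rft: np.ndarray) -> CorrelationResult:
    """Pearson correlation of -sqrt(|SMP|) with sqrt(rainfall total).

    Both sides are square-root transformed to linearise the relation;
    only jointly observed days enter.  Reports r, t = r*sqrt(n-2)/
    sqrt(1-r²) and the two-sided P.
    """
    smp = np.asarray(smp, dtype=float)
    rft = np.asarray(rft, dtype=float)
    if np.nanmin(rft, initial=0.0) < 0:
        raise ValueError("rainfall totals must be non-negative")
    mask = ~(np.isnan(smp) | np.isnan(rft))
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 jointly observed days")
    x = smp_regression_transform(smp[mask])
    y = np.sqrt(rft[mask])
    r, p = stats.pearsonr(x, y)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    return CorrelationResult(r=float(r), t=float(t), n=n, p=float(p))


def first_complete_span(dates: pd.DatetimeIndex, values: np.ndarray,
                        min_days: int = 2) -> PeriodWindow:
    """Longest contiguous run of observed days, as a PeriodWindow."""
    mask = ~np.isnan(np.asarray(values, dtype=float))
    best = (0, -1)
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        if j - i > best[1] - best[0] + 1:
            best = (i, j - 1)
        i = j
    if best[1] - best[0] + 1 < min_days:
        raise ValueError("no sufficiently long complete span")
    return PeriodWindow(start=dates[best[0]].date(), end=dates[best[1]].date())
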