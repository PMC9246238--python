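"""Diurnal girth-change profiles and the wet-period confidence envelope.

Within-day girth change is expressed relative to the midnight value:
``gthch_t = ((girth_t - girth_1) / girth_1) * 1e4`` for the 48 half-hour
slots t = 1..48.  A day with any missing slot contributes no profile.
The long wet period is cut into consecutive 18-day sub-periods whose
mean profiles, treated as independent replicates, give a Student-t
confidence envelope; a dry-period mean profile falling outside the
envelope at any slot rejects, at 1 - level, the hypothesis that wet and
dry diurnal behaviour are the same.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries_core import SLOTS_PER_DAY, HalfHourlyGirthSeries, PeriodWindow

GTHCH_SCALE = 1e4


@dataclass
class DiurnalProfile:
    """Mean diurnal girth-change profile (x 1e4, slot 1 = midnight = 0)."""

    band_id: str
    values: np.ndarray  # 48 slot means
    n_days: int
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != SLOTS_PER_DAY:
            raise ValueError(f"profile must have {SLOTS_PER_DAY} slots")


@dataclass
class Envelope:
    """Mean-of-means profile with per-slot confidence bounds."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_subperiods: int
    level: float

    def __post_init__(self) -> None:
        for arr in (self.mean, self.lower, self.upper):
            if len(arr) != SLOTS_PER_DAY:
                raise ValueError(f"envelope arrays must have {SLOTS_PER_DAY} slots")
        if not (np.all(self.lower <= self.mean) and np.all(self.mean <= self.upper)):
            raise ValueError("bounds must bracket the mean at every slot")


def gthch_day(day_girth: np.ndarray) -> np.ndarray:
    """Relative girth change x 1e4 for one complete day of 48 slots.

    Returns all-NaN when any slot is missing (incomplete days carry no
    diurnal information).  Slot 1 is exactly 0 by construction, and the
    result is invariant to rescaling the whole day by a constant.
    """
    day_girth = np.asarray(day_girth, dtype=float)
    if len(day_girth) != SLOTS_PER_DAY:
        raise ValueError(f"a day has {SLOTS_PER_DAY} half-hour slots")
    if np.isnan(day_girth).any():
        return np.full(SLOTS_PER_DAY, np.nan)
    g1 = day_girth[0]
    return (day_girth - g1) / g1 * GTHCH_SCALE


def exclude_heavy_rain_days(days: pd.DatetimeIndex, rain: pd.Series,
                            cutoff: float = 10.0) -> pd.DatetimeIndex:
    """Drop days with rainfall >= ``cutoff`` mm before profile averaging.

    Heavy showers re-wet dry bark and transiently swell it, biasing
    dry-period diurnal profiles; lighter showers are retained.
    """
    keep = []
    for d in days:
        r = rain.get(d, np.nan)
        if np.isnan(r) or r < cutoff:
            keep.append(d)
    return pd.DatetimeIndex(keep)


def _day_matrix(series: HalfHourlyGirthSeries) -> tuple[pd.DatetimeIndex, np.ndarray]:
    n = len(series)
    if n % SLOTS_PER_DAY != 0:
        raise ValueError("series must cover whole days (align_to_frame first)")
    days = series.index[::SLOTS_PER_DAY].normalize()
    mat = series.girth.reshape(-1, SLOTS_PER_DAY)
    return days, mat


def period_profile(series: HalfHourlyGirthSeries,
                   include_days: pd.DatetimeIndex | None = None,
                   label: str = "") -> DiurnalProfile:
    """Mean gthch profile over the (optionally restricted) days of a series."""
    days, mat = _day_matrix(series)
    rows = []
    for i, d in enumerate(days):
        if include_days is not None and d not in include_days:
            continue
        prof = gthch_day(mat[i])
        if not np.isnan(prof).any():
            rows.append(prof)
    if not rows:
        return DiurnalProfile(series.band_id, np.full(SLOTS_PER_DAY, np.nan), 0, label)
    return DiurnalProfile(series.band_id, np.mean(rows, axis=0), len(rows), label)


def subperiod_profiles(series: HalfHourlyGirthSeries, window: PeriodWindow,
                       block_days: int = 18,
                       include_days: pd.DatetimeIndex | None = None
                       ) -> list[DiurnalProfile]:
    """Mean profiles over consecutive non-overlapping ``block_days`` blocks.

    The window is tiled from its start; trailing remainder days are
    dropped (550 days with 18-day blocks -> 30 blocks, last 10 days
    ignored).  Each block's profile averages its qualifying complete
    days.
    """
    if window.n_days < block_days:
        raise ValueError(
            f"window of {window.n_days} days shorter than block of {block_days}"
        )
    from .timeseries_core import align_to_frame

    aligned = align_to_frame(series, window)
    days, mat = _day_matrix(aligned)
    n_blocks = window.n_days // block_days
    profiles = []
    for b in range(n_blocks):
        rows = []
        for i in range(b * block_days, (b + 1) * block_days):
            if include_days is not None and days[i] not in include_days:
                continue
            prof = gthch_day(mat[i])
            if not np.isnan(prof).any():
                rows.append(prof)
        values = np.mean(rows, axis=0) if rows else np.full(SLOTS_PER_DAY, np.nan)
        profiles.append(
            DiurnalProfile(series.band_id, values, len(rows), label=f"block{b + 1}")
        )
    return profiles


def wet_envelope(profiles: list[DiurnalProfile], level: float = 0.99) -> Envelope:
    """Mean of sub-period mean profiles with Student-t confidence bounds.

    Sub-periods are treated as independent replicates: per slot the
    bounds are mean ± t_{level, n-1} * SD / sqrt(n).  Requires at least
    three profiles with data.
    """
    mats = [p.values for p in profiles if not np.isnan(p.values).all()]
    n = len(mats)
    if n < 3:
        raise ValueError(f"need >= 3 sub-period profiles, got {n}")
    arr = np.vstack(mats)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    half = tcrit * sd / np.sqrt(n)
    return Envelope(mean=mean, lower=mean - half, upper=mean + half,
                    n_subperiods=n, level=level)


def compare_dry_to_envelope(dry: DiurnalProfile, env: Envelope) -> pd.DataFrame:
    """Slot-wise position of a dry-period profile against the envelope.

    Returns a 48-row frame with columns ``slot``, ``value``, ``flag``
    (below / inside / above).  Any slot outside rejects equality of wet
    and dry diurnal behaviour at P < 1 - level.
    """
    flags = np.where(
        np.isnan(dry.values), "missing",
        np.where(dry.values < env.lower, "below",
                 np.where(dry.values > env.upper, "above", "inside")),
    )
    return pd.DataFrame(
        {"slot": np.arange(1, SLOTS_PER_DAY + 1), "value": dry.values, "flag": flags}
    )


def any_outside(comparison: pd.DataFrame) -> bool:
    """Summary indicator: does any slot fall outside the envelope?"""
    return bool(comparison["flag"].isin(["below", "above"]).any())


def profile_min_max(profile: DiurnalProfile) -> tuple[float, float]:
    """(gthch_min, gthch_max): extremes of the mean profile over 48 slots."""
    if np.isnan(profile.values).all():
        raise ValueError("profile has no data")
    return float(np.nanmin(profile.values)), float(np.nanmax(profile.values))
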