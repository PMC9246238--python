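"""Calendar alignment, gap imputation and daily girth aggregation.

Dendrometer bands log stem girth (cm) every 30 minutes, 48 slots per
calendar day with the midnight slot opening the new day.  Everything
downstream — daily means ``gthm``, next-day increments ``gthi``, diurnal
profiles — assumes series aligned to a common day grid with explicit
missingness, which this module provides.

Units: girth in cm; ``gthi`` in cm·10⁻³ per day; ``agr`` in mm per year.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

SLOTS_PER_DAY = 48
GTHI_SCALE = 1e3  # cm -> cm*10^-3


@dataclass(frozen=True)
class PeriodWindow:
    """Inclusive calendar window, e.g. the 550-day wet period."""

    start: date
    end: date
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"window end {self.end} before start {self.start}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


@dataclass
class HalfHourlyGirthSeries:
    """One band's girth record on the 30-minute grid.

    ``girth`` uses NaN for missing; ``imputed`` marks values filled by
    :func:`impute_short_gaps`.
    """

    band_id: str
    index: pd.DatetimeIndex
    girth: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.girth = np.asarray(self.girth, dtype=float)
        if len(self.index) != len(self.girth):
            raise ValueError("index and girth lengths differ")
        if len(self.index) > 1:
            steps = np.diff(self.index.asi8)
            if not np.all(steps == 30 * 60 * 10 ** 9):
                raise ValueError("timestamps must lie on a strict 30-min grid")
        if np.nanmin(self.girth, initial=np.inf) <= 0:
            raise ValueError("girth must be positive where present")
        if self.imputed is None:
            self.imputed = np.zeros(len(self.girth), dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)

    def __len__(self) -> int:
        return len(self.girth)


@dataclass
class DailyTreeSeries:
    """Per-day mean girth and next-day increment for one band.

    ``gthm`` is the mean of the 48 half-hour values (cm); ``gthi`` the
    increment to the following day in cm·10⁻³, defined only where both
    days have ``gthm``.
    """

    band_id: str
    dates: pd.DatetimeIndex
    gthm: np.ndarray
    gthi: np.ndarray = field(default=None)  # type: ignore[assignment]
    complete: np.ndarray = field(default=None)  # type: ignore[assignment]
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gthm = np.asarray(self.gthm, dtype=float)
        n = len(self.dates)
        if len(self.gthm) != n:
            raise ValueError("dates and gthm lengths differ")
        if self.gthi is None:
            self.gthi = np.full(n, np.nan)
        else:
            self.gthi = np.asarray(self.gthi, dtype=float)
        if self.complete is None:
            self.complete = ~np.isnan(self.gthm)
        if self.imputed is None:
            self.imputed = np.zeros(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_id": self.band_id,
                "date": self.dates,
                "gthm": self.gthm,
                "gthi": self.gthi,
                "complete": self.complete,
                "imputed": self.imputed,
            }
        )


@dataclass(frozen=True)
class TreeRecord:
    """Static per-tree covariates (girth at breast height, guild, position)."""

    band_id: str
    species_code: str
    gbh: float
    station: int
    scl: int | None = None
    x: float | None = None
    y: float | None = None
    can_stat: float | None = None
    overstorey_threshold: float = 60.0

    def __post_init__(self) -> None:
        if self.gbh <= 0:
            raise ValueError("gbh must be positive")
        expected = 2 if self.gbh > self.overstorey_threshold else 1
        if self.scl is None:
            object.__setattr__(self, "scl", expected)
        elif self.scl != expected:
            raise ValueError(
                f"scl={self.scl} inconsistent with gbh={self.gbh} and "
                f"threshold {self.overstorey_threshold}"
            )

    @property
    def basal_area(self) -> float:
        """Stem basal area in cm², assuming a circular stem: gbh²/(4π)."""
        return self.gbh ** 2 / (4.0 * np.pi)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def half_hour_grid(window: PeriodWindow) -> pd.DatetimeIndex:
    """48-slot grid covering ``window``; midnight opens each day."""
    start = pd.Timestamp(window.start)
    return pd.date_range(start, periods=window.n_days * SLOTS_PER_DAY, freq="30min")


def align_to_frame(
    series: HalfHourlyGirthSeries, window: PeriodWindow
) -> HalfHourlyGirthSeries:
    """Reindex onto the common frame of ``window`` (missing where absent).

    Values are never altered; slots outside the input are NaN.
    """
    grid = half_hour_grid(window)
    s = pd.Series(series.girth, index=series.index).reindex(grid)
    imp = pd.Series(series.imputed, index=series.index).reindex(grid, fill_value=False)
    return HalfHourlyGirthSeries(
        band_id=series.band_id,
        index=grid,
        girth=s.to_numpy(),
        imputed=imp.to_numpy(dtype=bool),
    )


def _impute_values(values: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Fill interior NaN runs of length <= max_gap with the bounding mean."""
    out = values.copy()
    filled = np.zeros(len(values), dtype=bool)
    isnan = np.isnan(values)
    i = 0
    n = len(values)
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        run = j - i
        # interior run, bounded on both sides
        if 0 < i and j < n and run <= max_gap:
            fill = 0.5 * (values[i - 1] + values[j])
            out[i:j] = fill
            filled[i:j] = True
        i = j
    return out, filled


def impute_short_gaps(series, max_gap: int = 2):
    """Fill missing runs of <= ``max_gap`` values with the mean of the
    bounding pair; longer and edge runs stay missing.

    Works on the half-hourly girth grid (gap unit: 30 min) and on daily
    series (gap unit: days).  Observed values are never changed, and the
    operation is idempotent.
    """
    if isinstance(series, HalfHourlyGirthSeries):
        girth, filled = _impute_values(series.girth, max_gap)
        return HalfHourlyGirthSeries(
            band_id=series.band_id,
            index=series.index,
            girth=girth,
            imputed=series.imputed | filled,
        )
    if isinstance(series, DailyTreeSeries):
        gthm, filled = _impute_values(series.gthm, max_gap)
        out = DailyTreeSeries(
            band_id=series.band_id,
            dates=series.dates,
            gthm=gthm,
            complete=series.complete.copy(),
            imputed=series.imputed | filled,
        )
        return out
    raise TypeError(f"unsupported series type {type(series).__name__}")


def daily_mean_girth(
    series: HalfHourlyGirthSeries, require_complete: bool = True
) -> DailyTreeSeries:
    """Mean girth per calendar day (``gthm``, cm).

    A day counts as complete only when all 48 half-hour slots are present
    (after any upstream imputation).  With ``require_complete`` the mean of
    an incomplete day is left missing, mirroring how incomplete days are
    excluded from increment analysis.
    """
    n = len(series)
    if n % SLOTS_PER_DAY != 0:
        raise ValueError("series must cover whole days (align_to_frame first)")
    days = n // SLOTS_PER_DAY
    values = series.girth.reshape(days, SLOTS_PER_DAY)
    imputed = series.imputed.reshape(days, SLOTS_PER_DAY)
    present = ~np.isnan(values)
    complete = present.all(axis=1)
    counts = present.sum(axis=1)
    partial = np.where(counts > 0, np.nansum(values, axis=1) / np.maximum(counts, 1), np.nan)
    gthm = np.where(complete, partial, np.nan if require_complete else partial)
    dates = series.index[::SLOTS_PER_DAY].normalize()
    return DailyTreeSeries(
        band_id=series.band_id,
        dates=dates,
        gthm=gthm,
        complete=complete,
        imputed=imputed.any(axis=1),
    )


def daily_increment(daily: DailyTreeSeries) -> DailyTreeSeries:
    """Next-day girth increment ``gthi = (gthm_{i+1} − gthm_i)·10³``.

    The increment for day *i* is attached to day *i* (its left endpoint)
    and is missing whenever either bounding ``gthm`` is missing; the last
    day has no increment.
    """
    gthm = daily.gthm
    gthi = np.full(len(gthm), np.nan)
    gthi[:-1] = (gthm[1:] - gthm[:-1]) * GTHI_SCALE
    return dataclasses.replace(daily, gthi=gthi)


def compute_agr(daily: DailyTreeSeries, window: PeriodWindow | None = None) -> float:
    """Simple-difference absolute growth rate, mm/yr, over ``window``.

    Uses ``gthm`` at (or nearest inside to) the window endpoints; a year is
    365.25 days.  Nearly proportional to mean ``gthi`` (factor ≈ 3.65 =
    10·365.25/10³ mm·yr⁻¹ per cm·10⁻³·d⁻¹).
    """
    dates = daily.dates
    mask = ~np.isnan(daily.gthm)
    if window is not None:
        inside = (dates >= pd.Timestamp(window.start)) & (dates <= pd.Timestamp(window.end))
        mask = mask & inside.to_numpy()
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise ValueError("need gthm on at least two days inside the window")
    i0, i1 = idx[0], idx[-1]
    span_days = (dates[i1] - dates[i0]).days
    if span_days == 0:
        raise ValueError("window endpoints coincide")
    return (daily.gthm[i1] - daily.gthm[i0]) * 10.0 * 365.25 / span_days


def scale_coefficient(coef: float, gbh: float, reference_gbh: float = 50.0) -> float:
    """Standardise a response coefficient to a reference stem size.

    Multiplies by ``reference_gbh / gbh`` (default 50 cm), making slopes
    comparable across trees of different girth.  Invertible via
    :func:`unscale_coefficient`.
    """
    if gbh <= 0:
        raise ValueError("gbh must be positive")
    return coef * reference_gbh / gbh


def unscale_coefficient(scaled: float, gbh: float, reference_gbh: float = 50.0) -> float:
    """Inverse of :func:`scale_coefficient`."""
    if gbh <= 0:
        raise ValueError("gbh must be positive")
    return scaled * gbh / reference_gbh


def neighbourhood_ba_d(
    focal: TreeRecord,
    neighbours: list[TreeRecord],
    radius: float = 5.0,
    min_gbh: float = 10.0,
) -> float:
    """Distance-weighted neighbourhood basal-area index BA/d (cm²/m).

    Sums BA_j / d_j over neighbours with gbh >= ``min_gbh`` within
    ``radius`` metres of the focal tree (focal excluded).  A neighbour at
    zero distance has no defined weight and is rejected.
    """
    if focal.x is None or focal.y is None:
        raise ValueError("focal tree lacks coordinates")
    total = 0.0
    for nb in neighbours:
        if nb.band_id == focal.band_id:
            continue
        if nb.x is None or nb.y is None:
            raise ValueError(f"neighbour {nb.band_id} lacks coordinates")
        if nb.gbh < min_gbh:
            continue
        d = float(np.hypot(nb.x - focal.x, nb.y - focal.y))
        if d == 0.0:
            raise ValueError(f"neighbour {nb.band_id} at zero distance from focal")
        if d <= radius:
            total += nb.basal_area / d
    return total


def window_length_days(window: PeriodWindow) -> int:
    """Inclusive calendar day count of a window."""
    return window.n_days


def window_mask(dates: pd.DatetimeIndex, window: PeriodWindow) -> np.ndarray:
    """Boolean mask of the dates falling inside an inclusive window."""
    return np.asarray((dates >= pd.Timestamp(window.start))
                      & (dates <= pd.Timestamp(window.end)))


def iterate_window_days(window: PeriodWindow):
    """Brute-force day iterator (used as an independent calendar oracle)."""
    d = window.start
    while d <= window.end:
        yield d
        d = d + timedelta(days=1)
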