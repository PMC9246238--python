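"""Readers and writers for the delimited-text input/output dialects.

All tables are plain CSV with ISO-8601 timestamps; readers tolerate
CR/LF line endings and quoted fields (pandas defaults).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .soil_climate import SensorSmpSeries
from .timeseries_core import DailyTreeSeries, HalfHourlyGirthSeries, TreeRecord


def write_girth_table(series: list[HalfHourlyGirthSeries], path) -> None:
    frames = [
        pd.DataFrame({"band_id": s.band_id, "timestamp": s.index, "girth_cm": s.girth})
        for s in series
    ]
    out = pd.concat(frames, ignore_index=True)
    out = out[~out["girth_cm"].isna()]  # missingness is implicit: absent rows
    out.to_csv(path, index=False)


def read_girth_table(path) -> list[HalfHourlyGirthSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for band_id, grp in df.groupby("band_id", sort=True):
        grp = grp.sort_values("timestamp")
        idx = pd.DatetimeIndex(grp["timestamp"])
        # re-grid onto a strict 30-min grid spanning the band's record
        grid = pd.date_range(idx[0].floor("D"), idx[-1].ceil("D") - pd.Timedelta("30min"),
                             freq="30min")
        s = pd.Series(grp["girth_cm"].to_numpy(), index=idx).reindex(grid)
        out.append(HalfHourlyGirthSeries(band_id=str(band_id), index=grid,
                                         girth=s.to_numpy()))
    return out


def write_sensor_table(sensors: list[SensorSmpSeries], path) -> None:
    frames = [
        pd.DataFrame({"sensor_id": s.sensor_id, "station": s.station,
                      "date": s.dates, "smp_kpa": s.smp})
        for s in sensors
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensor_table(path) -> list[SensorSmpSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for (sensor_id, station), grp in df.groupby(["sensor_id", "station"], sort=True):
        grp = grp.sort_values("date")
        out.append(SensorSmpSeries(sensor_id=str(sensor_id), station=int(station),
                                   dates=pd.DatetimeIndex(grp["date"]),
                                   smp=grp["smp_kpa"].to_numpy()))
    return out


def write_climate_table(dates, rain, temp14, path) -> None:
    pd.DataFrame({"date": dates, "rain_mm": rain, "temp14_c": temp14}).to_csv(
        path, index=False)


def read_climate_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df.sort_values("date").reset_index(drop=True)


def write_tree_table(records: list[TreeRecord], path) -> None:
    pd.DataFrame(
        [
            {"band_id": r.band_id, "species_code": r.species_code, "gbh": r.gbh,
             "scl": r.scl, "station": r.station, "x": r.x, "y": r.y,
             "can_stat": r.can_stat}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_tree_table(path) -> list[TreeRecord]:
    df = pd.read_csv(path)
    return [
        TreeRecord(band_id=str(r.band_id), species_code=str(r.species_code),
                   gbh=float(r.gbh), station=int(r.station),
                   scl=int(r.scl) if not pd.isna(r.scl) else None,
                   x=float(r.x) if not pd.isna(r.x) else None,
                   y=float(r.y) if not pd.isna(r.y) else None,
                   can_stat=float(r.can_stat) if not pd.isna(r.can_stat) else None)
        for r in df.itertuples()
    ]


def write_daily_table(daily: list[DailyTreeSeries], path) -> None:
    pd.concat([d.to_frame() for d in daily], ignore_index=True).to_csv(path, index=False)


def write_coefficients_table(rows: list[dict], path) -> None:
    """One tidy coefficients table per analysis run."""
    pd.DataFrame(rows).to_csv(path, index=False)
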