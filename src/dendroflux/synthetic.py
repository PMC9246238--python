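"""Synthetic dendroband / climate generator with known ground truth.

Emulates the study conditions the analysis pipeline assumes: an everwet
tropical rainfall regime with embedded multi-week dry spells; soil
moisture potential (SMP) behaving as a bucket that is recharged by rain
and drawn down by temperature-driven evapotranspiration, read by several
noisy, positively biased sensors per station; logger temperature at
14:00 following a bounded AR(1); and per-tree girth built from a daily
random walk whose increments respond linearly to -sqrt(|SMP|) lagged one
day and to same-day temperature, with ARMA(2,2) daily noise, a smooth
within-day swelling/shrinkage cycle, a quadratic-in-ln(rain) bark
swelling artefact on rain days, and injected missing-value gaps.

True per-tree response coefficients are emitted separately (SimTruth)
and never written into the analysis-facing tables, so every pipeline
stage can be validated by parameter recovery.

Default dimensions mirror the study the pipeline targets: 18 banded
trees at 4 stations with 3-4 SMP sensors each, a 550-day wet period and
a 98-day dry period inside a 1614-day frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
from scipy import signal

from .timeseries_core import (
    SLOTS_PER_DAY,
    HalfHourlyGirthSeries,
    PeriodWindow,
    TreeRecord,
)

FULL_FRAME = PeriodWindow(date(2007, 3, 1), date(2011, 7, 31), "frame")
WET_WINDOW = PeriodWindow(date(2007, 3, 17), date(2008, 9, 16), "wet")
DRY_WINDOW = PeriodWindow(date(2010, 3, 18), date(2010, 6, 23), "dry")

#: rain-suppression span producing the low-SMP episode of early 2010;
#: starts about a month before the SMP-defined dry period, as the soil
#: moisture response lags the rainfall deficit
DEFAULT_DRY_SPELLS = (
    PeriodWindow(date(2010, 2, 10), date(2010, 6, 18), "rain_deficit"),
)


@dataclass(frozen=True)
class TreeParams:
    """Ground-truth parameters for one simulated band."""

    band_id: str
    species_code: str
    station: int
    gbh: float  # cm at start
    beta_s_scaled: float  # response to -sqrt(|SMP_-1|), at 50 cm gbh
    beta_t_scaled: float  # response to TEMP_0, at 50 cm gbh
    diurnal_amplitude: float  # gthch units (x 1e4)
    bark_b1: float = 0.0  # linear term in ln(rain), gthi units
    bark_b2: float = 0.0  # quadratic term
    target_mean_gthi: float = 1.5  # cm*1e-3 / day
    long_gap: tuple[int, int] | None = None  # (start day offset, length days)

    @property
    def beta_s(self) -> float:
        """Raw (unscaled) SMP coefficient for this tree's own size."""
        return self.beta_s_scaled * self.gbh / 50.0

    @property
    def beta_t(self) -> float:
        return self.beta_t_scaled * self.gbh / 50.0


def default_trees() -> list[TreeParams]:
    """The default 18-band stand: 4 stations, mixed sizes and guilds.

    Sizes and station layout follow the banded-tree table of the target
    study; planted responses are mixed-sign, positive for most small
    (understorey) trees and negative for the large overstorey ones, the
    pattern the wet-period analysis is expected to recover.
    """
    rows = [
        # band, species, station, gbh, bS*, bT*, amp
        ("g11", "Mw", 1, 31, 1.2, 1.1, 8.0),
        ("g12", "Sf", 1, 97, -1.5, 0.8, 2.5),
        ("g14", "Lb", 1, 31, -0.4, -0.3, 6.0),
        ("g15", "Sf", 1, 27, 2.2, 1.8, 12.0),
        ("g22", "Pm", 2, 74, -1.1, 0.9, 3.0),
        ("g23", "Dm", 2, 30, 0.9, 1.6, 7.0),
        ("g24", "Mw", 2, 34, 0.7, 1.0, 9.0),
        ("g25", "Sf", 2, 33, 2.6, 2.4, 14.0),
        ("g31", "Mw", 3, 34, 0.5, 1.2, 8.0),
        ("g32", "Sp", 3, 78, -1.8, 0.6, 2.0),
        ("g33", "Lb", 3, 39, -0.6, -0.2, 5.0),
        ("g34", "Dm", 3, 39, 1.0, 1.9, 6.0),
        ("g35", "Dm", 3, 48, 0.6, 1.5, 5.0),
        ("g41", "Sf", 4, 31, 1.9, 2.1, 13.0),
        ("g42", "Dm", 4, 33, 0.8, 1.4, 7.0),
        ("g43", "Pm", 4, 117, -1.3, 0.7, 2.0),
        ("g44", "Sp", 4, 97, -2.0, 0.5, 2.5),
        ("g45", "Pm", 4, 69, -0.9, 0.8, 3.5),
    ]
    trees = []
    for band, sp, st, gbh, bs, bt, amp in rows:
        # a mild bark artefact on every band; two bands get a long outage
        long_gap = {"g14": (120, 12), "g31": (300, 17)}.get(band)
        trees.append(
            TreeParams(
                band_id=band, species_code=sp, station=st, gbh=float(gbh),
                beta_s_scaled=bs, beta_t_scaled=bt, diurnal_amplitude=amp,
                bark_b1=0.8, bark_b2=0.35, long_gap=long_gap,
            )
        )
    return trees


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults ARE the study conditions."""

    seed: int
    window: PeriodWindow = FULL_FRAME
    trees: tuple[TreeParams, ...] = field(default_factory=lambda: tuple(default_trees()))
    # rainfall (zero-inflated gamma, everwet regime)
    rain_wet_prob: float = 0.60
    rain_gamma_shape: float = 0.7
    rain_gamma_scale: float = 18.0  # -> ~7.6 mm/day long-run mean
    dry_spells: tuple[PeriodWindow, ...] = DEFAULT_DRY_SPELLS
    dry_rain_prob: float = 0.45
    dry_rain_scale: float = 2.5  # light showers dominate a dry spell
    dry_heavy_prob: float = 0.06  # occasional >= 10 mm shower
    dry_heavy_scale: float = 12.0
    # temperature AR(1) at 14:00, deg C
    temp_mean: float = 26.9
    temp_rho: float = 0.6
    temp_sd: float = 0.7
    temp_bounds: tuple[float, float] = (23.5, 31.5)
    # SMP bucket (kPa)
    smp_gain_in: float = 4.0  # kPa recharge per mm rain
    smp_gain_out: float = 1.6  # kPa loss per deg C above 20, per day
    smp_floor: float = -500.0
    bark_dry_threshold: float = -100.0  # bark artefact only when this dry
    n_sensors_per_station: tuple[int, ...] = (4, 3, 4, 3)
    sensor_bias_range: tuple[float, float] = (2.0, 12.0)  # positive offsets
    sensor_noise_sd: float = 3.0
    sensor_extreme_prob: float = 0.0015
    sensor_extreme_value: float = -2000.0
    # daily gthi noise, ARMA(2,2), units cm*1e-3
    arma_ar: tuple[float, float] = (0.55, -0.12)
    arma_ma: tuple[float, float] = (0.22, 0.10)
    noise_sd: float = 2.0
    # half-hourly missingness (event rates per slot)
    single_gap_rate: float = 0.003
    pair_gap_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        from statsmodels.tsa.arima_process import ArmaProcess

        proc = ArmaProcess(np.r_[1.0, -np.asarray(self.arma_ar)],
                           np.r_[1.0, np.asarray(self.arma_ma)])
        if not (proc.isstationary and proc.isinvertible):
            raise ValueError("ARMA noise parameters must be stationary and invertible")
        if self.noise_sd < 0 or self.sensor_noise_sd < 0 or self.temp_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class ClimateFields:
    """Daily climate realisation shared by all trees."""

    dates: pd.DatetimeIndex
    rain: np.ndarray  # mm/day
    temp14: np.ndarray  # deg C
    smp_latent: dict[int, np.ndarray]  # per-station true SMP, kPa (<= 0)
    sensors: list  # SensorSmpSeries (raw readings)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the data, never consumed by it."""

    trees: pd.DataFrame
    dry_spell_windows: tuple[PeriodWindow, ...]

    def to_frame(self) -> pd.DataFrame:
        return self.trees


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def simulate_climate(config: SimConfig, rng: np.random.Generator | None = None
                     ) -> ClimateFields:
    """Draw one realisation of rainfall, temperature and sensor SMP."""
    from .soil_climate import SensorSmpSeries

    rng = np.random.default_rng(config.seed) if rng is None else rng
    dates = config.window.dates()
    n = len(dates)

    in_spell = np.zeros(n, dtype=bool)
    for w in config.dry_spells:
        in_spell |= np.asarray((dates >= pd.Timestamp(w.start)) &
                               (dates <= pd.Timestamp(w.end)))

    p_wet = np.where(in_spell, config.dry_rain_prob, config.rain_wet_prob)
    scale = np.where(in_spell, config.dry_rain_scale, config.rain_gamma_scale)
    wet = rng.random(n) < p_wet
    amounts = rng.gamma(config.rain_gamma_shape, scale)
    # a dry spell still sees the odd heavier shower
    heavy = in_spell & (rng.random(n) < config.dry_heavy_prob)
    amounts = np.where(heavy, rng.gamma(2.0, config.dry_heavy_scale, n), amounts)
    rain = np.where(wet | heavy, amounts, 0.0)

    temp = np.empty(n)
    innov_sd = config.temp_sd * np.sqrt(1.0 - config.temp_rho ** 2)
    temp[0] = config.temp_mean + rng.normal(0.0, config.temp_sd)
    z = rng.normal(0.0, innov_sd, n)
    for i in range(1, n):
        temp[i] = (config.temp_mean
                   + config.temp_rho * (temp[i - 1] - config.temp_mean) + z[i])
    # dry spells run warmer (clearer skies); keeps TEMP~SMP negatively coupled
    temp = temp + 0.8 * in_spell
    temp = np.clip(temp, *config.temp_bounds)

    smp_latent: dict[int, np.ndarray] = {}
    sensors = []
    stations = sorted({t.station for t in config.trees}) or [1, 2, 3, 4]
    for s_i, station in enumerate(stations):
        gain_in = config.smp_gain_in * rng.uniform(0.9, 1.1)
        smp = np.empty(n)
        level = 0.0
        for i in range(n):
            level = level + gain_in * rain[i] - config.smp_gain_out * max(temp[i] - 20.0, 0.0)
            level = float(np.clip(level, config.smp_floor, 0.0))
            smp[i] = level
        smp_latent[station] = smp
        n_sens = config.n_sensors_per_station[s_i % len(config.n_sensors_per_station)]
        for j in range(n_sens):
            bias = rng.uniform(*config.sensor_bias_range)
            reading = smp + bias + rng.normal(0.0, config.sensor_noise_sd, n)
            extreme = rng.random(n) < config.sensor_extreme_prob
            reading = np.where(extreme, config.sensor_extreme_value, reading)
            sensors.append(
                SensorSmpSeries(sensor_id=f"s{station}{j + 1}", station=station,
                                dates=dates, smp=reading)
            )
    return ClimateFields(dates=dates, rain=rain, temp14=temp,
                         smp_latent=smp_latent, sensors=sensors)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def diurnal_shape() -> np.ndarray:
    """Unit within-day girth-change shape over 48 slots.

    Zero at midnight, peak about +0.8 mid-morning (~10:00), trough -1
    mid-afternoon (~15:30), recovering towards the next midnight.
    """
    hours = np.arange(SLOTS_PER_DAY) / 2.0
    shape = (0.8 * np.exp(-0.5 * ((hours - 10.0) / 2.2) ** 2)
             - 1.0 * np.exp(-0.5 * ((hours - 15.5) / 2.6) ** 2))
    return shape - shape[0]


def _arma_noise(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    burn = 200
    z = rng.normal(0.0, config.noise_sd, n + burn)
    ar = np.r_[1.0, -np.asarray(config.arma_ar)]
    ma = np.r_[1.0, np.asarray(config.arma_ma)]
    return signal.lfilter(ma, ar, z)[burn:]


def bark_effect(rain: np.ndarray, b1: float, b2: float,
                rain_cutoff: float = 1.0,
                dry_bark: np.ndarray | None = None) -> np.ndarray:
    """Quadratic-in-ln(rain) bark-swelling contribution to gthi.

    The artefact is a shower re-wetting *dry* bark; in an everwet period
    the bark never dries, so ``dry_bark`` (a boolean day mask, typically
    soil drier than -100 kPa the day before) restricts it to dry spells.
    """
    rain = np.asarray(rain, dtype=float)
    out = np.zeros(len(rain))
    wet = rain >= rain_cutoff
    if dry_bark is not None:
        wet &= np.asarray(dry_bark, dtype=bool)
    lr = np.log(rain[wet])
    out[wet] = b1 * lr + b2 * lr ** 2
    return out


def planted_predictor(tree: TreeParams, climate: ClimateFields) -> np.ndarray:
    """The tree's true daily linear predictor of gthi (no noise, no bark)."""
    smp = climate.smp_latent[tree.station]
    temp = climate.temp14
    smp_lag1 = np.r_[smp[0], smp[:-1]]  # day 0 reuses its own value
    x_s = -np.sqrt(np.abs(smp_lag1))
    beta0 = (tree.target_mean_gthi
             - tree.beta_s * x_s.mean() - tree.beta_t * temp.mean())
    return beta0 + tree.beta_s * x_s + tree.beta_t * temp


def simulate_tree(climate: ClimateFields, tree: TreeParams, config: SimConfig,
                  rng: np.random.Generator | None = None,
                  noise: bool = True, missing: bool = True,
                  bark: bool = True) -> HalfHourlyGirthSeries:
    """One band's half-hourly girth series for the climate realisation.

    The daily mean path integrates the planted linear predictor plus
    ARMA(2,2) noise plus the bark term; half-hourly values modulate each
    day's mean with a zero-mean diurnal cycle, so daily means recover
    the path exactly and, with noise off, the recomputed increments
    reproduce the planted predictor exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = len(climate.dates)
    incr = planted_predictor(tree, climate).copy()
    if noise:
        incr = incr + _arma_noise(rng, config, n)
    if bark:
        # bark dries out only through a sustained rain deficit; a single
        # damp day in an everwet stretch leaves it saturated
        in_spell = np.zeros(n, dtype=bool)
        for w in config.dry_spells:
            in_spell |= np.asarray((climate.dates >= pd.Timestamp(w.start)) &
                                   (climate.dates <= pd.Timestamp(w.end)))
        smp = climate.smp_latent[tree.station]
        dry_soil = np.r_[False, smp[:-1] <= config.bark_dry_threshold]
        incr = incr + bark_effect(climate.rain, tree.bark_b1, tree.bark_b2,
                                  dry_bark=in_spell & dry_soil)
    # increment for day i spans i -> i+1; the last day's increment unused
    gthm = tree.gbh + 1e-3 * np.r_[0.0, np.cumsum(incr[:-1])]

    shape = diurnal_shape()
    shape_centered = shape - shape.mean()
    girth = (gthm[:, None]
             * (1.0 + tree.diurnal_amplitude / 1e4 * shape_centered[None, :]))
    values = girth.ravel()

    if missing:
        n_slots = len(values)
        singles = rng.random(n_slots) < config.single_gap_rate
        values[singles] = np.nan
        pair_starts = np.flatnonzero(rng.random(n_slots) < config.pair_gap_rate)
        for s in pair_starts:
            values[s:s + 2] = np.nan
        if tree.long_gap is not None:
            d0, length = tree.long_gap
            values[d0 * SLOTS_PER_DAY:(d0 + length) * SLOTS_PER_DAY] = np.nan

    index = pd.date_range(pd.Timestamp(config.window.start),
                          periods=n * SLOTS_PER_DAY, freq="30min")
    return HalfHourlyGirthSeries(band_id=tree.band_id, index=index, girth=values)


# ---------------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------------

def tree_records(config: SimConfig, rng: np.random.Generator | None = None
                 ) -> list[TreeRecord]:
    """Static metadata table for the simulated stand (with coordinates)."""
    rng = np.random.default_rng(config.seed + 7919 if rng is None else None) \
        if rng is None else rng
    station_xy = {1: (20.0, 20.0), 2: (20.0, 80.0), 3: (80.0, 20.0), 4: (80.0, 80.0)}
    records = []
    for t in config.trees:
        cx, cy = station_xy.get(t.station, (50.0, 50.0))
        records.append(
            TreeRecord(
                band_id=t.band_id, species_code=t.species_code, gbh=t.gbh,
                station=t.station,
                x=cx + rng.uniform(-15.0, 15.0), y=cy + rng.uniform(-15.0, 15.0),
                can_stat=float(np.clip(1.426 + 0.0276 * t.gbh + rng.normal(0, 0.3),
                                       1.0, 5.0)),
            )
        )
    return records


def simulate_dataset(config: SimConfig) -> tuple[ClimateFields, list[HalfHourlyGirthSeries], SimTruth]:
    """Full draw: climate, all tree series, and the ground truth."""
    rng = np.random.default_rng(config.seed)
    climate = simulate_climate(config, rng)
    series = [simulate_tree(climate, t, config, rng) for t in config.trees]
    truth_rows = []
    for t in config.trees:
        truth_rows.append({
            "band_id": t.band_id, "species_code": t.species_code,
            "station": t.station, "gbh": t.gbh,
            "beta_s": t.beta_s, "beta_t": t.beta_t,
            "beta_s_scaled": t.beta_s_scaled, "beta_t_scaled": t.beta_t_scaled,
            "diurnal_amplitude": t.diurnal_amplitude,
            "bark_b1": t.bark_b1, "bark_b2": t.bark_b2,
        })
    truth = SimTruth(trees=pd.DataFrame(truth_rows),
                     dry_spell_windows=config.dry_spells)
    return climate, series, truth


def emit_dataset(config: SimConfig, outdir) -> SimTruth:
    """Write the bundle as delimited text in the pipeline's input dialects.

    Files: ``girth.csv`` (band_id, timestamp, girth_cm), ``sensors.csv``
    (sensor_id, station, date, smp_kpa), ``climate.csv`` (date, rain_mm,
    temp14_c), ``trees.csv`` (metadata) and ``truth.csv`` (SimTruth,
    separate from everything the pipeline reads).
    """
    from pathlib import Path

    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    climate, series, truth = simulate_dataset(config)
    dio.write_girth_table(series, outdir / "girth.csv")
    dio.write_sensor_table(climate.sensors, outdir / "sensors.csv")
    dio.write_climate_table(climate.dates, climate.rain, climate.temp14,
                            outdir / "climate.csv")
    dio.write_tree_table(tree_records(config), outdir / "trees.csv")
    truth.trees.to_csv(outdir / "truth.csv", index=False)
    return truth
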