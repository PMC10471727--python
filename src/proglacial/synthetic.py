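"""Fully synthetic proglacial world with stored ground truth.

The generator lays out one mountain patch per glacier on a single projected
grid (meters), each with a conical summit, a retreating glacier outline (two
epochs), and temperature-logger stations scattered over the foreland.  Glaciers
are assigned to three latitude bands (Northern, Inter-tropical, Southern) which
double as regions, so the hierarchical weighting scheme always has multiple
levels to exercise.

Every observable is generated from known coefficients of the monthly soil
model (natural scale, converted exactly to the standardized scale actually
fitted), a glacier random intercept, seasonal macroclimate with a linear
warming trend, solar-geometry-consistent radiation, and an
elevation/macroclimate snow rule; hourly logger traces add a snow-damped
diurnal cycle and AR(1) noise.  All randomness flows from one seed through
named substreams, so each artifact is bit-reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter
from shapely.geometry import Point

from . import radiation as rad
from . import terrain as terr
from .loggers import LoggerSeries
from .raster import Raster
from .soil_model import (
    CONTINUOUS_PREDICTORS,
    FIXED_TERMS,
    INTERACTIONS,
    Standardization,
    build_design,
)

#: Generating coefficients on the natural scale.  Interactions multiply the
#: natural columns (sfd in %, mT in °C, rad in MJ m-2 d-1, sqrt(dg) in m^0.5,
#: d in cm); every term is nonzero so each is individually recoverable.
DEFAULT_NATURAL_COEFFICIENTS: dict[str, float] = {
    "intercept": 1.0,
    "mT": 0.55,
    "rad": 0.08,
    "sfd": 0.02,
    "dg": 0.01,
    "tc": -0.8,
    "pf": -0.5,
    "d": -0.08,
    "sfd:mT": 0.005,
    "sfd:rad": 0.005,
    "sfd:dg": 0.004,
    "sfd:d": -0.003,
    "tc:rad": -0.06,
}

#: Latitude-band climates: (band name, latitude, sea-level mean °C, seasonal
#: amplitude °C, month of the warm peak).
BAND_CLIMATES = (
    ("Northern", 47.0, 16.0, 10.0, 7),
    ("Inter-tropical", -8.0, 18.0, 1.5, 7),
    ("Southern", -44.0, 16.0, 10.0, 1),
)

_STREAMS = {
    "terrain": 0,
    "stations": 1,
    "intercepts": 2,
    "snow": 3,
    "residual": 4,
    "trace": 5,
    "satellite": 6,
    "treecover": 7,
}


@dataclass
class WorldConfig:
    """Study conditions of the synthetic world (defaults mirror the field study:
    26 forelands, ~7 stations each, ~2 years of monthly records)."""

    n_glaciers: int = 26
    stations_per_glacier: int = 7
    n_months: int = 24
    dem_size: int = 32  # cells per side of each glacier's patch
    cell_size: float = 30.0
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NATURAL_COEFFICIENTS)
    )
    coefficients_standardized: bool = False  # natural scale by default
    glacier_intercept_sd: float = 1.0
    residual_sd: float = 1.0
    diurnal_amplitude_snowfree: float = 5.0
    diurnal_amplitude_snow: float = 0.2
    cloud_missing_prob: float = 0.2
    trend: float = 0.5  # °C per decade on macroclimate
    seed: int = 0
    relief: float = 500.0  # m of within-patch elevation range
    base_elevation: float = 2300.0
    snow_jitter: float = 0.1  # per-day probability of flipping the snow state
    ar1_rho: float = 0.6  # lag-1 autocorrelation of the hourly noise
    start: str = "2019-01"  # first calibration month
    period_gap_years: float = 15.0  # midpoint gap between the two projection periods

    def __post_init__(self) -> None:
        for name in ("n_glaciers", "stations_per_glacier", "n_months", "dem_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"WorldConfig.{name} must be >= 1")
        if self.dem_size < 16:
            raise ValueError("WorldConfig.dem_size must be >= 16")
        for name in ("glacier_intercept_sd", "residual_sd", "relief"):
            if getattr(self, name) < 0:
                raise ValueError(f"WorldConfig.{name} must be >= 0")
        if not 0.0 <= self.cloud_missing_prob <= 1.0:
            raise ValueError("WorldConfig.cloud_missing_prob must lie in [0, 1]")
        if not self.diurnal_amplitude_snow < self.diurnal_amplitude_snowfree:
            raise ValueError(
                "WorldConfig.diurnal_amplitude_snow must be smaller than "
                "diurnal_amplitude_snowfree (snow insulation must be detectable)"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=self.n_months, freq="M")


@dataclass
class WorldTruth:
    natural_coefficients: pd.Series
    standardized_coefficients: pd.Series
    glacier_intercepts: dict[str, float]
    snow_calendar: dict[str, pd.DatetimeIndex]  # station -> snow-covered days
    monthly: pd.DataFrame  # per station-month truth incl. soilT and covariates
    standardization: Standardization


@dataclass
class World:
    config: WorldConfig
    terrain: terr.TerrainGrid
    outlines_epoch1: list
    outlines_epoch2: list
    glaciers: pd.DataFrame  # glacier_id, band/region, latitude, longitude, patch row/col
    stations: pd.DataFrame  # station metadata incl. covariate constants
    factors: rad.TerrainRadiationFactors
    distance_epoch1: Raster
    distance_epoch2: Raster
    tc_raster: Raster
    pf_raster: Raster
    truth: WorldTruth

    @property
    def monthly_table(self) -> pd.DataFrame:
        return self.truth.monthly


# ---------------------------------------------------------------------------
# terrain and glacier layout
# ---------------------------------------------------------------------------

def _patch_layout(n: int) -> tuple[int, int]:
    ncol = int(math.ceil(math.sqrt(n)))
    nrow = int(math.ceil(n / ncol))
    return nrow, ncol


def generate_terrain(config: WorldConfig):
    """DEM plus two-epoch glacier outlines (epoch 2 retreated inside epoch 1)."""
    rng = config.rng("terrain")
    prow, pcol = _patch_layout(config.n_glaciers)
    ps = config.dem_size
    nrow, ncol = prow * ps, pcol * ps
    extent = ps * config.cell_size
    z = np.full((nrow, ncol), config.base_elevation)
    summits = []
    for g in range(config.n_glaciers):
        pr, pc = divmod(g, pcol)
        rr = slice(pr * ps, (pr + 1) * ps)
        cc = slice(pc * ps, (pc + 1) * ps)
        yy, xx = np.mgrid[0:ps, 0:ps]
        # summit placed off-center so aspect varies between glaciers
        sr = ps * (0.35 + 0.3 * rng.random())
        sc = ps * (0.35 + 0.3 * rng.random())
        dist = np.hypot(yy - sr, xx - sc) / ps
        z[rr, cc] += config.relief * np.maximum(0.0, 1.0 - 1.6 * dist)
        summits.append((pr * ps + sr, pc * ps + sc))
    if config.relief > 0:
        z += gaussian_filter(rng.standard_normal(z.shape), 3.0) * 0.06 * config.relief
    dem = Raster(z, origin=(0.0, nrow * config.cell_size), cell_size=config.cell_size)
    outlines1, outlines2 = [], []
    r1 = 0.16 * extent
    for (srow, scol) in summits:
        x = (scol + 0.5) * config.cell_size
        y = dem.origin[1] - (srow + 0.5) * config.cell_size
        # epoch-2 front sits slightly inside epoch 1 (ongoing retreat)
        outlines1.append(Point(x, y).buffer(r1, quad_segs=16))
        outlines2.append(Point(x, y).buffer(0.95 * r1, quad_segs=16))
    return dem, outlines1, outlines2


def _band_of_glacier(g: int) -> tuple[str, float, float, float, int]:
    return BAND_CLIMATES[g % len(BAND_CLIMATES)]


def _sea_level_temperature(config: WorldConfig, band_idx: int, period: pd.Period) -> float:
    name, lat, t0, amp, peak = BAND_CLIMATES[band_idx]
    months_since = (period - pd.Period(config.start, freq="M")).n
    seasonal = amp * math.cos(2.0 * math.pi * (period.month - peak) / 12.0)
    return t0 + seasonal + config.trend * months_since / 120.0


# ---------------------------------------------------------------------------
# world assembly
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig) -> World:
    """Build the full world: terrain, stations, covariates, truth table."""
    dem, outlines1, outlines2 = generate_terrain(config)
    tg = terr.slope_aspect(dem)
    factors = rad.horizon_and_svf(tg, n_sectors=24, max_search=25 * config.cell_size)
    dist1 = terr.distance_to_glacier(outlines1, dem)
    dist2 = terr.distance_to_glacier(outlines2, dem)

    # tree cover: patchy low-elevation vegetation; permafrost: high elevations
    tc_rng = config.rng("treecover")
    noise = gaussian_filter(tc_rng.standard_normal(dem.shape), 2.0)
    tc_mask = (noise > np.quantile(noise, 0.65)) & (
        dem.data < np.quantile(dem.data, 0.75)
    )
    # permafrost probability rises linearly with elevation; occurrence is the
    # conservative prob >= 0.9, i.e. the upper part of each cone
    rel = max(config.relief, 1.0)
    pf_prob = np.clip(
        (dem.data - (config.base_elevation + 0.05 * rel)) / (0.5 * rel), 0.0, 1.0
    )
    tc_raster = dem.like(tc_mask.astype(float))
    pf_raster = dem.like((pf_prob >= 0.9).astype(float))

    prow, pcol = _patch_layout(config.n_glaciers)
    ps = config.dem_size
    st_rng = config.rng("stations")
    glacier_rows = []
    station_rows = []
    for g in range(config.n_glaciers):
        band_idx = g % len(BAND_CLIMATES)
        band, lat, *_ = BAND_CLIMATES[band_idx]
        gid = f"G{g:02d}"
        pr, pc = divmod(g, pcol)
        glacier_rows.append(
            {
                "glacier_id": gid,
                "region": band,
                "band_idx": band_idx,
                "latitude": lat + 0.5 * st_rng.standard_normal(),
                "longitude": 10.0 + 0.3 * g,
                "patch_row": pr,
                "patch_col": pc,
            }
        )
        rr = slice(pr * ps, (pr + 1) * ps)
        cc = slice(pc * ps, (pc + 1) * ps)
        local_dist = dist2.data[rr, cc]
        cand = np.argwhere(
            (local_dist > config.cell_size) & (local_dist < 0.65 * ps * config.cell_size)
        )
        if len(cand) < config.stations_per_glacier:
            raise RuntimeError(f"glacier {gid}: not enough candidate station cells")
        pick = st_rng.choice(len(cand), size=config.stations_per_glacier, replace=False)
        for k, idx in enumerate(pick):
            row = pr * ps + cand[idx][0]
            col = pc * ps + cand[idx][1]
            station_rows.append(
                {
                    "station_id": f"{gid}S{k}",
                    "glacier_id": gid,
                    "region": band,
                    "band_idx": band_idx,
                    "row": int(row),
                    "col": int(col),
                    "latitude": glacier_rows[-1]["latitude"] + 1e-4 * cand[idx][0],
                    "longitude": glacier_rows[-1]["longitude"] + 1e-4 * cand[idx][1],
                    "elevation": float(dem.data[row, col]),
                    "slope": float(tg.slope.data[row, col]),
                    "aspect": float(tg.aspect.data[row, col]),
                    "svf": float(factors.svf[row, col]),
                    "dg": float(dist2.data[row, col]),
                    "tc": float(tc_raster.data[row, col]),
                    "pf": float(pf_raster.data[row, col]),
                    "d": float(st_rng.choice([5, 10, 15])),
                }
            )
    glaciers = pd.DataFrame(glacier_rows)
    stations = pd.DataFrame(station_rows)

    truth = _build_truth(config, tg, factors, glaciers, stations)
    return World(
        config=config,
        terrain=tg,
        outlines_epoch1=outlines1,
        outlines_epoch2=outlines2,
        glaciers=glaciers,
        stations=stations,
        factors=factors,
        distance_epoch1=dist1,
        distance_epoch2=dist2,
        tc_raster=tc_raster,
        pf_raster=pf_raster,
        truth=truth,
    )


def _station_macro_temperature(config: WorldConfig, station: pd.Series, period: pd.Period) -> float:
    t_sl = _sea_level_temperature(config, int(station["band_idx"]), period)
    return t_sl - 0.0065 * station["elevation"]


def _snow_calendar_for_station(
    config: WorldConfig, station: pd.Series, rng: np.random.Generator
) -> tuple[pd.DatetimeIndex, pd.DataFrame]:
    """Daily snow states: snow when the downscaled monthly mean is below 0 °C,
    with independent per-day jitter; returns the calendar and per-month sfd."""
    snow_days = []
    month_rows = []
    for period in config.months:
        mt = _station_macro_temperature(config, station, period)
        base_snow = mt < 0.0
        days = pd.date_range(period.start_time, period.end_time, freq="D", tz="UTC")
        flip = rng.random(len(days)) < config.snow_jitter
        snow = np.full(len(days), base_snow) ^ flip
        snow_days.extend(days[snow])
        month_rows.append(
            {
                "year": period.year,
                "month": period.month,
                "mT": mt,
                # expressed as count/n so detection recounts reproduce it bitwise
                "sfd": 100.0 * float(len(days) - snow.sum()) / len(days),
                "n_days": len(days),
                "n_snow_days": int(snow.sum()),
            }
        )
    return pd.DatetimeIndex(snow_days), pd.DataFrame(month_rows)


def hourly_solar_positions(lat: float, lon: float, year: int, month: int) -> list[rad.SolarPosition]:
    """Solar positions for the 24 local-solar-time hours of the 15th day."""
    out = []
    base = datetime(year, month, 15, tzinfo=timezone.utc)
    for h in range(24):
        when = base + timedelta(hours=h - lon / 15.0)
        out.append(rad.solar_position(lat, lon, when))
    return out


def _monthly_forcing(config: WorldConfig, band_idx: int, period: pd.Period) -> tuple[float, float]:
    """(clearness index, adjacent albedo) for a band and month."""
    _, _, _, _, peak = BAND_CLIMATES[band_idx]
    kt = 0.55 + 0.15 * math.cos(2.0 * math.pi * (period.month - peak) / 12.0)
    t_mid = _sea_level_temperature(config, band_idx, period) - 0.0065 * config.base_elevation
    albedo = 0.6 if t_mid < 0 else 0.2
    return kt, albedo


def _hourly_samples(
    config: WorldConfig, band_idx: int, lat: float, lon: float, period: pd.Period
) -> list[tuple[rad.RadiationSample, rad.SolarPosition]]:
    kt_month, albedo = _monthly_forcing(config, band_idx, period)
    out = []
    for h, pos in enumerate(hourly_solar_positions(lat, lon, period.year, period.month)):
        etr = rad.extraterrestrial_horizontal(pos)
        downward = kt_month * etr
        net = 0.8 * downward
        out.append((rad.make_sample(h, downward, net, pos, albedo), pos))
    return out


def _station_radiation(
    config: WorldConfig,
    factors: rad.TerrainRadiationFactors,
    glaciers: pd.DataFrame,
    stations: pd.DataFrame,
) -> pd.DataFrame:
    """Daily cumulative absorbed shortwave per station and month (MJ m-2 d-1)."""
    rows = []
    for _, gl in glaciers.iterrows():
        sts = stations[stations["glacier_id"] == gl["glacier_id"]]
        rsel = sts["row"].to_numpy()
        csel = sts["col"].to_numpy()
        slope = sts["slope"].to_numpy()
        aspect = sts["aspect"].to_numpy()
        sub = rad.TerrainRadiationFactors(
            svf=factors.svf[rsel, csel],
            horizon=factors.horizon[:, rsel, csel],
            n_sectors=factors.n_sectors,
        )
        for period in config.months:
            hourly = []
            for sample, pos in _hourly_samples(
                config, int(gl["band_idx"]), gl["latitude"], gl["longitude"], period
            ):
                hourly.append(rad.absorbed_hourly(sample, pos, sub, slope, aspect))
            daily = rad.daily_cumulative(np.asarray(hourly))
            for sid, val in zip(sts["station_id"], daily):
                rows.append(
                    {"station_id": sid, "year": period.year, "month": period.month, "rad": val}
                )
    return pd.DataFrame(rows)


def _build_truth(
    config: WorldConfig,
    tg: terr.TerrainGrid,
    factors: rad.TerrainRadiationFactors,
    glaciers: pd.DataFrame,
    stations: pd.DataFrame,
) -> WorldTruth:
    snow_rng = config.rng("snow")
    calendars: dict[str, pd.DatetimeIndex] = {}
    frames = []
    for _, st in stations.iterrows():
        cal, months = _snow_calendar_for_station(config, st, snow_rng)
        calendars[st["station_id"]] = cal
        months.insert(0, "station_id", st["station_id"])
        frames.append(months)
    monthly = pd.concat(frames, ignore_index=True)
    rad_tab = _station_radiation(config, factors, glaciers, stations)
    monthly = monthly.merge(rad_tab, on=["station_id", "year", "month"])
    const_cols = ["station_id", "glacier_id", "region", "dg", "tc", "pf", "d"]
    monthly = monthly.merge(stations[const_cols], on="station_id")

    int_rng = config.rng("intercepts")
    intercepts = {
        gid: config.glacier_intercept_sd * int_rng.standard_normal()
        for gid in glaciers["glacier_id"]
    }

    beta_nat = pd.Series(
        {t: config.true_coefficients.get(t, 0.0) for t in FIXED_TERMS}, index=list(FIXED_TERMS)
    )
    if config.coefficients_standardized:
        raise NotImplementedError(
            "generation from standardized coefficients is not supported; provide "
            "natural-scale coefficients (the induced standardized vector is stored)"
        )
    design = build_design(monthly.assign(soilT=0.0))
    std = design.standardization
    beta_std = natural_to_standardized(beta_nat, std)

    eta = _natural_predictor(monthly, beta_nat)
    b = monthly["glacier_id"].map(intercepts).to_numpy()
    res_rng = config.rng("residual")
    eps = config.residual_sd * res_rng.standard_normal(len(monthly))
    soil = np.where(
        monthly["sfd"].to_numpy() > 20.0,
        eta + b + eps,
        # snowpack decoupling: insulated soil hovers near 0 °C
        0.0 + 0.3 * np.sign(eps) * np.minimum(np.abs(eps), 1.0),
    )
    monthly["soilT"] = soil
    return WorldTruth(
        natural_coefficients=beta_nat,
        standardized_coefficients=beta_std,
        glacier_intercepts=intercepts,
        snow_calendar=calendars,
        monthly=monthly,
        standardization=std,
    )


def _natural_predictor(table: pd.DataFrame, beta_nat: pd.Series) -> np.ndarray:
    """Evaluate the soil model on the natural scale (dg via sqrt)."""
    cols = {
        "mT": table["mT"].to_numpy(float),
        "rad": table["rad"].to_numpy(float),
        "sfd": table["sfd"].to_numpy(float),
        "dg": np.sqrt(table["dg"].to_numpy(float)),
        "tc": table["tc"].to_numpy(float),
        "pf": table["pf"].to_numpy(float),
        "d": table["d"].to_numpy(float),
    }
    eta = np.full(len(table), beta_nat["intercept"], dtype=float)
    for name, x in cols.items():
        eta += beta_nat[name] * x
    for a, bb in INTERACTIONS:
        eta += beta_nat[f"{a}:{bb}"] * cols[a] * cols[bb]
    return eta


def natural_to_standardized(beta_nat: pd.Series, std: Standardization) -> pd.Series:
    """Exact conversion of natural-scale coefficients (with interactions) to the
    coefficients of the standardized design fitted by the soil model."""

    def mean(c):
        return std.means.get(c, 0.0)

    def sd(c):
        return std.sds.get(c, 1.0)

    out = {}
    for a, b in INTERACTIONS:
        out[f"{a}:{b}"] = beta_nat[f"{a}:{b}"] * sd(a) * sd(b)
    mains = ["mT", "rad", "sfd", "dg", "tc", "pf", "d"]
    for j in mains:
        val = beta_nat[j] * sd(j)
        for a, b in INTERACTIONS:
            if a == j:
                val += beta_nat[f"{a}:{b}"] * mean(b) * sd(j)
            elif b == j:
                val += beta_nat[f"{a}:{b}"] * mean(a) * sd(j)
        out[j] = val
    inter = beta_nat["intercept"] + sum(beta_nat[j] * mean(j) for j in mains)
    for a, b in INTERACTIONS:
        inter += beta_nat[f"{a}:{b}"] * mean(a) * mean(b)
    out["intercept"] = inter
    return pd.Series(out, index=list(FIXED_TERMS))


# ---------------------------------------------------------------------------
# observables: logger traces and satellite snow cover
# ---------------------------------------------------------------------------

def generate_logger_traces(world: World) -> list[LoggerSeries]:
    """Hourly logger traces: monthly truth + snow-damped diurnal cycle + AR(1).

    The diurnal term is A sin(2 pi (h - 8) / 24) (peak at 14:00 local), with A
    the snow or snow-free amplitude by day.  The hourly AR(1) texture noise is
    snow-damped like the diurnal cycle (marginal sd = 5% of the day's
    amplitude): an insulated sensor is quiet at every time scale, which keeps
    the diurnal-range snow signal intact.  The monthly-level model residual
    (sd = ``residual_sd``) is already part of the stored monthly truth.
    """
    config = world.config
    rng = config.rng("trace")
    truth = world.truth.monthly.set_index(["station_id", "year", "month"])
    out = []
    hours_of_day = np.arange(24)
    diurnal_shape = np.sin(2.0 * np.pi * (hours_of_day - 8.0) / 24.0)
    rho, noise_frac = config.ar1_rho, 0.05
    for _, st in world.stations.iterrows():
        sid = st["station_id"]
        snow_set = set(world.truth.snow_calendar[sid].normalize())
        idx_parts, val_parts, amp_parts = [], [], []
        for period in config.months:
            mean_t = truth.loc[(sid, period.year, period.month), "soilT"]
            days = pd.date_range(period.start_time, period.end_time, freq="D", tz="UTC")
            amp = np.where(
                [d in snow_set for d in days],
                config.diurnal_amplitude_snow,
                config.diurnal_amplitude_snowfree,
            )
            vals = (mean_t + amp[:, None] * diurnal_shape[None, :]).ravel()
            idx = pd.date_range(
                period.start_time.tz_localize("UTC"), periods=len(days) * 24, freq="h"
            )
            idx_parts.append(idx)
            val_parts.append(vals)
            amp_parts.append(np.repeat(amp, 24))
        idx = idx_parts[0].append(idx_parts[1:])
        vals = np.concatenate(val_parts)
        amp_hourly = np.concatenate(amp_parts)
        if np.any(amp_hourly > 0):
            innov = math.sqrt(1.0 - rho**2) * rng.standard_normal(len(vals))
            innov[0] = rng.standard_normal()
            unit_ar1 = lfilter([1.0], [1.0, -rho], innov)
            vals = vals + noise_frac * amp_hourly * unit_ar1
        out.append(
            LoggerSeries(
                station_id=sid,
                glacier_id=st["glacier_id"],
                region=st["region"],
                latitude=float(st["latitude"]),
                longitude=float(st["longitude"]),
                elevation=float(st["elevation"]),
                depth_cm=int(st["d"]),
                nominal_frequency=24,
                records=pd.Series(vals, index=idx),
            )
        )
    return out


def generate_satellite_snow(world: World) -> dict[str, pd.Series]:
    """Daily fractional snow cover (%) per station, with cloud gaps.

    Snow-covered days draw cover in [40, 100); snow-free days in [0, 40); each
    day is independently missing (NaN) with the configured cloud probability.
    """
    config = world.config
    rng = config.rng("satellite")
    start = config.months[0].start_time.tz_localize("UTC")
    end = config.months[-1].end_time.tz_localize("UTC")
    days = pd.date_range(start.normalize(), end.normalize(), freq="D")
    out = {}
    for sid in world.stations["station_id"]:
        snow_set = set(world.truth.snow_calendar[sid].normalize())
        is_snow = np.array([d in snow_set for d in days])
        u = rng.random(len(days))
        cover = np.where(is_snow, 40.0 + 60.0 * u, 40.0 * u)
        missing = rng.random(len(days)) < config.cloud_missing_prob
        cover = np.where(missing, np.nan, cover)
        out[sid] = pd.Series(cover, index=days)
    return out


# ---------------------------------------------------------------------------
# projection-period covariate rasters
# ---------------------------------------------------------------------------

def _band_index_raster(config: WorldConfig, template: Raster) -> np.ndarray:
    prow, pcol = _patch_layout(config.n_glaciers)
    ps = config.dem_size
    nrow, ncol = template.shape
    out = np.zeros((nrow, ncol), dtype=int)
    for g in range(config.n_glaciers):
        pr, pc = divmod(g, pcol)
        out[pr * ps : (pr + 1) * ps, pc * ps : (pc + 1) * ps] = g % len(BAND_CLIMATES)
    return out


def period_covariate_rasters(world: World, period: str) -> dict:
    """Monthly covariate rasters for one projection period ('early' or 'late').

    Macroclimate is the band seasonal cycle plus the linear trend evaluated at
    the period midpoint (the two midpoints are ``period_gap_years`` apart);
    radiation is the monthly climatology; sfd follows the snow rule (expected
    10% under the 0 °C threshold, 90% above, matching the per-day jitter);
    distance to glacier uses the epoch outline of the period.
    """
    config = world.config
    if period not in ("early", "late"):
        raise ValueError("period must be 'early' or 'late'")
    offset_years = 0.0 if period == "early" else config.period_gap_years
    dem = world.terrain.elevation
    band_idx = _band_index_raster(config, dem)
    months = pd.period_range(config.start, periods=12, freq="M")
    mT_list, sfd_list, rad_list = [], [], []
    for period_m in months:
        t_sl = np.zeros(dem.shape)
        for bi in range(len(BAND_CLIMATES)):
            val = _sea_level_temperature(config, bi, period_m) + config.trend * offset_years / 10.0
            t_sl[band_idx == bi] = val
        mT = t_sl - 0.0065 * dem.data
        mT_list.append(dem.like(mT))
        sfd_list.append(dem.like(np.where(mT < 0.0, 10.0, 90.0)))
        hourly = np.zeros((24,) + dem.shape)
        for bi, (_, lat, *_rest) in enumerate(BAND_CLIMATES):
            sel = band_idx == bi
            if not sel.any():
                continue
            sub = rad.TerrainRadiationFactors(
                svf=world.factors.svf[sel],
                horizon=world.factors.horizon[:, sel],
                n_sectors=world.factors.n_sectors,
            )
            for h, (sample, pos) in enumerate(
                _hourly_samples(config, bi, lat, 10.0, period_m)
            ):
                hourly[h][sel] = rad.absorbed_hourly(
                    sample, pos, sub, world.terrain.slope.data[sel], world.terrain.aspect.data[sel]
                )
        rad_list.append(dem.like(rad.daily_cumulative(hourly)))
    # both projection periods use the most recent outline: glacier retreat
    # within the projection window is not part of the generated world
    outlines = world.outlines_epoch2
    dist = world.distance_epoch2
    days_in_month = np.array([m.days_in_month for m in months], dtype=float)
    season = np.zeros(dem.shape)
    for dim, sfd_r in zip(days_in_month, sfd_list):
        season += dim * sfd_r.data / 100.0
    return {
        "months": months,
        "mT": mT_list,
        "rad": rad_list,
        "sfd": sfd_list,
        "dg": dist,
        "tc": world.tc_raster,
        "pf": world.pf_raster,
        "outlines": outlines,
        "season_duration": dem.like(season),
    }
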