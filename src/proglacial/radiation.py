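"""Topographic absorbed shortwave radiation with direct/diffuse separation.

For each raster cell the hourly absorbed shortwave radiation of the 15th day of
a month is built from (i) the solar position, (ii) a clearness-index based
diffuse-fraction correlation splitting albedo-free ("net") radiation into its
direct-beam and diffuse parts, and (iii) terrain factors: self-slope and horizon
sky-view reduction, cast shading, a Hay-type circumsolar anisotropy for the
diffuse component and a terrain-reflected component driven by the albedo of
adjacent surfaces.  The 24 hourly values sum to the monthly-averaged daily
cumulative radiation in MJ m-2 d-1, the radiation covariate of the soil model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from .terrain import TerrainGrid

#: Solar constant, MJ m-2 h-1 (1367 W m-2 x 3600 s / 1e6).
SOLAR_CONSTANT_MJ_H = 1367.0 * 3600.0 / 1e6

#: Guard for the 1/sin(altitude) beam amplification at low sun.
SIN_ALT_EPS = 1e-3

# Piecewise clearness-index -> diffuse-fraction correlation (Erbs et al. 1982).
# kd = 1 - 0.09 kt                              for kt <= 0.22
# kd = 0.9511 - 0.1604 kt + 4.388 kt^2
#      - 16.638 kt^3 + 12.336 kt^4              for 0.22 < kt <= 0.80
# kd = 0.165                                    for kt > 0.80
_ERBS_MID = (0.9511, -0.1604, 4.388, -16.638, 12.336)


@dataclass
class SolarPosition:
    altitude: float  # degrees above horizon
    azimuth: float  # degrees clockwise from north
    declination: float  # degrees
    latitude: float
    longitude: float
    when: datetime


@dataclass
class RadiationSample:
    """One hour of coarse radiation forcing for a location."""

    hour: int
    downward_total: float  # MJ m-2 h-1, global downward shortwave
    net_total: float  # MJ m-2 h-1, albedo-free (net) shortwave
    extraterrestrial_horizontal: float  # MJ m-2 h-1
    kt: float
    kd: float
    direct: float
    diffuse: float
    albedo_adjacent: float


@dataclass
class TerrainRadiationFactors:
    """Sky view factor and sector horizon angles for every cell of a grid."""

    svf: np.ndarray  # [nrow, ncol] in [0, 1]
    horizon: np.ndarray  # [n_sectors, nrow, ncol], degrees >= 0
    n_sectors: int

    def horizon_at(self, azimuth: float) -> np.ndarray:
        sector = int(azimuth % 360.0 // (360.0 / self.n_sectors))
        return self.horizon[sector]


def _day_of_year(when: datetime) -> float:
    start = datetime(when.year, 1, 1, tzinfo=timezone.utc)
    return (when - start).total_seconds() / 86400.0 + 1.0


def solar_declination(when: datetime) -> float:
    """Solar declination (degrees), Spencer (1971) Fourier series."""
    g = 2.0 * math.pi * (_day_of_year(when) - 1.0) / 365.0
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return math.degrees(decl)


def equation_of_time(when: datetime) -> float:
    """Equation of time in minutes (Spencer series)."""
    g = 2.0 * math.pi * (_day_of_year(when) - 1.0) / 365.0
    eot = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    return eot


def solar_position(latitude: float, longitude: float, when: datetime) -> SolarPosition:
    """Solar altitude/azimuth from a standard low-precision ephemeris.

    ``when`` must be timezone-aware UTC.  Accuracy is a few hundredths of a
    degree in declination and well under half a degree in altitude/azimuth,
    sufficient for hourly terrain radiation.
    """
    if when.tzinfo is None:
        raise ValueError("datetime must be timezone-aware (UTC)")
    when = when.astimezone(timezone.utc)
    decl = math.radians(solar_declination(when))
    eot = equation_of_time(when)
    hours_utc = when.hour + when.minute / 60.0 + when.second / 3600.0
    true_solar_minutes = hours_utc * 60.0 + 4.0 * longitude + eot
    hour_angle = math.radians(true_solar_minutes / 4.0 - 180.0)
    hour_angle = (hour_angle + math.pi) % (2.0 * math.pi) - math.pi
    lat = math.radians(latitude)
    sin_alt = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(hour_angle)
    sin_alt = min(1.0, max(-1.0, sin_alt))
    alt = math.asin(sin_alt)
    cos_az = (math.sin(decl) - math.sin(lat) * sin_alt) / max(1e-12, math.cos(lat) * math.cos(alt))
    cos_az = min(1.0, max(-1.0, cos_az))
    az = math.degrees(math.acos(cos_az))
    if hour_angle > 0:  # afternoon: sun west of the meridian
        az = 360.0 - az
    return SolarPosition(
        altitude=math.degrees(alt),
        azimuth=az % 360.0,
        declination=math.degrees(decl),
        latitude=latitude,
        longitude=longitude,
        when=when,
    )


def extraterrestrial_horizontal(pos: SolarPosition) -> float:
    """Hourly extraterrestrial radiation on a horizontal plane, MJ m-2 h-1."""
    if pos.altitude <= 0:
        return 0.0
    doy = _day_of_year(pos.when)
    e0 = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)  # eccentricity factor
    return SOLAR_CONSTANT_MJ_H * e0 * math.sin(math.radians(pos.altitude))


def clearness_index(downward_total: float, extraterrestrial: float) -> float:
    """Kt = downward / extraterrestrial, clipped to [0, 1]; 0 at night."""
    if downward_total < 0 or extraterrestrial < 0:
        raise ValueError("radiation inputs must be non-negative")
    if extraterrestrial == 0:
        return 0.0
    return float(np.clip(downward_total / extraterrestrial, 0.0, 1.0))


def diffuse_fraction(kt: float | np.ndarray) -> float | np.ndarray:
    """Diffuse fraction Kd from the hourly clearness index Kt.

    Piecewise polynomial correlation (Erbs et al. 1982), clipped to [0, 1]:
    overcast skies (Kt -> 0) are fully diffuse, clear skies retain a diffuse
    floor of 0.165.
    """
    kt_arr = np.asarray(kt, dtype=float)
    if np.any((kt_arr < 0) | (kt_arr > 1)):
        raise ValueError("Kt must lie in [0, 1]")
    c0, c1, c2, c3, c4 = _ERBS_MID
    mid = c0 + c1 * kt_arr + c2 * kt_arr**2 + c3 * kt_arr**3 + c4 * kt_arr**4
    kd = np.where(kt_arr <= 0.22, 1.0 - 0.09 * kt_arr, np.where(kt_arr <= 0.80, mid, 0.165))
    kd = np.clip(kd, 0.0, 1.0)
    return float(kd) if np.isscalar(kt) or np.ndim(kt) == 0 else kd


def partition_net(net_total: float, kd: float) -> tuple[float, float]:
    """Split albedo-free radiation into (direct, diffuse) = net x (1-Kd, Kd)."""
    if net_total < 0:
        raise ValueError("net radiation must be non-negative")
    if not 0.0 <= kd <= 1.0:
        raise ValueError("Kd must lie in [0, 1]")
    diffuse = net_total * kd
    direct = net_total - diffuse  # exact conservation
    return direct, diffuse


def make_sample(
    hour: int,
    downward_total: float,
    net_total: float,
    pos: SolarPosition,
    albedo_adjacent: float,
) -> RadiationSample:
    """Assemble the per-hour radiation partition from coarse forcing."""
    etr = extraterrestrial_horizontal(pos)
    if pos.altitude <= 0:
        kt, kd = 0.0, 1.0  # night convention
        direct, diffuse = 0.0, net_total * 0.0
    else:
        kt = clearness_index(downward_total, etr)
        kd = float(diffuse_fraction(kt))
        direct, diffuse = partition_net(net_total, kd)
    return RadiationSample(
        hour=hour,
        downward_total=downward_total,
        net_total=net_total,
        extraterrestrial_horizontal=etr,
        kt=kt,
        kd=kd,
        direct=direct,
        diffuse=diffuse,
        albedo_adjacent=albedo_adjacent,
    )


def horizon_and_svf(
    terrain: TerrainGrid,
    n_sectors: int = 24,
    max_search: float = 5000.0,
) -> TerrainRadiationFactors:
    """Sector horizon angles by ray marching and the resulting sky view factor.

    svf = cos^2(slope/2) x mean over sectors of cos^2(horizon angle): the first
    factor is the self-obstruction of the tilted surface, the second the share
    of the sky dome cut away by surrounding terrain.
    """
    if n_sectors < 4:
        raise ValueError("need at least 4 azimuth sectors")
    z = terrain.elevation.data
    cell = terrain.cell_size
    nrow, ncol = z.shape
    n_steps = max(1, int(max_search / cell))
    horizon = np.zeros((n_sectors, nrow, ncol))
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    for s in range(n_sectors):
        az = math.radians(s * 360.0 / n_sectors)
        de, dn = math.sin(az), math.cos(az)  # east, north unit components
        best = np.full(z.shape, -np.inf)
        for k in range(1, n_steps + 1):
            # offsets are uniform across cells; use the true horizontal
            # distance to the rounded sample cell
            dr = int(np.rint(-dn * k))  # north decreases row index
            dc = int(np.rint(de * k))
            if dr == 0 and dc == 0:
                continue
            dist = math.hypot(dr, dc) * cell
            ri = rows + dr
            ci = cols + dc
            ok = (ri >= 0) & (ri < nrow) & (ci >= 0) & (ci < ncol)
            if not ok.any():
                break
            dz = np.where(ok, z[np.clip(ri, 0, nrow - 1), np.clip(ci, 0, ncol - 1)] - z, -np.inf)
            ang = np.arctan(dz / dist)
            best = np.maximum(best, ang)
        horizon[s] = np.degrees(np.maximum(best, 0.0))
    slope = np.radians(terrain.slope.data)
    svf = np.cos(slope / 2.0) ** 2 * np.mean(np.cos(np.radians(horizon)) ** 2, axis=0)
    return TerrainRadiationFactors(svf=np.clip(svf, 0.0, 1.0), horizon=horizon, n_sectors=n_sectors)


def incidence_cosine(
    altitude: float, azimuth: float, slope: np.ndarray, aspect: np.ndarray
) -> np.ndarray:
    """cos of the beam incidence angle on a tilted surface (can be negative)."""
    alt = math.radians(altitude)
    sl = np.radians(slope)
    return np.sin(alt) * np.cos(sl) + np.cos(alt) * np.sin(sl) * np.cos(
        math.radians(azimuth) - np.radians(aspect)
    )


def absorbed_hourly(
    sample: RadiationSample,
    pos: SolarPosition,
    factors: TerrainRadiationFactors,
    slope: np.ndarray,
    aspect: np.ndarray,
) -> np.ndarray:
    """Absorbed shortwave radiation on the tilted, possibly shaded surface.

    direct term:   beam irradiance routed through cos(incidence)/sin(altitude),
                   zeroed when the sun is below the horizon or the cell shaded;
    diffuse term:  circumsolar share (Hay anisotropy index = direct beam /
                   extraterrestrial) routed like the beam + isotropic share
                   weighted by the sky view factor;
    reflected:     albedo of adjacent terrain x (1 - svf) x global radiation.
    """
    slope = np.asarray(slope, dtype=float)
    aspect = np.asarray(aspect, dtype=float)
    sun_up = pos.altitude > 0.0
    shaded = factors.horizon_at(pos.azimuth) > pos.altitude if sun_up else np.ones_like(slope, bool)
    if sun_up:
        cos_i = np.maximum(0.0, incidence_cosine(pos.altitude, pos.azimuth, slope, aspect))
        beam_factor = cos_i / max(SIN_ALT_EPS, math.sin(math.radians(pos.altitude)))
        beam_factor = np.where(shaded, 0.0, beam_factor)
    else:
        beam_factor = np.zeros_like(slope)
    direct_term = sample.direct * beam_factor
    if sun_up and sample.extraterrestrial_horizontal > 0:
        anis = min(1.0, sample.direct / sample.extraterrestrial_horizontal)
    else:
        anis = 0.0  # no circumsolar component without a sun
    diffuse_term = sample.diffuse * (anis * beam_factor + (1.0 - anis) * factors.svf)
    reflected = sample.albedo_adjacent * (1.0 - factors.svf) * sample.net_total
    out = direct_term + diffuse_term + reflected
    if np.any(out < 0):  # numerically impossible with the guards above; clamp anyway
        out = np.maximum(out, 0.0)
    return out


def daily_cumulative(hourly: np.ndarray) -> np.ndarray:
    """Sum 24 hourly absorbed values to MJ m-2 d-1 (axis 0 = hour)."""
    hourly = np.asarray(hourly, dtype=float)
    if hourly.shape[0] != 24:
        raise ValueError("expected exactly 24 hourly values")
    return hourly.sum(axis=0)
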