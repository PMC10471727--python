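"""Soil-temperature logger series: container and CSV round-trip.

One `LoggerSeries` is a single buried device: hourly (or coarser) timestamped
soil temperatures plus geography, burying depth, glacier and region labels.
The on-disk format is a long CSV, one row per record, with station metadata
repeated on every row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Physically plausible soil temperature window (°C); rows outside are rejected.
TEMP_SANITY = (-60.0, 60.0)

REQUIRED_COLUMNS = [
    "station_id",
    "glacier_id",
    "region",
    "latitude",
    "longitude",
    "elevation",
    "depth_cm",
    "nominal_frequency",
    "timestamp",
    "temperature",
]


@dataclass
class LoggerSeries:
    station_id: str
    glacier_id: str
    region: str
    latitude: float
    longitude: float
    elevation: float
    depth_cm: int  # burying depth, one of {5, 10, 15}
    nominal_frequency: int  # expected records per day
    records: pd.Series = field(repr=False)  # DatetimeIndex (UTC) -> °C

    def __post_init__(self) -> None:
        if self.depth_cm not in (5, 10, 15):
            raise ValueError(f"depth_cm must be 5, 10 or 15 cm, got {self.depth_cm}")
        if self.nominal_frequency < 1:
            raise ValueError("nominal_frequency must be >= 1 record/day")
        if not self.records.index.is_monotonic_increasing:
            self.records = self.records.sort_index()


def write_loggers(series: list[LoggerSeries], path) -> None:
    frames = []
    for s in series:
        df = pd.DataFrame(
            {
                "station_id": s.station_id,
                "glacier_id": s.glacier_id,
                "region": s.region,
                "latitude": s.latitude,
                "longitude": s.longitude,
                "elevation": s.elevation,
                "depth_cm": s.depth_cm,
                "nominal_frequency": s.nominal_frequency,
                "timestamp": s.records.index.strftime("%Y-%m-%dT%H:%M:%SZ"),
                "temperature": s.records.values,
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_loggers(path) -> list[LoggerSeries]:
    """Parse a logger CSV into one LoggerSeries per station.

    Duplicate timestamps within a station are collapsed by mean (with a
    warning); records outside the temperature sanity window are rejected and
    counted in the log.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty logger file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = ~df["temperature"].between(*TEMP_SANITY)
    if bad.any():
        log.warning("%s: rejected %d record(s) outside %s °C", path, int(bad.sum()), TEMP_SANITY)
        df = df[~bad]
    out: list[LoggerSeries] = []
    for sid, grp in df.groupby("station_id", sort=True):
        ts = pd.to_datetime(grp["timestamp"], utc=True)
        rec = pd.Series(grp["temperature"].to_numpy(), index=pd.DatetimeIndex(ts))
        if rec.index.has_duplicates:
            ndup = int(rec.index.duplicated().sum())
            warnings.warn(f"station {sid}: {ndup} duplicate timestamp(s) collapsed by mean")
            rec = rec.groupby(level=0).mean()
        meta = grp.iloc[0]
        out.append(
            LoggerSeries(
                station_id=str(sid),
                glacier_id=str(meta["glacier_id"]),
                region=str(meta["region"]),
                latitude=float(meta["latitude"]),
                longitude=float(meta["longitude"]),
                elevation=float(meta["elevation"]),
                depth_cm=int(meta["depth_cm"]),
                nominal_frequency=int(meta["nominal_frequency"]),
                records=rec.sort_index(),
            )
        )
    return out
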