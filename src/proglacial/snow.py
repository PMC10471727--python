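"""Snow-free-day frequency (sfd) from loggers and satellite fractional cover.

A buried sensor under snow shows almost no diurnal temperature range, so days
with a range below a threshold are classed as snow-covered.  Satellite
fractional snow cover is converted to occurrence with a conservative 40%
threshold.  The two monthly sfd series are reconciled on a calibration grid of
(range threshold x minimum image count) combinations scored with the weighted
agreement statistics, and the snow-free season duration is the yearly count of
snow-free days averaged over a period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loggers import LoggerSeries
from .weights import build_weights, weighted_stats

#: Fractional snow-cover (%) at or above which a day counts as snow-covered.
SNOW_COVER_THRESHOLD = 40.0

#: Diurnal-range thresholds (°C) scanned during calibration.
RANGE_THRESHOLDS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Minimum-image filters scanned during calibration.
MIN_IMAGE_LEVELS = (1, 5, 10, 15, 20)

#: Minimum records per local calendar day for a valid daily range.
MIN_RECORDS_PER_DAY = 4


def daily_range(trace: LoggerSeries, min_records: int = MIN_RECORDS_PER_DAY) -> pd.Series:
    """Per-day max - min temperature; days with too few records are NaN."""
    by_day = trace.records.groupby(trace.records.index.floor("D"))
    rng = by_day.max() - by_day.min()
    counts = by_day.count()
    rng[counts < min_records] = np.nan
    return rng


def sensor_sfd(trace: LoggerSeries, threshold: float = 1.5) -> pd.DataFrame:
    """Monthly % of snow-free days from the diurnal range of a logger.

    A day is snow-covered when its range is strictly below ``threshold``;
    the denominator is the number of days with a valid range in the month.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rng = daily_range(trace)
    valid = rng.dropna()
    if valid.empty:
        return pd.DataFrame(columns=["station_id", "year", "month", "sfd_sensor", "n_days"])
    snow_free = valid >= threshold
    grouper = [valid.index.year, valid.index.month]
    n_days = valid.groupby(grouper).count()
    out = pd.DataFrame(
        {
            # 100*k/n, in this evaluation order, so truth recounts match bitwise
            "sfd_sensor": 100.0 * snow_free.groupby(grouper).sum() / n_days,
            "n_days": n_days,
        }
    )
    out.index.names = ["year", "month"]
    out = out.reset_index()
    out.insert(0, "station_id", trace.station_id)
    return out


def satellite_sfd(
    cover: pd.Series,
    min_images: int = 15,
    snow_threshold: float = SNOW_COVER_THRESHOLD,
    calendar_denominator: bool = False,
) -> pd.DataFrame:
    """Monthly % of snow-free days from daily fractional snow cover (0-100, NaN = cloud).

    Snow is present when cover >= ``snow_threshold`` (snow-free strictly below);
    months with fewer than ``min_images`` valid days are dropped.  By default
    the denominator counts observed days; ``calendar_denominator=True`` divides
    by calendar days instead.
    """
    cover = cover.dropna()
    if cover.empty:
        return pd.DataFrame(columns=["year", "month", "sfd_satellite", "n_images"])
    snow_free = cover < snow_threshold
    grouper = [cover.index.year, cover.index.month]
    n_images = cover.groupby(grouper).count()
    free_days = snow_free.groupby(grouper).sum()
    if calendar_denominator:
        month_starts = pd.PeriodIndex(
            [pd.Period(f"{y}-{m:02d}") for y, m in n_images.index], freq="M"
        )
        denom = pd.Series(month_starts.days_in_month.to_numpy(), index=n_images.index)
    else:
        denom = n_images
    out = pd.DataFrame({"sfd_satellite": 100.0 * free_days / denom, "n_images": n_images})
    out.index.names = ["year", "month"]
    out = out.reset_index()
    return out[out["n_images"] >= min_images].reset_index(drop=True)


@dataclass
class CalibrationGrid:
    """Weighted agreement per (range threshold, min-image) combination."""

    table: pd.DataFrame  # columns: threshold, min_images, wR2, wMAE, wRMSE, n
    selected_threshold: float
    selected_min_images: int

    def selected_row(self) -> pd.Series:
        t = self.table
        return t[
            (t["threshold"] == self.selected_threshold)
            & (t["min_images"] == self.selected_min_images)
        ].iloc[0]


def calibrate(
    traces: list[LoggerSeries],
    covers: dict[str, pd.Series],
    station_meta: pd.DataFrame,
    thresholds=RANGE_THRESHOLDS,
    min_image_levels=MIN_IMAGE_LEVELS,
) -> CalibrationGrid:
    """Score sensor vs satellite monthly sfd over the calibration grid.

    ``station_meta`` maps station_id -> (region, glacier_id) for the
    hierarchical downweighting.  Selection maximizes wR2, breaking ties by the
    smaller wRMSE.
    """
    meta = station_meta.set_index("station_id") if "station_id" in station_meta else station_meta
    rows = []
    for thr in thresholds:
        sensor = pd.concat([sensor_sfd(t, thr) for t in traces], ignore_index=True)
        for mi in min_image_levels:
            sat_frames = []
            for sid, cov in covers.items():
                s = satellite_sfd(cov, min_images=mi)
                s.insert(0, "station_id", sid)
                sat_frames.append(s)
            sat = pd.concat(sat_frames, ignore_index=True)
            merged = sensor.merge(sat, on=["station_id", "year", "month"], how="inner")
            if len(merged) < 2:
                continue
            labels = merged.join(meta, on="station_id")
            scheme = build_weights(
                region=labels["region"],
                group=labels["glacier_id"],
                sfd=labels["sfd_satellite"],
            )
            stats = weighted_stats(
                observed=merged["sfd_sensor"].to_numpy(),
                predicted=merged["sfd_satellite"].to_numpy(),
                weights=scheme.weights,
            )
            rows.append(
                {
                    "threshold": thr,
                    "min_images": mi,
                    "wR2": stats.wr2,
                    "wMAE": stats.wmae,
                    "wRMSE": stats.wrmse,
                    "n": len(merged),
                }
            )
    if not rows:
        raise ValueError("no overlapping sensor/satellite months to calibrate on")
    table = pd.DataFrame(rows)
    best = table.sort_values(["wR2", "wRMSE"], ascending=[False, True]).iloc[0]
    return CalibrationGrid(
        table=table,
        selected_threshold=float(best["threshold"]),
        selected_min_images=int(best["min_images"]),
    )


def season_duration(cover: pd.Series, years: list[int] | None = None) -> float:
    """Snow-free season length: snow-free days per year, averaged over a period.

    ``cover`` is a daily fractional snow-cover series; a day is snow-free when
    cover < 40%.  Missing days are assumed to carry the state of the nearest
    observation within the year (forward/backward fill) so that a sparse but
    unbiased satellite record still yields a full-year count.
    """
    cover = cover.sort_index()
    if years is None:
        years = sorted(set(cover.index.year))
    per_year = []
    for y in years:
        yr = cover[cover.index.year == y]
        if yr.dropna().empty:
            continue
        idx = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D", tz=yr.index.tz)
        filled = yr.reindex(idx).ffill().bfill()
        per_year.append(float((filled < SNOW_COVER_THRESHOLD).sum()))
    return float(np.mean(per_year)) if per_year else float("nan")
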