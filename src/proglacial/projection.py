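"""Population-level projection over rasters, stratified sampling and buffering.

The transferable (LOO-mean) coefficients are applied to covariate rasters of
two multi-year periods; points sampled on an equal-area grid, stratified by
distance from the most recent glacier outline, yield the temperature change
ΔT (annual and seasonal), the change in snow-free season duration, the local
spatial variability T_var (80% inter-percentile range within a 250 m buffer)
and the buffering potential T_bp = T_var / ΔT, whose absolute value exceeds 1
when nearby spatial variability is larger than the temporal change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster
from .soil_model import Standardization, build_design, predict_fixed

#: Meteorological seasons by month number.
SEASONS = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}

#: T_bp class edges and labels (signed ratio).
TBP_CLASS_LABELS = ("<=-10", "(-10,-1]", "(-1,1]", "(1,10]", ">10")

#: |ΔT| below this is treated as "no temporal change" (T_bp sentinel +inf).
DELTA_T_EPS = 1e-6

#: Tropic latitude separating the three latitudinal bands.
TROPIC_LAT = 23.44


@dataclass
class SamplingDesign:
    """Stratified equal-area sampling design (defaults: 50 km grid, five
    distance-from-glacier bands, two points per band, whole cells only)."""

    cell_size: float = 50_000.0
    distance_classes: tuple[tuple[float, float], ...] = (
        (0.0, 100.0),
        (400.0, 600.0),
        (900.0, 1100.0),
        (1900.0, 2100.0),
        (2900.0, 3100.0),
    )
    points_per_class: int = 2

    def __post_init__(self) -> None:
        spans = sorted(self.distance_classes)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("distance classes must be disjoint")

    @property
    def min_points(self) -> int:
        return self.points_per_class * len(self.distance_classes)


def latitude_band(lat: float) -> str:
    if lat > TROPIC_LAT:
        return "Northern"
    if lat < -TROPIC_LAT:
        return "Southern"
    return "Inter-tropical"


def project_soilT(
    coefficients: pd.Series,
    standardization: Standardization,
    covariates: dict,
    depth_cm: float = 5.0,
    sfd_cutoff: float = 20.0,
) -> list[Raster]:
    """Monthly soil-temperature rasters from transferable coefficients.

    ``covariates`` holds 12 monthly ``mT``/``rad``/``sfd`` rasters plus static
    ``dg``/``tc``/``pf`` rasters.  Cells with sfd <= ``sfd_cutoff`` (or missing
    covariates) are masked; no random effect is added.
    """
    mT_list, rad_list, sfd_list = covariates["mT"], covariates["rad"], covariates["sfd"]
    dg, tc, pf = covariates["dg"], covariates["tc"], covariates["pf"]
    template = dg
    for r in (*mT_list, *rad_list, *sfd_list, tc, pf):
        if r.shape != template.shape or r.origin != template.origin or r.cell_size != template.cell_size:
            raise ValueError(
                f"misaligned covariate raster: shape {r.shape} origin {r.origin} "
                f"vs template {template.shape} {template.origin}"
            )
    out = []
    for mT_r, rad_r, sfd_r in zip(mT_list, rad_list, sfd_list):
        table = pd.DataFrame(
            {
                "mT": mT_r.data.ravel(),
                "rad": rad_r.data.ravel(),
                "sfd": sfd_r.data.ravel(),
                "dg": dg.data.ravel(),
                "tc": tc.data.ravel(),
                "pf": pf.data.ravel(),
                "d": depth_cm,
                "glacier_id": "projection",
            }
        )
        valid = (
            table[["mT", "rad", "sfd", "dg"]].notna().all(axis=1)
            & (table["sfd"] > sfd_cutoff)
        )
        pred = np.full(len(table), np.nan)
        if valid.any():
            design = build_design(
                table[valid].reset_index(drop=True),
                standardization=standardization,
                sfd_cutoff=sfd_cutoff,
            )
            pred[np.flatnonzero(valid)] = predict_fixed(design.X, coefficients)
        out.append(template.like(pred.reshape(template.shape)))
    return out


def stratified_sample(
    design: SamplingDesign, distance: Raster, seed: int
) -> pd.DataFrame:
    """Random stratified points: per grid cell, ``points_per_class`` raster
    cells in each distance band, sampled without replacement; grid cells that
    cannot supply every band are dropped entirely."""
    rng = np.random.default_rng(seed)
    nrow, ncol = distance.shape
    xs, ys = distance.cell_centers()
    x0, y0 = distance.origin
    gcol = np.floor((xs - x0) / design.cell_size).astype(int)
    grow = np.floor((y0 - ys) / design.cell_size).astype(int)
    cell_ids = grow * (gcol.max() + 1) + gcol
    rows = []
    dist = distance.data
    for cid in np.unique(cell_ids):
        in_cell = cell_ids == cid
        picks = []
        ok = True
        for ci, (lo, hi) in enumerate(design.distance_classes):
            cand = np.argwhere(in_cell & (dist >= lo) & (dist <= hi) & np.isfinite(dist))
            if len(cand) < design.points_per_class:
                ok = False
                break
            sel = rng.choice(len(cand), size=design.points_per_class, replace=False)
            for s in sel:
                r, c = cand[s]
                picks.append(
                    {
                        "cell_id": int(cid),
                        "dist_class": f"{int(lo)}-{int(hi)}m",
                        "class_index": ci,
                        "row": int(r),
                        "col": int(c),
                        "x": float(xs[r, c]),
                        "y": float(ys[r, c]),
                        "distance": float(dist[r, c]),
                    }
                )
        if ok:
            rows.extend(picks)
    if not rows:
        raise ValueError("no grid cell could supply the full stratified sample")
    out = pd.DataFrame(rows)
    out.insert(0, "point_id", np.arange(len(out)))
    return out


def _season_months(months: pd.PeriodIndex, season: str) -> np.ndarray:
    if season == "annual":
        return np.arange(len(months))
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    wanted = SEASONS[season]
    return np.flatnonzero([m.month in wanted for m in months])


def delta_T(
    points: pd.DataFrame,
    early: list[Raster],
    late: list[Raster],
    months: pd.PeriodIndex,
    season: str = "annual",
) -> pd.Series:
    """Per-point ΔT = late-period seasonal mean - early-period seasonal mean.

    Months masked in either period are excluded pairwise from both means.
    """
    sel = _season_months(months, season)
    r = points["row"].to_numpy()
    c = points["col"].to_numpy()
    e = np.stack([early[m].data[r, c] for m in sel])
    l = np.stack([late[m].data[r, c] for m in sel])
    both = np.isfinite(e) & np.isfinite(l)
    e = np.where(both, e, np.nan)
    l = np.where(both, l, np.nan)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        out = np.nanmean(l, axis=0) - np.nanmean(e, axis=0)
    return pd.Series(out, index=points.index, name=f"delta_T_{season}")


def t_var(
    points: pd.DataFrame, annual_mean: Raster, radius: float = 250.0, min_cells: int = 5
) -> pd.Series:
    """80% inter-percentile range (q90 - q10) within ``radius`` m of each point."""
    xs, ys = annual_mean.cell_centers()
    vals = annual_mean.data
    out = []
    for _, p in points.iterrows():
        within = (xs - p["x"]) ** 2 + (ys - p["y"]) ** 2 <= radius**2
        v = vals[within]
        v = v[np.isfinite(v)]
        if v.size == 1:
            out.append(0.0)  # degenerate buffer: a single value has no spread
        elif v.size < min_cells:
            out.append(np.nan)
        else:
            out.append(float(np.quantile(v, 0.9) - np.quantile(v, 0.1)))
    return pd.Series(out, index=points.index, name="t_var")


def t_bp(tvar: pd.Series | np.ndarray, delta: pd.Series | np.ndarray) -> pd.DataFrame:
    """Signed buffering potential T_bp = T_var / ΔT and its class.

    |ΔT| below ``DELTA_T_EPS`` yields a +inf sentinel (spatial variability
    trivially exceeds no change), classed '>10'.
    """
    tvar = np.asarray(tvar, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(tvar[np.isfinite(tvar)] < 0):
        raise ValueError("T_var must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(delta) < DELTA_T_EPS, np.inf, tvar / delta)
    cls = np.select(
        [ratio <= -10, ratio <= -1, ratio <= 1, ratio <= 10],
        TBP_CLASS_LABELS[:4],
        default=TBP_CLASS_LABELS[4],
    )
    cls = np.where(np.isfinite(ratio) | np.isinf(ratio), cls, None)
    return pd.DataFrame({"t_bp": ratio, "t_bp_class": cls})


def summarize(records: pd.DataFrame, by=("band", "dist_class")) -> pd.DataFrame:
    """Group means/sds/medians/quartiles of ΔT and season change, plus the
    percentage distribution of T_bp classes per group."""
    if records.empty:
        raise ValueError("no buffering records to summarize")
    rows = []
    for key, grp in records.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n"] = len(grp)
        for col in ("delta_T_annual", "season_change"):
            if col in grp:
                vals = grp[col].dropna()
                row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
                row[f"{col}_median"] = float(vals.median()) if len(vals) else np.nan
                row[f"{col}_q1"] = float(vals.quantile(0.25)) if len(vals) else np.nan
                row[f"{col}_q3"] = float(vals.quantile(0.75)) if len(vals) else np.nan
        if "t_bp_class" in grp:
            counts = grp["t_bp_class"].value_counts(normalize=True) * 100.0
            for label in TBP_CLASS_LABELS:
                row[f"pct_{label}"] = float(counts.get(label, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


def extrapolation_audit(
    projection_values: pd.DataFrame, training_ranges: pd.DataFrame
) -> pd.Series:
    """Percentage of projection values strictly outside the training range,
    per predictor (dg compared on the sqrt scale, like the training ranges)."""
    out = {}
    for pred in training_ranges.index:
        if pred not in projection_values:
            continue
        vals = projection_values[pred].dropna().to_numpy(dtype=float)
        if pred == "dg":
            vals = np.sqrt(vals)
        lo, hi = training_ranges.loc[pred, "min"], training_ranges.loc[pred, "max"]
        out[pred] = 100.0 * float(np.mean((vals < lo) | (vals > hi))) if vals.size else np.nan
    return pd.Series(out, name="pct_outside")


def buffering_records(
    points: pd.DataFrame,
    early: list[Raster],
    late: list[Raster],
    months: pd.PeriodIndex,
    season_early: Raster,
    season_late: Raster,
    band: pd.Series,
    radius: float = 250.0,
) -> pd.DataFrame:
    """Assemble per-point buffering records from the two projected periods."""
    records = points.copy()
    records["band"] = band.to_numpy()
    records["delta_T_annual"] = delta_T(points, early, late, months, "annual")
    for season in SEASONS:
        records[f"delta_T_{season}"] = delta_T(points, early, late, months, season)
    r = points["row"].to_numpy()
    c = points["col"].to_numpy()
    records["season_early"] = season_early.data[r, c]
    records["season_late"] = season_late.data[r, c]
    records["season_change"] = records["season_late"] - records["season_early"]
    with np.errstate(invalid="ignore"):
        annual_late = np.nanmean(np.stack([m.data for m in late]), axis=0)
    records["t_var"] = t_var(points, season_early.like(annual_late), radius=radius)
    bp = t_bp(records["t_var"], records["delta_T_annual"])
    records["t_bp"] = bp["t_bp"].to_numpy()
    records["t_bp_class"] = bp["t_bp_class"].to_numpy()
    return records
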