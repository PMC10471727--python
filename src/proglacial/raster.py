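"""Lightweight georeferenced raster container and text-based raster / outline I/O.

Rasters are north-up, cell-center registered, row 0 at the northern edge, with a
projected CRS (meters) required for any metric operation.  On disk they are ESRI
ASCII grids (plain text) with a small JSON sidecar carrying the CRS string.
Glacier outlines travel as GeoJSON polygons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass
class Raster:
    """A 2D grid with an affine north-up georeference.

    ``origin`` is the (x, y) of the *outer corner* of the top-left cell; the
    center of cell (row, col) is ``(x0 + (col + 0.5) dx, y0 - (row + 0.5) dx)``.
    """

    data: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 30.0
    crs: str = "LOCAL:meters"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of every cell center."""
        nrow, ncol = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrow) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing the point, or raise if outside."""
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cell_size))
        row = int(math.floor((y0 - y) / self.cell_size))
        nrow, ncol = self.data.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.index_of(x, y)
        return float(self.data[r, c])

    def like(self, data: np.ndarray) -> "Raster":
        """New raster sharing this georeference."""
        if np.shape(data) != self.data.shape:
            raise ValueError("shape mismatch with template raster")
        return replace(self, data=np.asarray(data, dtype=float))


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid plus a ``.json`` sidecar with the CRS."""
    path = Path(path)
    data = np.where(np.isfinite(raster.data), raster.data, nodata)
    nrow, ncol = raster.shape
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {raster.origin[0]}\n"
        f"yllcorner {raster.origin[1] - nrow * raster.cell_size}\n"
        f"cellsize {raster.cell_size}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump({"crs": raster.crs}, fh)


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = meta.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    sidecar = path.with_suffix(path.suffix + ".json")
    crs = "LOCAL:meters"
    if sidecar.exists():
        crs = json.loads(sidecar.read_text()).get("crs", crs)
    y0 = meta["yllcorner"] + meta["nrows"] * meta["cellsize"]
    return Raster(data, origin=(meta["xllcorner"], y0), cell_size=meta["cellsize"], crs=crs)


def write_outlines(geoms: list[BaseGeometry], path: str | Path, crs: str = "LOCAL:meters") -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": {"id": i}}
        for i, g in enumerate(geoms)
    ]
    payload = {"type": "FeatureCollection", "crs_note": crs, "features": features}
    Path(path).write_text(json.dumps(payload))


def read_outlines(path: str | Path) -> list[BaseGeometry]:
    payload = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in payload["features"]]


def mollweide_xy(lon: np.ndarray, lat: np.ndarray, radius: float = 6_371_007.181) -> tuple[np.ndarray, np.ndarray]:
    """Forward Mollweide (equal-area pseudocylindrical) projection.

    Standard closed form with Newton iteration for the auxiliary angle;
    ``radius`` defaults to the authalic sphere radius used by ESRI:54009.
    Returns (x, y) in meters.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon)
    theta = phi.copy()
    target = np.pi * np.sin(phi)
    for _ in range(50):
        f = 2 * theta + np.sin(2 * theta) - target
        fp = 2 + 2 * np.cos(2 * theta)
        step = np.where(np.abs(fp) > 1e-12, f / np.where(fp == 0, 1, fp), 0.0)
        theta = theta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    x = radius * (2 * math.sqrt(2) / math.pi) * lam * np.cos(theta)
    y = radius * math.sqrt(2) * np.sin(theta)
    return x, y
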