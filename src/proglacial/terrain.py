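"""DEM derivatives, lapse-rate macroclimate downscaling and distance to glacier.

Monthly mean macroclimate is the midpoint of gridded monthly minimum and maximum
temperature; high-resolution surfaces are obtained by shifting the coarse value
with a fixed environmental lapse rate applied to the elevation difference between
the fine DEM and the coarse cell's reference elevation.  Distance from the
glacier forefront (a proxy for katabatic-wind cooling) is an 8-connected
chamfer/geodesic path distance over the raster lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep
from shapely.geometry import Point
from skimage.graph import MCP_Geometric

from .raster import Raster

#: Aspect assigned to perfectly flat cells (any value is equivalent at slope 0).
FLAT_ASPECT = 180.0


@dataclass
class TerrainGrid:
    """Elevation plus Horn slope/aspect, degrees; aspect clockwise from north."""

    elevation: Raster
    slope: Raster
    aspect: Raster

    @property
    def cell_size(self) -> float:
        return self.elevation.cell_size


@dataclass
class DownscaleConfig:
    """Environmental lapse rate (°C/m, negative) used for altitudinal downscaling."""

    lapse_rate: float = -0.0065
    alternates: tuple[float, ...] = (-0.005, -0.008)

    def __post_init__(self) -> None:
        if self.lapse_rate >= 0:
            raise ValueError("lapse_rate must be negative (temperature decreases with elevation)")


def _horn_gradients(z: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    # Odd reflection about the edge value == linear extrapolation, so borders
    # behave as one-sided differences and planar ramps are exact everywhere.
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    g = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    # dz/dx (east positive); row 0 is the northern edge so north is -row
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell_size)
    return gx, gy


def slope_aspect(elevation: Raster) -> TerrainGrid:
    """Horn 3x3 slope (degrees) and aspect (degrees clockwise from north).

    Flat cells receive slope 0 and the sentinel aspect ``FLAT_ASPECT``.
    """
    z = elevation.data
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation grid must be at least 3x3")
    if not np.all(np.isfinite(z)):
        bad = np.flatnonzero(~np.isfinite(z))
        raise ValueError(f"elevation has {bad.size} non-finite cells (first flat index {bad[0]})")
    gx, gy = _horn_gradients(z, elevation.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    # aspect = compass bearing of the steepest-descent vector (-gx, -gy)
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(slope == 0.0, FLAT_ASPECT, aspect)
    return TerrainGrid(elevation, elevation.like(slope), elevation.like(aspect))


def monthly_mean_from_minmax(tmin: Raster, tmax: Raster) -> Raster:
    """Monthly mean temperature as the midpoint of monthly min and max grids."""
    if tmin.shape != tmax.shape or tmin.origin != tmax.origin or tmin.cell_size != tmax.cell_size:
        raise ValueError("tmin and tmax grids must share shape and georeference")
    return tmin.like((tmin.data + tmax.data) / 2.0)


def coarse_reference_elevation(fine_dem: Raster, coarse_template: Raster) -> Raster:
    """Mean fine elevation aggregated to each coarse cell.

    Used as the elevation the coarse temperature refers to, which makes the
    lapse-rate shift mean-preserving over every coarse cell.
    """
    xs, ys = fine_dem.cell_centers()
    out = np.full(coarse_template.shape, np.nan)
    cnt = np.zeros(coarse_template.shape)
    x0, y0 = coarse_template.origin
    cols = np.floor((xs - x0) / coarse_template.cell_size).astype(int)
    rows = np.floor((y0 - ys) / coarse_template.cell_size).astype(int)
    ok = (rows >= 0) & (rows < out.shape[0]) & (cols >= 0) & (cols < out.shape[1])
    np.add.at(cnt, (rows[ok], cols[ok]), 1.0)
    acc = np.zeros(coarse_template.shape)
    np.add.at(acc, (rows[ok], cols[ok]), fine_dem.data[ok])
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.where(cnt == 0, 1, cnt), np.nan)
    return coarse_template.like(out)


def downscale_temperature(
    coarse_mean: Raster,
    coarse_ref_elev: Raster,
    fine_dem: Raster,
    config: DownscaleConfig | None = None,
) -> Raster:
    """Shift each fine cell's coarse temperature by lapse_rate x elevation offset."""
    config = config or DownscaleConfig()
    xs, ys = fine_dem.cell_centers()
    x0, y0 = coarse_mean.origin
    cols = np.floor((xs - x0) / coarse_mean.cell_size).astype(int)
    rows = np.floor((y0 - ys) / coarse_mean.cell_size).astype(int)
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= coarse_mean.shape[0] or cols.max() >= coarse_mean.shape[1]:
        raise ValueError("fine grid extends outside the coarse grid extent")
    t_coarse = coarse_mean.data[rows, cols]
    z_ref = coarse_ref_elev.data[rows, cols]
    return fine_dem.like(t_coarse + config.lapse_rate * (fine_dem.data - z_ref))


def rasterize_outlines(outlines: list[BaseGeometry], template: Raster) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside any outline polygon."""
    if not outlines:
        raise ValueError("empty outline set")
    xs, ys = template.cell_centers()
    mask = np.zeros(template.shape, dtype=bool)
    for geom in outlines:
        if geom.is_empty:
            continue
        if not geom.is_valid:
            raise ValueError("invalid outline polygon")
        pg = prep(geom)
        minx, miny, maxx, maxy = geom.bounds
        cand = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy) & ~mask
        idx = np.argwhere(cand)
        for r, c in idx:
            if pg.contains(Point(xs[r, c], ys[r, c])):
                mask[r, c] = True
    return mask


def distance_to_glacier(
    outlines: list[BaseGeometry],
    template: Raster,
    max_distance: float = np.inf,
) -> Raster:
    """8-connected chamfer path distance (m) from each cell center to the glacier.

    Cells inside a glacier outline have distance 0; cells farther than
    ``max_distance`` are masked (NaN).
    """
    mask = rasterize_outlines(outlines, template)
    if not mask.any():
        raise ValueError("no raster cell falls inside any outline; refine the grid or outlines")
    costs = np.ones(template.shape)
    mcp = MCP_Geometric(costs)
    starts = [tuple(ix) for ix in np.argwhere(mask)]
    dist, _ = mcp.find_costs(starts)
    dist = dist * template.cell_size
    dist[mask] = 0.0
    dist = np.where(dist <= max_distance, dist, np.nan)
    return template.like(dist)
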