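"""Attribute each aerosol sampling interval to its sea-surface source.

For every dye map falling inside a sampling interval: interpolate the
station wind to the map time (on Cartesian components, so direction
wraps correctly), cast the *upwind* ray from the sampler site (toward
the direction the wind blows FROM), intersect it with the shoreline at
the concurrent water level, and average the dye concentration in a
200 m alongshore x 100 m offshore window centred on that intersection.
The spatio-temporal mean over the interval's windows is the source-water
concentration [dye]_sea; the mean window-centre-to-site distance is the
downwind distance.

Offshore-directed winds produce no shoreline crossing and contribute no
window; intervals with no windows at all (e.g. night, when no dye maps
exist) carry missing [dye]_sea and downwind distance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from skimage import measure

from .core import (
    DyeMap,
    Terrain,
    WaterLevelSeries,
    WindSeries,
    times_to_seconds,
    uv_to_wind,
    wind_to_uv,
)

#: source-window extents (m): alongshore width and offshore reach; the
#: offshore reach is limited to the surfzone where sea spray aerosol is
#: mainly generated by depth-limited wave breaking
ALONGSHORE_EXTENT_M = 200.0
OFFSHORE_EXTENT_M = 100.0


@dataclass
class Shoreline:
    """Land/water boundary polyline at a given water level."""

    vertices: np.ndarray  # (n, 2) local (x, y) metres
    water_level: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("shoreline needs >= 2 (x, y) vertices")

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)


@dataclass
class SourceWindow:
    """One per-map upwind source window and its spatial-mean dye value."""

    center: tuple  # (x, y) shoreline intersection, metres
    map_time: np.datetime64
    mean_conc: Optional[float]  # ppb; None when no valid cells fall inside
    n_cells: int = 0
    alongshore_extent: float = ALONGSHORE_EXTENT_M
    offshore_extent: float = OFFSHORE_EXTENT_M


@dataclass
class SiteAttribution:
    """Interval-level attribution result for one aerosol sample."""

    sample_id: int
    dye_sea_ppb: Optional[float]
    inland_m: float
    downwind_m: Optional[float]
    windows: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# winds


def interpolate_wind(winds: WindSeries, target_times):
    """Wind (speed, FROM-direction) at ``target_times``.

    Interpolation is linear on Cartesian (u, v) components and converted
    back, so directions interpolate across the 0/360 wrap (midway between
    350 deg and 10 deg is 0 deg, never 180).  Targets outside the station
    record are refused rather than extrapolated.
    """
    tt = times_to_seconds(np.atleast_1d(np.asarray(target_times, dtype="datetime64[s]")))
    ts = times_to_seconds(winds.times)
    if tt.min() < ts[0] or tt.max() > ts[-1]:
        raise ValueError("target times outside the wind record; refusing to extrapolate")
    u, v = wind_to_uv(winds.speed_ms, winds.dir_deg_from)
    ui = np.interp(tt, ts, u)
    vi = np.interp(tt, ts, v)
    return uv_to_wind(ui, vi)


# ---------------------------------------------------------------------------
# shoreline geometry


def shoreline_at(terrain: Terrain, water_level: float) -> Shoreline:
    """Shoreline polyline: the contour of elevation == water_level.

    When the contour is broken (islands, ponds) the longest piece is
    taken as the open-coast shoreline.
    """
    z = terrain.elevation
    if not (z.min() < water_level < z.max()):
        raise ValueError("water level outside terrain elevation range: no shoreline")
    contours = measure.find_contours(z, water_level)
    if not contours:
        raise ValueError("no shoreline contour found at this water level")
    best = max(contours, key=len)
    x = terrain.origin[0] + best[:, 1] * terrain.cell_size
    y = terrain.origin[1] + best[:, 0] * terrain.cell_size
    return Shoreline(np.column_stack([x, y]), float(water_level))


def upwind_intersection(
    site, speed_ms: float, dir_deg_from: float, shoreline: Shoreline, max_range_m: float = 50_000.0
):
    """Nearest crossing of the upwind ray from ``site`` with the shoreline.

    The ray points toward the direction the wind blows FROM.  Returns the
    (x, y) crossing nearest the site, or None when the ray never meets
    the shoreline (offshore-directed wind).
    """
    if speed_ms <= 0:
        raise ValueError("wind speed must be positive to define an upwind direction")
    theta = np.deg2rad(dir_deg_from)
    d = np.array([np.sin(theta), np.cos(theta)])  # unit vector toward FROM-direction
    p0 = np.asarray(site, dtype=float)
    ray = LineString([p0, p0 + max_range_m * d])
    hit = ray.intersection(shoreline.line)
    if hit.is_empty:
        return None
    pts = []
    for geom in getattr(hit, "geoms", [hit]):
        if isinstance(geom, Point):
            pts.append((geom.x, geom.y))
        else:  # collinear overlap: take its endpoints
            pts.extend(list(geom.coords))
    pts = np.asarray(pts)
    dist = np.hypot(pts[:, 0] - p0[0], pts[:, 1] - p0[1])
    return tuple(pts[np.argmin(dist)])


def shoreline_tangent(shoreline: Shoreline, point, half_step_m: float = 2.0) -> np.ndarray:
    """Unit tangent of the shoreline at (near) ``point``."""
    line = shoreline.line
    s = line.project(Point(point))
    p1 = line.interpolate(max(s - half_step_m, 0.0))
    p2 = line.interpolate(min(s + half_step_m, line.length))
    t = np.array([p2.x - p1.x, p2.y - p1.y])
    n = np.linalg.norm(t)
    if n == 0:
        raise ValueError("degenerate shoreline segment")
    return t / n


def extract_window(
    dyemap: DyeMap,
    center,
    tangent,
    landward_point,
    alongshore_extent: float = ALONGSHORE_EXTENT_M,
    offshore_extent: float = OFFSHORE_EXTENT_M,
) -> SourceWindow:
    """Spatial-mean dye in the source rectangle on one map.

    The rectangle is centred alongshore on ``center``, aligned to the
    local shoreline ``tangent``, and extends ``offshore_extent`` on the
    seaward side (the side away from ``landward_point``, normally the
    sampler site).  A cell belongs to the window when its centre falls
    inside the rectangle.  With no valid cells, mean_conc is None.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    normal = np.array([t[1], -t[0]])  # one of the two shore-normals
    c = np.asarray(center, dtype=float)
    to_land = np.asarray(landward_point, dtype=float) - c
    if np.dot(normal, to_land) > 0:  # make the normal point seaward
        normal = -normal

    xc, yc = np.meshgrid(dyemap.x_centers, dyemap.y_centers)  # (ny, nx)
    dx = xc - c[0]
    dy = yc - c[1]
    s = dx * t[0] + dy * t[1]  # alongshore offset
    q = dx * normal[0] + dy * normal[1]  # seaward offset
    inside = (np.abs(s) <= alongshore_extent / 2.0) & (q >= 0.0) & (q <= offshore_extent)
    vals = dyemap.conc_ppb[inside]
    vals = vals[np.isfinite(vals)]
    mean_conc = float(vals.mean()) if vals.size else None
    return SourceWindow(
        center=(float(c[0]), float(c[1])),
        map_time=dyemap.time,
        mean_conc=mean_conc,
        n_cells=int(vals.size),
        alongshore_extent=alongshore_extent,
        offshore_extent=offshore_extent,
    )


def mean_source_concentration(windows) -> Optional[float]:
    """Unweighted mean over maps of the per-window spatial means; None
    when no window carries a value (e.g. night samples)."""
    vals = [w.mean_conc for w in windows if w.mean_conc is not None]
    return float(np.mean(vals)) if vals else None


def distance_inland(site, shoreline: Shoreline) -> float:
    """Minimum Euclidean distance (m) from the site to the shoreline."""
    return float(shoreline.line.distance(Point(site)))


def distance_downwind(site, windows) -> Optional[float]:
    """Mean distance (m) from the per-map window centres to the site."""
    p = np.asarray(site, dtype=float)
    ds = [
        float(np.hypot(w.center[0] - p[0], w.center[1] - p[1]))
        for w in windows
        if w.mean_conc is not None
    ]
    return float(np.mean(ds)) if ds else None


def transit_time_s(distance_m: float, speed_ms: float) -> float:
    """Advective transit time (s) over ``distance_m`` at ``speed_ms`` —
    the sanity check justifying zero lag between wind and source times."""
    if speed_ms <= 0:
        raise ValueError("speed must be positive")
    return distance_m / speed_ms


# ---------------------------------------------------------------------------
# interval-level driver


def attribute_sample(
    sample_id: int,
    site,
    start,
    end,
    winds: WindSeries,
    dye_maps,
    terrain: Terrain,
    water_levels: WaterLevelSeries,
    alongshore_extent: float = ALONGSHORE_EXTENT_M,
    offshore_extent: float = OFFSHORE_EXTENT_M,
) -> SiteAttribution:
    """Full attribution of one sampling interval.

    Each dye map inside [start, end] gets its own interpolated wind,
    tidal shoreline, upwind intersection and window; maps whose wind is
    offshore-directed are skipped.  Distance inland uses the datum
    (water level 0) shoreline, so it is fixed per site while downwind
    distance varies with the winds.
    """
    start = np.datetime64(start, "s")
    end = np.datetime64(end, "s")
    windows = []
    for m in dye_maps:
        if not (start <= m.time <= end):
            continue
        speed, direction = interpolate_wind(winds, m.time)
        speed = float(speed[0])
        direction = float(direction[0])
        if speed <= 0:
            continue
        eta = float(water_levels.at(m.time)[0])
        shore = shoreline_at(terrain, eta)
        hit = upwind_intersection(site, speed, direction, shore)
        if hit is None:
            continue
        tangent = shoreline_tangent(shore, hit)
        windows.append(
            extract_window(m, hit, tangent, site, alongshore_extent, offshore_extent)
        )

    datum_shore = shoreline_at(terrain, 0.0)
    return SiteAttribution(
        sample_id=sample_id,
        dye_sea_ppb=mean_source_concentration(windows),
        inland_m=distance_inland(site, datum_shore),
        downwind_m=distance_downwind(site, windows),
        windows=windows,
    )


def attribute_samples(
    samples, winds: WindSeries, dye_maps, terrain: Terrain, water_levels: WaterLevelSeries
) -> pd.DataFrame:
    """Attribution table for a list of AerosolSample-like objects with
    ``id``, ``location``, ``start`` and ``end`` attributes."""
    rows = []
    for s in samples:
        att = attribute_sample(
            s.id, s.location, s.start, s.end, winds, dye_maps, terrain, water_levels
        )
        rows.append(
            {
                "id": att.sample_id,
                "dye_sea_ppb": att.dye_sea_ppb,
                "inland_m": att.inland_m,
                "downwind_m": att.downwind_m,
                "n_windows": sum(1 for w in att.windows if w.mean_conc is not None),
            }
        )
    return pd.DataFrame(rows)
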