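"""Monthly home-range estimation via k-LoCoh isopleths.

The local convex hull (LoCoh) estimator builds, for every fix, the
convex hull of that fix and its k nearest neighbours, orders the hulls
by ascending area, and accumulates their union until it covers a target
fraction of all fixes. The 50% isopleth is the intensively used core;
the 90% isopleth the total monthly range. The minimum convex polygon
(MCP) of all points is the degenerate case (fraction 1, k = n-1) and
serves as an independent check.

Geographic coordinates are first projected to a local plane with an
azimuthal equidistant projection about the point centroid, which
preserves distances from the centroid exactly and areas to first order
at home-range scale (tens of km).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point

from .trajectory import DEFAULT_TZ_OFFSET_H, EARTH_RADIUS_KM, Trajectory

__all__ = [
    "MonthlyRange",
    "project_local",
    "project_inverse",
    "locoh_isopleths",
    "locoh_hulls",
    "mcp_area",
    "monthly_ranges",
    "default_k",
]


# ---------------------------------------------------------------------------
# local projection (spherical azimuthal equidistant)
# ---------------------------------------------------------------------------

def project_local(
    lon: np.ndarray, lat: np.ndarray, center: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Project lon/lat (degrees) to planar x/y in km.

    Azimuthal equidistant about ``center`` (default: the coordinate
    centroid). Returns ``(x, y, center)`` so the inverse is available.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size == 0:
        raise ValueError("empty input")
    if center is None:
        center = (float(lon.mean()), float(lat.mean()))
    lam0, phi0 = math.radians(center[0]), math.radians(center[1])
    lam, phi = np.radians(lon), np.radians(lat)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    # k' = c / sin c, with the c -> 0 limit of 1
    with np.errstate(invalid="ignore", divide="ignore"):
        kprime = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_KM * kprime * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * kprime * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y, center


def project_inverse(
    x: np.ndarray, y: np.ndarray, center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_local`: planar km back to lon/lat degrees."""
    x = np.atleast_1d(np.asarray(x, dtype=float)) / EARTH_RADIUS_KM
    y = np.atleast_1d(np.asarray(y, dtype=float)) / EARTH_RADIUS_KM
    lam0, phi0 = math.radians(center[0]), math.radians(center[1])
    c = np.hypot(x, y)
    safe_c = np.where(c > 1e-12, c, 1.0)
    sin_c, cos_c = np.sin(c), np.cos(c)
    phi = np.arcsin(
        np.where(
            c > 1e-12,
            cos_c * math.sin(phi0) + y * sin_c * math.cos(phi0) / safe_c,
            math.sin(phi0),
        )
    )
    lam = lam0 + np.where(
        c > 1e-12,
        np.arctan2(
            x * sin_c,
            safe_c * math.cos(phi0) * cos_c - y * sin_c * math.sin(phi0),
        ),
        0.0,
    )
    return np.degrees(lam), np.degrees(phi)


# ---------------------------------------------------------------------------
# LoCoh
# ---------------------------------------------------------------------------

def default_k(n: int) -> int:
    """The square-root heuristic for the LoCoh neighbour count."""
    return max(2, math.ceil(math.sqrt(n)))


def _point_hulls(pts: np.ndarray, k: int) -> list:
    """Per-point convex hulls of each point plus its k nearest
    neighbours, ties broken by point index (stable sort on distance)."""
    n = pts.shape[0]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    hulls = []
    for i in range(n):
        nbr = np.argsort(d2[i], kind="stable")[: k + 1]  # includes i itself
        hulls.append(MultiPoint(pts[nbr]).convex_hull)
    return hulls


def locoh_hulls(points: np.ndarray, k: int):
    """Ordered LoCoh hulls and their cumulative point coverage.

    Returns ``(hulls, order, coverage)`` where ``hulls`` are shapely
    geometries in ascending-area order (ties by parent index),
    and ``coverage[m]`` is the number of points covered (inside or on
    the boundary) by the union of the first ``m+1`` hulls.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    if k + 1 < 3:
        raise ValueError("need k+1 >= 3")
    hulls = _point_hulls(pts, k)
    areas = np.array([h.area for h in hulls])
    order = np.lexsort((np.arange(n), areas))  # area asc, parent index asc
    shp_pts = shapely.points(pts)
    # membership: covered(p) after m hulls <=> some added hull covers p
    covered = np.zeros(n, dtype=bool)
    coverage = np.zeros(n, dtype=int)
    tree = shapely.STRtree(shp_pts)
    running = 0
    for m, idx in enumerate(order):
        h = hulls[idx]
        cand = tree.query(h, predicate="covers")
        new = cand[~covered[cand]]
        covered[new] = True
        running += new.size
        coverage[m] = running
    return [hulls[i] for i in order], order, coverage


def locoh_isopleths(
    points: np.ndarray,
    k: int,
    fractions: tuple[float, ...] = (0.5, 0.9),
    return_geoms: bool = False,
) -> dict:
    """Union areas (km^2) of the accumulated LoCoh hulls per fraction.

    For each requested fraction f, hulls are accumulated in ascending
    area order until their union covers at least ``ceil(f * n)`` of the
    points; the union's area is returned. Monotone in f by construction.
    All-collinear input yields zero areas with a warning.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("fractions must lie in (0, 1]")
    hulls, _, coverage = locoh_hulls(pts, k)
    if hulls[-1].area == 0.0 and MultiPoint(pts).convex_hull.area == 0.0:
        warnings.warn("degenerate (collinear) point set: zero-area isopleths",
                      RuntimeWarning)
    out: dict[float, float] = {}
    geoms: dict[float, object] = {}
    for f in sorted(fractions):
        need = math.ceil(f * n)
        m = int(np.searchsorted(coverage, need))
        m = min(m, len(hulls) - 1)
        union = shapely.unary_union(hulls[: m + 1])
        out[f] = float(union.area)
        if return_geoms:
            geoms[f] = union
    return (out, geoms) if return_geoms else out


def mcp_area(points: np.ndarray, fraction: float = 1.0) -> float:
    """Minimum convex polygon area (km^2) of the ``fraction`` of points
    closest to the centroid. Degenerate (collinear) geometry returns 0
    with a warning."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    centroid = pts.mean(axis=0)
    d = np.hypot(*(pts - centroid).T)
    keep = np.argsort(d, kind="stable")[: max(3, math.ceil(fraction * n))]
    hull = MultiPoint(pts[keep]).convex_hull
    if hull.area == 0.0:
        warnings.warn("degenerate (collinear) point set: zero-area MCP",
                      RuntimeWarning)
    return float(hull.area)


# ---------------------------------------------------------------------------
# monthly ranges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonthlyRange:
    """Per-female, per-calendar-month core and total range."""

    female_id: str
    month: pd.Period
    core50_km2: float
    total90_km2: float
    n_points: int
    k: int


def monthly_ranges(
    traj: Trajectory,
    k_rule=default_k,
    fractions: tuple[float, float] = (0.5, 0.9),
    min_points: int = 10,
    tz_offset_h: int = DEFAULT_TZ_OFFSET_H,
) -> list[MonthlyRange]:
    """k-LoCoh core/total areas per calendar month (local civil time).

    Months with fewer than ``max(min_points, k+1)`` fixes are skipped
    (flagged absent by omission from the result).
    """
    if len(traj) == 0:
        return []
    local = traj.df["t"] + pd.Timedelta(hours=tz_offset_h)
    month = local.dt.tz_localize(None).dt.to_period("M")
    out: list[MonthlyRange] = []
    f_lo, f_hi = min(fractions), max(fractions)
    for m, idx in traj.df.groupby(month).groups.items():
        sub = traj.df.loc[idx]
        n = len(sub)
        k = k_rule(n)
        if n < max(min_points, k + 1):
            continue
        x, y, _ = project_local(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        areas = locoh_isopleths(np.column_stack([x, y]), k, (f_lo, f_hi))
        out.append(
            MonthlyRange(
                female_id=traj.female_id,
                month=m,
                core50_km2=areas[f_lo],
                total90_km2=areas[f_hi],
                n_points=n,
                k=k,
            )
        )
    out.sort(key=lambda r: r.month)
    return out


def monthly_range_polygons(
    traj: Trajectory,
    k_rule=default_k,
    fractions: tuple[float, float] = (0.5, 0.9),
    min_points: int = 10,
    tz_offset_h: int = DEFAULT_TZ_OFFSET_H,
) -> list[tuple[dict, object]]:
    """Per-month isopleth polygons, inverse-projected to WGS84.

    Returns (properties, shapely geometry) pairs suitable for GeoJSON
    export; properties carry female id, month, fraction and area.
    """
    from shapely.ops import transform

    if len(traj) == 0:
        return []
    local = traj.df["t"] + pd.Timedelta(hours=tz_offset_h)
    month = local.dt.tz_localize(None).dt.to_period("M")
    out = []
    for m, idx in traj.df.groupby(month).groups.items():
        sub = traj.df.loc[idx]
        n = len(sub)
        k = k_rule(n)
        if n < max(min_points, k + 1):
            continue
        x, y, center = project_local(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        areas, geoms = locoh_isopleths(
            np.column_stack([x, y]), k, fractions, return_geoms=True)
        for f in sorted(fractions):
            geom = transform(lambda px, py: project_inverse(px, py, center),
                             geoms[f])
            out.append(
                ({"female_id": traj.female_id, "month": str(m),
                  "fraction": f, "area_km2": areas[f]}, geom)
            )
    return out
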