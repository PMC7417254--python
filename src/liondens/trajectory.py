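"""Movement indicators from GPS fix streams.

A trajectory is the time-ordered sequence of collar fixes for one
female. From it we derive the three behavioural indicators used to flag
parturition: step lengths between consecutive fixes, daily net
displacement, and residency clusters (maximal runs of consecutive fixes
inside a 200 m radius, the proxy for a den or carcass site).

All distances are great-circle (haversine) on a sphere of radius
6371.0088 km; at the 200 m cluster scale this is accurate to well under
a metre. Civil days are bounded at UTC+2 (South African civil time) by
default, configurable via ``tz_offset_h``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "GPSFix",
    "Trajectory",
    "ResidencyCluster",
    "haversine_km",
    "step_lengths",
    "daily_net_displacement",
    "detect_clusters",
    "duration_of_stay",
]

EARTH_RADIUS_KM = 6371.0088
DEFAULT_TZ_OFFSET_H = 2  # Kruger civil time


@dataclass(frozen=True)
class GPSFix:
    """One collar position record."""

    female_id: str
    t: pd.Timestamp
    lon: float
    lat: float
    altitude_m: float | None = None
    temperature_C: float | None = None


class Trajectory:
    """Time-ordered fixes for one female.

    Wraps a DataFrame with columns ``t`` (tz-aware UTC timestamps),
    ``lon`` and ``lat`` (WGS84 decimal degrees). Timestamps must be
    strictly increasing; gaps (failed fixes) are allowed.
    """

    def __init__(self, female_id: str, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        required = {"t", "lon", "lat"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        t = pd.to_datetime(df["t"], utc=True)
        if len(t) > 1 and not (t.diff().dropna() > pd.Timedelta(0)).all():
            raise ValueError("timestamps must be strictly increasing")
        lat = df["lat"].to_numpy(dtype=float)
        lon = df["lon"].to_numpy(dtype=float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("coordinates outside WGS84 bounds")
        self.female_id = female_id
        self.df = df.assign(t=t)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.df["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.df["lat"].to_numpy(dtype=float)


@dataclass(frozen=True)
class ResidencyCluster:
    """Maximal run of consecutive fixes within ``radius_m`` of a common
    running centroid; candidate den (or carcass) site."""

    female_id: str
    start_t: pd.Timestamp
    end_t: pd.Timestamp
    centroid_lon: float
    centroid_lat: float
    n_fixes: int
    max_radius_m: float

    @property
    def duration_days(self) -> float:
        return (self.end_t - self.start_t).total_seconds() / 86400.0

    def overlaps(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        return self.start_t <= end and self.end_t >= start


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km between WGS84 points (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def step_lengths(traj: Trajectory) -> pd.DataFrame:
    """Distance (km) between each pair of consecutive fixes.

    Returns a DataFrame with ``t_start``, ``t_end``, ``distance_km``;
    empty (with those columns) for trajectories of fewer than two fixes.
    """
    cols = ["t_start", "t_end", "distance_km"]
    if len(traj) < 2:
        return pd.DataFrame(columns=cols)
    lon, lat = traj.lon, traj.lat
    d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    return pd.DataFrame(
        {"t_start": traj.t[:-1], "t_end": traj.t[1:], "distance_km": d}
    )


def daily_net_displacement(
    traj: Trajectory,
    tz_offset_h: int = DEFAULT_TZ_OFFSET_H,
    how: str = "mean",
) -> pd.Series:
    """Per-civil-day displacement statistic, indexed by local date.

    Each step is attributed to the civil day (boundary at
    ``tz_offset_h`` east of UTC) containing its *later* fix.
    ``how="mean"`` averages the day's step distances; ``how="sum"``
    totals them, i.e. the distance travelled that day. Days with no
    steps are omitted.
    """
    if how not in ("mean", "sum"):
        raise ValueError("how must be 'mean' or 'sum'")
    steps = step_lengths(traj)
    if steps.empty:
        return pd.Series(dtype=float, name=f"net_displacement_{how}")
    local_end = pd.DatetimeIndex(steps["t_end"]) + pd.Timedelta(hours=tz_offset_h)
    day = local_end.floor("D").date
    grouped = steps.groupby(day)["distance_km"]
    out = grouped.mean() if how == "mean" else grouped.sum()
    out.name = f"net_displacement_{how}"
    out.index.name = "day"
    return out


def detect_clusters(
    traj: Trajectory,
    radius_m: float = 200.0,
    min_fixes: int = 3,
    anchor: str = "centroid",
) -> list[ResidencyCluster]:
    """Greedy maximal residency clusters.

    Scanning in time order, a fix joins the open cluster iff its
    distance to the cluster anchor is at most ``radius_m``; otherwise
    the cluster closes (kept iff it holds ``min_fixes`` fixes) and a new
    one opens at that fix. The anchor is the running centroid of the
    accepted fixes (``anchor="centroid"``) or the first fix
    (``anchor="first"``). Gaps from failed fixes do not break a cluster:
    only a received fix outside the radius does.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if anchor not in ("centroid", "first"):
        raise ValueError("anchor must be 'centroid' or 'first'")
    lon, lat, t = traj.lon, traj.lat, traj.t
    n = len(traj)
    clusters: list[ResidencyCluster] = []
    if n == 0:
        return clusters

    start = 0
    sum_lon, sum_lat = lon[0], lat[0]
    count = 1
    max_r = 0.0

    def close(end_idx: int) -> None:
        nonlocal clusters
        if count >= min_fixes:
            clusters.append(
                ResidencyCluster(
                    female_id=traj.female_id,
                    start_t=pd.Timestamp(t[start]),
                    end_t=pd.Timestamp(t[end_idx]),
                    centroid_lon=sum_lon / count,
                    centroid_lat=sum_lat / count,
                    n_fixes=count,
                    max_radius_m=max_r,
                )
            )

    for i in range(1, n):
        if anchor == "centroid":
            c_lon, c_lat = sum_lon / count, sum_lat / count
        else:
            c_lon, c_lat = lon[start], lat[start]
        d_m = float(haversine_km(c_lon, c_lat, lon[i], lat[i])) * 1000.0
        if d_m <= radius_m:
            sum_lon += lon[i]
            sum_lat += lat[i]
            count += 1
            max_r = max(max_r, d_m)
        else:
            close(i - 1)
            start = i
            sum_lon, sum_lat = lon[i], lat[i]
            count = 1
            max_r = 0.0
    close(n - 1)
    return clusters


def duration_of_stay(
    clusters: Sequence[ResidencyCluster],
    window_start: pd.Timestamp | None = None,
    window_end: pd.Timestamp | None = None,
    min_duration_days: float = 0.0,
) -> dict:
    """Summary of time spent at residency sites.

    Restricted to clusters overlapping ``[window_start, window_end]``
    (both optional) and lasting at least ``min_duration_days``. Returns
    ``{"count", "mean_days", "se_days", "max_days"}``; ``mean_days`` and
    friends are NaN when no cluster qualifies.
    """
    sel = []
    for c in clusters:
        if window_start is not None and window_end is not None:
            if not c.overlaps(window_start, window_end):
                continue
        if c.duration_days < min_duration_days:
            continue
        sel.append(c.duration_days)
    if not sel:
        return {"count": 0, "mean_days": float("nan"),
                "se_days": float("nan"), "max_days": float("nan")}
    arr = np.asarray(sel, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return {
        "count": int(arr.size),
        "mean_days": float(arr.mean()),
        "se_days": se,
        "max_days": float(arr.max()),
    }
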