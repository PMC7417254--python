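"""CSV / GeoJSON readers and writers for the pipeline artifacts.

All CSVs are RFC-4180 with a mandatory header row; timestamps are
serialised ISO-8601 UTC, coordinates as decimal degrees (6 dp in files,
full precision in memory elsewhere). Polygons and cluster centroids go
out as RFC 7946 GeoJSON in WGS84.
"""

from __future__ import annotations

import json
import logging
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import mapping

from .synth import TruthRecord
from .trajectory import ResidencyCluster, Trajectory

log = logging.getLogger("liondens")

FIX_COLUMNS = ["female_id", "timestamp_iso8601", "lon", "lat"]


def write_fixes(trajectories: Iterable[Trajectory], path) -> None:
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "female_id": traj.female_id,
                    "timestamp_iso8601": traj.df["t"].dt.strftime(
                        "%Y-%m-%dT%H:%M:%SZ"),
                    "lon": traj.df["lon"].round(6),
                    "lat": traj.df["lat"].round(6),
                }
            )
        )
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=FIX_COLUMNS))
    out.to_csv(path, index=False)


def read_fixes(path) -> list[Trajectory]:
    """Read a fix CSV into per-female trajectories.

    Rows are grouped by female and sorted by time. Malformed rows
    (unparseable timestamps, coordinates off the globe) are dropped and
    counted in the log; duplicate timestamps within a female are
    rejected.
    """
    df = pd.read_csv(path)
    missing = set(FIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fix CSV missing columns: {sorted(missing)}")
    if df.empty:
        return []
    t = pd.to_datetime(df["timestamp_iso8601"], utc=True, errors="coerce",
                       format="ISO8601")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = t.isna() | lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    if bad.any():
        for i in df.index[bad]:
            log.warning("dropping malformed fix row %d: %s", i,
                        df.loc[i].to_dict())
    df = df.loc[~bad].assign(t=t[~bad], lon=lon[~bad], lat=lat[~bad])
    out = []
    for fid, grp in df.groupby("female_id", sort=True):
        grp = grp.sort_values("t")
        if grp["t"].duplicated().any():
            raise ValueError(f"duplicate timestamps for female {fid}")
        out.append(Trajectory(str(fid), grp[["t", "lon", "lat"]]))
    return out


def write_environment(env: pd.DataFrame, path) -> None:
    cols = ["region", "year", "month", "rainfall_mm", "prey_biomass", "prey_pulse"]
    env[cols].to_csv(path, index=False)


def read_environment(path) -> pd.DataFrame:
    env = pd.read_csv(path)
    required = {"region", "year", "month", "rainfall_mm", "prey_biomass",
                "prey_pulse"}
    missing = required - set(env.columns)
    if missing:
        raise ValueError(f"environment CSV missing columns: {sorted(missing)}")
    env["prey_pulse"] = env["prey_pulse"].astype(bool)
    return env


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    rows = []
    for r in truth:
        rows.append(
            {
                "female_id": r.female_id,
                "region": r.region,
                "pregnant": r.pregnant,
                "conception_month": str(r.conception_month) if r.pregnant else "",
                "birth_month": str(r.birth_month) if r.pregnant else "",
                "den_lon": r.den_lon if r.den_lon is not None else "",
                "den_lat": r.den_lat if r.den_lat is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, dtype={"conception_month": str, "birth_month": str})
    out = []
    for _, r in df.iterrows():
        pregnant = bool(r["pregnant"])
        out.append(
            TruthRecord(
                female_id=str(r["female_id"]),
                region=str(r["region"]),
                pregnant=pregnant,
                conception_month=(pd.Period(r["conception_month"], "M")
                                  if pregnant else None),
                birth_month=(pd.Period(r["birth_month"], "M")
                             if pregnant else None),
                den_lon=float(r["den_lon"]) if pregnant and pd.notna(r.get("den_lon")) else None,
                den_lat=float(r["den_lat"]) if pregnant and pd.notna(r.get("den_lat")) else None,
            )
        )
    return out


def write_clusters(clusters: Sequence[ResidencyCluster], path) -> None:
    rows = [
        {
            "female_id": c.female_id,
            "start_t": c.start_t.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "end_t": c.end_t.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "centroid_lon": round(c.centroid_lon, 6),
            "centroid_lat": round(c.centroid_lat, 6),
            "n_fixes": c.n_fixes,
            "duration_days": c.duration_days,
            "max_radius_m": c.max_radius_m,
        }
        for c in clusters
    ]
    pd.DataFrame(
        rows,
        columns=["female_id", "start_t", "end_t", "centroid_lon",
                 "centroid_lat", "n_fixes", "duration_days", "max_radius_m"],
    ).to_csv(path, index=False)


def clusters_geojson(clusters: Sequence[ResidencyCluster]) -> dict:
    """Cluster centroids as a GeoJSON FeatureCollection (WGS84 points)."""
    features = []
    for c in clusters:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [round(c.centroid_lon, 6),
                                             round(c.centroid_lat, 6)]},
                "properties": {
                    "female_id": c.female_id,
                    "start_t": c.start_t.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "end_t": c.end_t.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "n_fixes": c.n_fixes,
                    "duration_days": c.duration_days,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def polygons_geojson(named_geoms: Sequence[tuple[dict, object]]) -> dict:
    """(properties, shapely geometry) pairs to a FeatureCollection."""
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for props, geom in named_geoms
    ]
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=None, separators=(",", ":"))
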