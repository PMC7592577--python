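"""Trajectory CSV, region GeoJSON and manifest I/O."""

from __future__ import annotations

import json
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .grids import RegionMask
from .movement import Trajectory

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "region_to_geojson",
    "write_region_geojson",
    "write_manifest",
]

# nominal study epoch used to render ISO-8601 timestamps (Movebank flavour)
STUDY_EPOCH = datetime(2020, 1, 1, tzinfo=timezone.utc)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    ts = [STUDY_EPOCH + timedelta(seconds=float(s)) for s in traj.t]
    df = pd.DataFrame(
        {
            "individual_id": traj.individual_id,
            "species": traj.species_id,
            "timestamp": [t.strftime("%Y-%m-%dT%H:%M:%SZ") for t in ts],
            "x": traj.x,
            "y": traj.y,
            "state": traj.state if traj.state is not None else "",
            "loc_error": traj.loc_error,
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"], utc=True)
    t = (ts - pd.Timestamp(STUDY_EPOCH)).dt.total_seconds().to_numpy()
    state = None
    if "state" in df and not df["state"].isna().all() and not (df["state"] == "").all():
        state = df["state"].astype(int).to_numpy()
    return Trajectory(
        individual_id=str(df["individual_id"].iloc[0]),
        species_id=int(df["species"].iloc[0]),
        t=t,
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        state=state,
        loc_error=float(df["loc_error"].iloc[0]) if "loc_error" in df else 5.0,
    )


def region_to_geojson(region: RegionMask) -> dict:
    """GeoJSON Feature for a region (polygonized raster mask or polygon)."""
    geometry: dict
    if region.polygon is not None:
        import shapely

        geometry = json.loads(shapely.to_geojson(region.polygon))
    elif region.mask is not None and region.grid is not None:
        from skimage import measure

        g = region.grid
        padded = np.zeros((g.n_rows + 2, g.n_cols + 2))
        padded[1:-1, 1:-1] = region.mask.astype(float)
        rings = measure.find_contours(padded, 0.5)
        polys = []
        for ring in rings:
            # contour coords are (row, col) on the padded grid
            xs = g.origin_x + (ring[:, 1] - 1 + 0.5) * g.cell_size
            ys = g.origin_y + (ring[:, 0] - 1 + 0.5) * g.cell_size
            polys.append([[float(x), float(y)] for x, y in zip(xs, ys)])
        geometry = {"type": "MultiPolygon", "coordinates": [[p] for p in polys]}
    else:
        raise ValueError("region has neither polygon nor mask")
    return {
        "type": "Feature",
        "geometry": geometry,
        "properties": {
            "method": region.method,
            "level": region.level,
            "area_m2": region.area,
            "converged": bool(region.converged),
        },
    }


def write_region_geojson(region: RegionMask, path, sidecar: dict | None = None) -> None:
    feature = region_to_geojson(region)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)
    if sidecar is not None:
        side = dict(feature["properties"])
        side.update(sidecar)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(side, fh, indent=2)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
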