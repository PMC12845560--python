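"""Map-aware preprocessing of raw UWB position tracks.

Raw real-time-location samples (t, x, y, z in cm at nominally 1 Hz) are
made physically consistent with the floor plan before filtering, in this
order: (1) samples inside forbidden zones are relocated to the closest
feasible corridor by a purely vertical/horizontal move; (2) temporal gaps
shorter than 60 s are filled at 1 Hz — by linear interpolation when the
straight line between the gap endpoints crosses no wall or forbidden zone,
otherwise along the polyline routed through the door anchors connecting
the endpoint zones; (3) samples inside corridor polygons are snapped
orthogonally to the corridor center line.  Interpolated samples carry an
inflated measurement covariance (cov_scale = alpha_R); gaps of 60 s or
more are left as missing coverage.

Tracks are pandas DataFrames with columns
``t, x, y, z, interpolated, cov_scale``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .floorplan import (FloorPlan, door_route, first_wall_crossing,
                        project_to_corridor)

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["t", "x", "y", "z", "interpolated", "cov_scale"]


def make_track(t, x, y, z=None, interpolated=None, cov_scale=None) -> pd.DataFrame:
    n = len(t)
    df = pd.DataFrame({
        "t": np.asarray(t, dtype=float),
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
        "z": np.zeros(n) if z is None else np.asarray(z, dtype=float),
        "interpolated": (np.zeros(n, dtype=bool) if interpolated is None
                         else np.asarray(interpolated, dtype=bool)),
        "cov_scale": (np.ones(n) if cov_scale is None
                      else np.asarray(cov_scale, dtype=float)),
    })
    if np.any(np.diff(df["t"].to_numpy()) <= 0):
        raise ValueError("track timestamps must be strictly increasing")
    return df


def relocate_forbidden(track: pd.DataFrame, plan: FloorPlan) -> pd.DataFrame:
    """Replace every sample inside a forbidden zone by its corridor
    projection; all other samples are untouched."""
    forbidden = [z.polygon for z in plan.zones_of_kind("forbidden")]
    if not forbidden or track.empty:
        return track.copy()
    out = track.copy()
    n_moved = 0
    for i in out.index:
        p = (out.at[i, "x"], out.at[i, "y"])
        if any(poly.covers(Point(p)) for poly in forbidden):
            reloc = project_to_corridor(p, plan)
            out.at[i, "x"], out.at[i, "y"] = reloc.point
            n_moved += 1
            if not reloc.axis_aligned:
                logger.warning("sample %d: no axis-aligned corridor move; "
                               "Euclidean fallback used", i)
    if n_moved:
        logger.info("relocated %d forbidden-zone samples", n_moved)
    return out


def _segment_feasible(p, q, plan: FloorPlan) -> bool:
    """True when segment p->q crosses no wall and no forbidden zone."""
    if first_wall_crossing(p, q, plan):
        return False
    seg = LineString([p, q])
    for z in plan.zones_of_kind("forbidden"):
        if seg.intersection(z.polygon).length > 1e-9:
            return False
    return True


def fill_gaps(track: pd.DataFrame, plan: FloorPlan, max_gap: float = 60.0,
              alpha_R: float = 4.0) -> pd.DataFrame:
    """Fill sub-``max_gap`` temporal gaps with 1 Hz interpolated samples.

    Inserted timestamps lie on the integer-second grid strictly between
    the gap endpoints; positions follow either the straight endpoint
    segment or the door-routed polyline, traversed at uniform speed
    (constant-speed arc-length parameterization).  Original samples are
    never altered.  Gaps with no feasible door route are left unfilled.
    """
    if track.empty:
        return track.copy()
    rows = [track.iloc[[0]]]
    t_arr = track["t"].to_numpy()
    for i in range(1, len(track)):
        t0, t1 = t_arr[i - 1], t_arr[i]
        dt = t1 - t0
        if 1.0 < dt < max_gap:
            p0 = (track.iloc[i - 1]["x"], track.iloc[i - 1]["y"])
            p1 = (track.iloc[i]["x"], track.iloc[i]["y"])
            path = None
            if _segment_feasible(p0, p1, plan):
                path = [p0, p1]
            else:
                za = plan.zone_containing(p0)
                zb = plan.zone_containing(p1)
                anchors = None
                if za is not None and zb is not None:
                    anchors = door_route(za.name, zb.name, plan)
                if anchors is not None:
                    path = [p0, *anchors, p1]
                else:
                    logger.warning("gap at t=%.0f s: no door route; left "
                                   "unfilled", t0)
            if path is not None:
                rows.append(_interpolate_on_path(
                    path, t0, t1,
                    float(track.iloc[i - 1]["z"]), float(track.iloc[i]["z"]),
                    alpha_R))
        rows.append(track.iloc[[i]])
    out = pd.concat(rows, ignore_index=True)
    return out


def _interpolate_on_path(path, t0: float, t1: float, z0: float, z1: float,
                         alpha_R: float) -> pd.DataFrame:
    """1 Hz samples on the integer grid strictly inside (t0, t1), placed by
    arc length at uniform speed along ``path``."""
    ts = np.arange(math.floor(t0) + 1, math.ceil(t1))
    ts = ts[(ts > t0) & (ts < t1)].astype(float)
    line = LineString(path)
    frac = (ts - t0) / (t1 - t0)
    pts = [line.interpolate(f * line.length) for f in frac] if line.length > 0 \
        else [Point(path[0]) for _ in frac]
    return make_track(
        ts,
        [p.x for p in pts],
        [p.y for p in pts],
        z=z0 + frac * (z1 - z0),
        interpolated=np.ones(len(ts), dtype=bool),
        cov_scale=np.full(len(ts), alpha_R),
    )


def snap_corridor(track: pd.DataFrame, plan: FloorPlan) -> pd.DataFrame:
    """Project samples lying inside a corridor polygon orthogonally onto
    that corridor's center polyline (nearest point among its segments;
    ties resolve to the earlier segment)."""
    corridors = plan.zones_of_kind("corridor")
    if not corridors or track.empty:
        return track.copy()
    out = track.copy()
    for i in out.index:
        p = Point(out.at[i, "x"], out.at[i, "y"])
        for c in corridors:
            if c.polygon.covers(p):
                q = _nearest_on_polyline(c.center_line, p)
                out.at[i, "x"], out.at[i, "y"] = q
                break
    return out


def _nearest_on_polyline(line: LineString, p: Point) -> tuple[float, float]:
    coords = list(line.coords)
    best = None
    for a, b in zip(coords, coords[1:]):
        seg = LineString([a, b])
        q = seg.interpolate(seg.project(p))
        d = p.distance(q)
        if best is None or d < best[0] - 1e-12:  # strict: ties keep earlier
            best = (d, (q.x, q.y))
    return best[1]


def preprocess(track: pd.DataFrame, plan: FloorPlan, max_gap: float = 60.0,
               alpha_R: float = 4.0) -> pd.DataFrame:
    """Full preprocessing chain: relocate forbidden samples, fill short
    gaps, snap corridor samples — exactly in this order."""
    out = relocate_forbidden(track, plan)
    out = fill_gaps(out, plan, max_gap=max_gap, alpha_R=alpha_R)
    out = snap_corridor(out, plan)
    return out


# ---------------------------------------------------------------------------
# Track I/O

def read_track_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return make_track(
        df["timestamp"], df["x_cm"], df["y_cm"],
        z=df["z_cm"] if "z_cm" in df else None,
        interpolated=df["interpolated"] if "interpolated" in df else None,
        cov_scale=df["cov_scale"] if "cov_scale" in df else None,
    )


def write_track_csv(path, track: pd.DataFrame) -> None:
    out = pd.DataFrame({
        "timestamp": track["t"], "x_cm": track["x"], "y_cm": track["y"],
        "z_cm": track["z"], "interpolated": track["interpolated"],
        "cov_scale": track["cov_scale"],
    })
    out.to_csv(path, index=False)
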