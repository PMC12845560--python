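"""Synthetic input generators with known ground truth.

Real deployments of this kind of system produce four input streams: radar
gate-energy days, bedroom light series, a floor plan, and UWB position
tracks.  The generators here emulate all four so that every pipeline stage
is testable end to end:

* radar days: per-gate folded-normal background clutter plus scheduled
  occupancy (micromovement) and activity (macromovement) bursts whose
  energy is spread over a few range gates around a slowly wandering
  target position;
* light days: lights-on/off profile consistent with a planted sleep window;
* the fixture floor plan: two rooms, a corridor with center line, a hall,
  a forbidden shaft flanking the corridor, a charging zone and three
  doors with midpoint anchors;
* UWB walks: a waypoint path routed through door anchors at constant
  nominal speed, with isotropic measurement noise, optional wall-crossing
  outliers (the NLOS artifact the constrained filter targets), scheduled
  coverage gaps and low-speed charging dwells.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .floorplan import FloorPlan, door_route, floorplan_from_dict
from .radar_energy import GateEnergyFrame, TimeSeries
from .stalta import SegmentList
from .uwb_preprocess import make_track

HOUR = 3600.0


# ---------------------------------------------------------------------------
# Radar days

@dataclass
class RadarDaySpec:
    """Study conditions for one synthetic radar day (seconds are absolute,
    07:00-22:00 daytime by default; energies on the 0-100 gate scale)."""

    seed: int = 0
    start: float = 7 * HOUR
    duration: float = 15 * HOUR
    n_gates: int = 9
    micro_background: float = 2.0   # folded-normal location per gate
    macro_background: float = 1.0
    noise_scale: float = 1.0        # folded-normal scale per gate
    # normalized C-signal increments during scheduled intervals;
    # 0.18 over a 0.02 background gives the nominal 10:1 contrast
    micro_amplitude_c: float = 0.18
    macro_amplitude_c: float = 0.15
    amplitude_jitter: float = 0.2   # relative second-to-second variation
    # a representative fairly active resident: bedroom occupied 12 h of the
    # 15 h daytime window, 4.2 h of it (35%) in non-sedentary activity.
    # Both fractions keep the elevated STA mode above the 75th percentile,
    # the regime the adaptive percentile/ECDF threshold rules address.
    occupancy: list[tuple[float, float]] = field(default_factory=lambda: [
        (8 * HOUR, 13 * HOUR), (14 * HOUR, 21 * HOUR)])
    activity: list[tuple[float, float]] = field(default_factory=lambda: [
        (8.5 * HOUR, 9.5 * HOUR), (10.5 * HOUR, 11.2 * HOUR),
        (14.5 * HOUR, 15.7 * HOUR), (17 * HOUR, 18 * HOUR),
        (19.5 * HOUR, 19.8 * HOUR)])
    missing: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        occ = SegmentList(self.occupancy)
        act = SegmentList(self.activity)
        for a, b in act.segments:
            if not any(a >= lo and b <= hi for lo, hi in occ.segments):
                raise ValueError("activity intervals must lie inside "
                                 "occupancy intervals")


def _interval_mask(times: np.ndarray,
                   intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for a, b in intervals:
        mask |= (times >= a) & (times < b)
    return mask


def gen_radar_day(spec: RadarDaySpec,
                  ) -> tuple[list[GateEnergyFrame], SegmentList, SegmentList]:
    """Generate one radar day; returns (frames, truth_occ, truth_act)."""
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration)
    times = spec.start + np.arange(n, dtype=float)
    g = spec.n_gates

    micro = np.abs(rng.normal(spec.micro_background, spec.noise_scale, (n, g)))
    macro = np.abs(rng.normal(spec.macro_background, spec.noise_scale, (n, g)))

    occ = _interval_mask(times, spec.occupancy)
    act = _interval_mask(times, spec.activity)

    # target range-gate position: slow bounded random walk
    steps = rng.integers(-1, 2, size=n)
    pos = np.clip(np.cumsum(steps) + g // 2, 0, g - 1)

    for mask, amp_c, channel in ((occ, spec.micro_amplitude_c, micro),
                                 (act, spec.macro_amplitude_c, macro)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        total = amp_c * 100.0 * g * np.clip(
            1.0 + spec.amplitude_jitter * rng.standard_normal(idx.size),
            0.0, None)
        for k, tot in zip(idx, total):
            center = pos[k]
            lo, hi = max(0, center - 1), min(g - 1, center + 1)
            weights = np.zeros(g)
            weights[lo:hi + 1] = 1.0
            weights[center] = 2.0
            weights /= weights.sum()
            channel[k] += tot * weights

    micro = np.clip(micro, 0.0, 100.0)
    macro = np.clip(macro, 0.0, 100.0)

    drop = _interval_mask(times, spec.missing)
    frames = [
        GateEnergyFrame(times[k], micro[k], macro[k], presence=int(occ[k]))
        for k in range(n) if not drop[k]
    ]
    occ_truth = SegmentList(spec.occupancy)
    act_truth = SegmentList(spec.activity)
    return frames, occ_truth, act_truth


# ---------------------------------------------------------------------------
# Light days

@dataclass
class LightDaySpec:
    """Bedroom light profile covering 18:00 through 12:00 next day."""

    seed: int = 0
    bedtime: float = 22.5 * HOUR          # light -> dark
    waketime: float = (24 + 7.5) * HOUR   # dark -> light, next morning
    on_level: float = 200.0
    off_level: float = 1.0
    noise: float = 0.5


def gen_light_day(spec: LightDaySpec) -> TimeSeries:
    rng = np.random.default_rng(spec.seed)
    start, end = 18 * HOUR, 36 * HOUR
    times = np.arange(start, end)
    dark = (times >= spec.bedtime) & (times < spec.waketime)
    vals = np.where(dark, spec.off_level, spec.on_level)
    vals = np.clip(vals + spec.noise * rng.standard_normal(len(vals)), 0, None)
    return TimeSeries(start, vals)


def gen_presence_day(visits: Sequence[tuple[float, float]],
                     start: float = 0.0, duration: float = 36 * HOUR,
                     ) -> TimeSeries:
    """Binary bathroom-presence series with planted visit intervals."""
    times = start + np.arange(int(duration), dtype=float)
    return TimeSeries(start, _interval_mask(times, visits).astype(float))


# ---------------------------------------------------------------------------
# Floor-plan fixture

def gen_floorplan_fixture() -> FloorPlan:
    """A small validated plan: two rooms and a hall joined by a corridor,
    a forbidden shaft flanking the corridor, and a charging zone.
    Coordinates in cm, origin at the lower-left."""
    payload = {
        "walls": [
            {"orientation": "horizontal", "fixed_coord": 600, "span": [0, 900]},
            {"orientation": "vertical", "fixed_coord": 0, "span": [200, 600]},
            {"orientation": "vertical", "fixed_coord": 900, "span": [200, 600]},
            # room/corridor divider with 80 cm door gaps at x=200 and x=700
            {"orientation": "horizontal", "fixed_coord": 300, "span": [0, 160]},
            {"orientation": "horizontal", "fixed_coord": 300, "span": [240, 660]},
            {"orientation": "horizontal", "fixed_coord": 300, "span": [740, 900]},
            # forbidden shaft side walls
            {"orientation": "vertical", "fixed_coord": 400, "span": [300, 600]},
            {"orientation": "vertical", "fixed_coord": 500, "span": [300, 600]},
            # corridor/hall divider with an 80 cm door gap at x=450
            {"orientation": "horizontal", "fixed_coord": 200, "span": [0, 410]},
            {"orientation": "horizontal", "fixed_coord": 200, "span": [490, 900]},
            # hall outer walls
            {"orientation": "vertical", "fixed_coord": 200, "span": [0, 200]},
            {"orientation": "vertical", "fixed_coord": 700, "span": [0, 200]},
            {"orientation": "horizontal", "fixed_coord": 0, "span": [200, 700]},
        ],
        "zones": [
            {"name": "room1", "kind": "room",
             "polygon": [[0, 300], [400, 300], [400, 600], [0, 600]]},
            {"name": "room2", "kind": "room",
             "polygon": [[500, 300], [900, 300], [900, 600], [500, 600]]},
            {"name": "corridor", "kind": "corridor",
             "polygon": [[0, 200], [900, 200], [900, 300], [0, 300]],
             "center_line": [[0, 250], [900, 250]]},
            {"name": "hall", "kind": "hall",
             "polygon": [[200, 0], [700, 0], [700, 200], [200, 200]]},
            {"name": "shaft", "kind": "forbidden",
             "polygon": [[400, 300], [500, 300], [500, 600], [400, 600]]},
            {"name": "charging", "kind": "charging",
             "polygon": [[600, 0], [700, 0], [700, 100], [600, 100]]},
        ],
        "doors": [
            {"anchor": [200, 300], "connects": ["room1", "corridor"]},
            {"anchor": [700, 300], "connects": ["room2", "corridor"]},
            {"anchor": [450, 200], "connects": ["hall", "corridor"]},
        ],
    }
    return floorplan_from_dict(payload)


# ---------------------------------------------------------------------------
# UWB walks

@dataclass
class WalkSpec:
    """One synthetic tagged walk on the fixture plan."""

    seed: int = 0
    start_time: float = 8 * HOUR
    waypoints: list[tuple[float, float]] = field(default_factory=lambda: [
        (200.0, 450.0), (650.0, 50.0), (700.0, 450.0), (200.0, 450.0)])
    dwells: Optional[list[float]] = None  # seconds paused at each waypoint
    speed: float = 50.0                   # nominal walking speed, cm/s
    sigma: float = 10.0                   # isotropic measurement noise, cm
    outlier_rate: float = 0.0
    outlier_magnitude: float = 40.0       # cm beyond the crossed wall
    outlier_wall_range: float = 100.0     # only walls this close produce
    door_pause_s: float = 2.0             # natural slow-down at doorways
    gaps: list[tuple[float, float]] = field(default_factory=list)
    # gap intervals in seconds relative to start_time

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.dwells is not None and len(self.dwells) != len(self.waypoints):
            raise ValueError("dwells must align with waypoints")


def _route_path(spec: WalkSpec, plan: FloorPlan) -> list[tuple[float, float]]:
    path = [spec.waypoints[0]]
    for a, b in zip(spec.waypoints, spec.waypoints[1:]):
        za = plan.zone_containing(a)
        zb = plan.zone_containing(b)
        if za is None or zb is None:
            raise ValueError(f"waypoint outside walkable zones: {a} or {b}")
        anchors = door_route(za.name, zb.name, plan)
        if anchors is None:
            raise ValueError(f"waypoints not connected via doors: "
                             f"{za.name} -> {zb.name}")
        path.extend(anchors)
        path.append(b)
    path = _expand_door_clearances(path, plan)
    return _via_corridor_center(path, plan)


DOOR_CLEARANCE_CM = 60.0


def _expand_door_clearances(path: list[tuple[float, float]],
                            plan: FloorPlan) -> list[tuple[float, float]]:
    """People pass doorways perpendicular to the wall: surround each door
    anchor with clearance points straight through the opening, so the
    crossing of the wall plane happens at the doorway itself."""
    anchors = {tuple(d.anchor) for d in plan.doors}
    out: list[tuple[float, float]] = []
    for i, p in enumerate(path):
        if 0 < i < len(path) - 1 and tuple(p) in anchors:
            prev = out[-1] if out else path[i - 1]
            nxt = path[i + 1]
            for axis in (1, 0):  # doors sit on horizontal walls first
                d_prev = prev[axis] - p[axis]
                d_next = nxt[axis] - p[axis]
                if d_prev == 0 and d_next == 0:
                    continue
                near = list(p)
                far = list(p)
                sign_prev = math.copysign(1.0, d_prev) if d_prev else \
                    -math.copysign(1.0, d_next)
                near[axis] = p[axis] + sign_prev * min(
                    DOOR_CLEARANCE_CM, abs(d_prev) or DOOR_CLEARANCE_CM)
                far[axis] = p[axis] - sign_prev * min(
                    DOOR_CLEARANCE_CM, abs(d_next) or DOOR_CLEARANCE_CM)
                _append(out, tuple(near))
                _append(out, tuple(p))
                _append(out, tuple(far))
                break
        else:
            _append(out, tuple(p))
    return out


def _append(path: list[tuple[float, float]], p: tuple[float, float]) -> None:
    if not path or math.dist(path[-1], p) > 1e-9:
        path.append(p)


def _via_corridor_center(path: list[tuple[float, float]],
                         plan: FloorPlan) -> list[tuple[float, float]]:
    """Route corridor spans along the center line: when two consecutive
    path points lie inside the same corridor, walk via their center-line
    feet instead of cutting diagonally across the corridor."""
    from .uwb_preprocess import _nearest_on_polyline
    from shapely.geometry import Point

    def corridor_of(p: tuple[float, float]):
        for z in plan.zones_of_kind("corridor"):
            if z.polygon.covers(Point(p)):
                return z
        return None

    out = [path[0]]
    for a, b in zip(path, path[1:]):
        ca, cb = corridor_of(a), corridor_of(b)
        if ca is not None and cb is not None and ca.name == cb.name:
            fa = _nearest_on_polyline(ca.center_line, Point(a))
            fb = _nearest_on_polyline(ca.center_line, Point(b))
            _append(out, fa)
            _append(out, fb)
        _append(out, b)
    return out


def gen_uwb_track(spec: WalkSpec, plan: FloorPlan,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (samples, truth) for a waypoint walk.

    The ground-truth path goes waypoint to waypoint through door anchors
    at the nominal speed (pausing ``dwells`` seconds at each waypoint) and
    never violates the plan; samples add isotropic noise, wall-crossing
    outliers, and scheduled coverage gaps.
    """
    rng = np.random.default_rng(spec.seed)
    dwells = spec.dwells or [0.0] * len(spec.waypoints)

    # 1 Hz ground truth: walk legs at constant speed, pauses at waypoints
    truth_xy: list[tuple[float, float]] = []
    path = _route_path(spec, plan)
    # walk the full routed path; pause whenever a waypoint is reached
    pending = list(path)
    cur = pending.pop(0)
    truth_xy.extend([cur] * (1 + int(dwells[0])))
    wp_index = 1
    carry = 0.0
    while pending:
        nxt = pending.pop(0)
        leg = math.dist(cur, nxt)
        t_leg = leg / spec.speed
        n_steps = int(math.floor(t_leg + carry))
        carry = t_leg + carry - n_steps
        for s in range(1, n_steps + 1):
            f = min(1.0, s * spec.speed / leg) if leg > 0 else 1.0
            truth_xy.append((cur[0] + f * (nxt[0] - cur[0]),
                             cur[1] + f * (nxt[1] - cur[1])))
        cur = nxt
        if wp_index < len(spec.waypoints) and \
                math.dist(cur, spec.waypoints[wp_index]) < 1e-9:
            dwell = int(dwells[wp_index])
            truth_xy.extend([cur] * dwell)
            wp_index += 1
        else:  # a door anchor: brief pause while passing the doorway
            truth_xy.extend([cur] * int(spec.door_pause_s))
    if not truth_xy:
        truth_xy = [path[0]]

    n = len(truth_xy)
    t = spec.start_time + np.arange(n, dtype=float)
    txy = np.array(truth_xy, dtype=float)
    truth = pd.DataFrame({"t": t, "x": txy[:, 0], "y": txy[:, 1]})

    xy = txy + rng.normal(0.0, spec.sigma, size=(n, 2))
    z = 100.0 + rng.normal(0.0, 2.0, size=n)

    outliers = rng.random(n) < spec.outlier_rate
    displaced_any = np.zeros(n, dtype=bool)
    for k in np.flatnonzero(outliers):
        displaced = _displace_across_nearest_wall(
            tuple(txy[k]), plan, spec.outlier_magnitude,
            spec.outlier_wall_range)
        if displaced is not None:
            xy[k] = displaced
            displaced_any[k] = True
    outliers &= displaced_any

    rel = t - spec.start_time
    keep = ~_interval_mask(rel, spec.gaps)
    track = make_track(t[keep], xy[keep, 0], xy[keep, 1], z=z[keep])
    track.attrs["outlier_indices"] = np.flatnonzero(outliers & keep).tolist()
    return track, truth


def _displace_across_nearest_wall(p: tuple[float, float], plan: FloorPlan,
                                  magnitude: float, wall_range: float,
                                  ) -> Optional[tuple[float, float]]:
    """Move p to ``magnitude`` cm beyond its nearest wall (perpendicular
    projection within the wall span); None when no wall faces the point
    within ``wall_range`` cm (multipath ghosts appear near walls)."""
    best = None
    for wall in plan.walls:
        axis = 0 if wall.orientation == "vertical" else 1
        other = 1 - axis
        lo, hi = wall.span
        if not (lo <= p[other] <= hi):
            continue
        d = abs(p[axis] - wall.fixed_coord)
        if d == 0.0 or d > wall_range:
            continue
        if best is None or d < best[0]:
            best = (d, wall, axis)
    if best is None:
        return None
    _, wall, axis = best
    out = list(p)
    side = math.copysign(1.0, wall.fixed_coord - p[axis])
    out[axis] = wall.fixed_coord + side * magnitude
    return (out[0], out[1])
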