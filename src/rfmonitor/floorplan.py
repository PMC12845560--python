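"""Indoor floor-plan model and geometric predicates.

The map is a planar, axis-aligned description in centimetres: walls are
horizontal/vertical line segments, zones (rooms, corridors, hall,
forbidden and charging regions) are simple polygons, and doors are anchor
points at doorway midpoints connecting two zones.  Doors induce the zone
adjacency graph used to route physically feasible paths.  Oblique walls
are rejected at load time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import networkx as nx
from shapely.geometry import LineString, Point, Polygon

PARAM_TOL = 1e-9


@dataclass
class Wall:
    """Axis-aligned wall segment: orientation, fixed coordinate, span."""

    orientation: Literal["horizontal", "vertical"]
    fixed_coord: float
    span: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.span
        if not lo < hi:
            raise ValueError("wall span must satisfy lo < hi")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("walls must be axis-aligned "
                             "(orientation horizontal|vertical)")

    @property
    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        lo, hi = self.span
        if self.orientation == "vertical":   # constrains x
            return (self.fixed_coord, lo), (self.fixed_coord, hi)
        return (lo, self.fixed_coord), (hi, self.fixed_coord)


@dataclass
class Zone:
    name: str
    kind: Literal["room", "corridor", "hall", "forbidden", "charging"]
    polygon: Polygon
    center_line: Optional[LineString] = None

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValueError(f"zone {self.name}: polygon must be simple")
        if self.kind == "corridor" and self.center_line is None:
            raise ValueError(f"corridor {self.name} needs a center_line")


@dataclass
class Door:
    anchor: tuple[float, float]
    connects: tuple[str, str]


@dataclass
class FloorPlan:
    walls: list[Wall]
    zones: list[Zone]
    doors: list[Door]
    adjacency: nx.Graph = field(init=False)

    def __post_init__(self) -> None:
        names = {z.name for z in self.zones}
        g = nx.Graph()
        g.add_nodes_from(names)
        for d in self.doors:
            a, b = d.connects
            if a not in names or b not in names:
                raise ValueError(f"door connects unknown zone: {d.connects}")
            pa, pb = self.zone(a).polygon, self.zone(b).polygon
            pt = Point(d.anchor)
            if pt.distance(pa.boundary) > 1.0 or pt.distance(pb.boundary) > 1.0:
                raise ValueError(f"door anchor {d.anchor} is not on the shared "
                                 f"boundary of {a} and {b}")
            # keep the shortest door if a pair is multiply connected
            if g.has_edge(a, b):
                continue
            g.add_edge(a, b, door=d)
        self.adjacency = g

    def zone(self, name: str) -> Zone:
        for z in self.zones:
            if z.name == name:
                return z
        raise KeyError(name)

    def zones_of_kind(self, kind: str) -> list[Zone]:
        return [z for z in self.zones if z.kind == kind]

    def zone_containing(self, p: tuple[float, float],
                        kinds: Sequence[str] = ("room", "corridor", "hall"),
                        ) -> Optional[Zone]:
        pt = Point(p)
        for z in self.zones:
            if z.kind in kinds and z.polygon.covers(pt):
                return z
        return None


# ---------------------------------------------------------------------------
# Geometric predicates

def first_wall_crossing(p: tuple[float, float], q: tuple[float, float],
                        plan: FloorPlan) -> list[Wall]:
    """Wall(s) crossed first by the open segment (p, q).

    Returns the wall(s) with the smallest crossing parameter along p->q
    (possibly one horizontal and one vertical wall crossed at the same
    parameter, e.g. at a corner), or an empty list when no wall is crossed.
    A segment that merely starts or ends on a wall does not cross it.
    """
    px, py = p
    qx, qy = q
    hits: list[tuple[float, Wall]] = []
    for wall in plan.walls:
        if wall.orientation == "vertical":
            a0, a1, b0, b1, w = px, qx, py, qy, wall.fixed_coord
        else:
            a0, a1, b0, b1, w = py, qy, px, qx, wall.fixed_coord
        d0, d1 = a0 - w, a1 - w
        if d0 == 0.0 or d1 == 0.0 or (d0 > 0) == (d1 > 0):
            continue  # no strict sign change: touch or same side
        t = d0 / (d0 - d1)
        other = b0 + t * (b1 - b0)
        lo, hi = wall.span
        if lo - PARAM_TOL <= other <= hi + PARAM_TOL:
            hits.append((t, wall))
    if not hits:
        return []
    tmin = min(t for t, _ in hits)
    return [w for t, w in hits if t <= tmin + PARAM_TOL]


def feasible_target(p_prev: tuple[float, float], p_new: tuple[float, float],
                    wall: Wall, offset: float) -> tuple[float, float]:
    """Feasible target position for a point that crossed ``wall``.

    Keeps the unconstrained coordinate of p_new and replaces the violating
    coordinate by the wall's fixed coordinate shifted ``offset`` cm toward
    p_prev's side.  If p_prev sits exactly on the wall, the offset is
    applied away from p_new's side.
    """
    axis = 0 if wall.orientation == "vertical" else 1
    w = wall.fixed_coord
    side = math.copysign(1.0, p_prev[axis] - w) if p_prev[axis] != w else \
        -math.copysign(1.0, p_new[axis] - w) if p_new[axis] != w else 1.0
    tgt = list(p_new)
    tgt[axis] = w + side * offset
    return (tgt[0], tgt[1])


@dataclass
class Relocation:
    point: tuple[float, float]
    axis_aligned: bool  # False when only a Euclidean fallback was possible


def project_to_corridor(p: tuple[float, float], plan: FloorPlan) -> Relocation:
    """Nearest corridor point reachable by a purely vertical or purely
    horizontal move; ties broken toward the smaller displacement, then
    horizontal.  Falls back (flagged) to the Euclidean-nearest corridor
    point when no axis-aligned move reaches a corridor."""
    corridors = plan.zones_of_kind("corridor")
    if not corridors:
        raise ValueError("plan has no corridors")
    pt = Point(p)
    if any(c.polygon.covers(pt) for c in corridors):
        return Relocation(p, True)
    minx, miny, maxx, maxy = _plan_bounds(plan)
    reach = max(maxx - minx, maxy - miny) + 1.0
    h_line = LineString([(p[0] - reach, p[1]), (p[0] + reach, p[1])])
    v_line = LineString([(p[0], p[1] - reach), (p[0], p[1] + reach)])
    best: Optional[tuple[float, int, tuple[float, float]]] = None
    for priority, line in ((0, h_line), (1, v_line)):  # horizontal wins ties
        for c in corridors:
            inter = line.intersection(c.polygon)
            if inter.is_empty:
                continue
            cand = nearest_on(inter, pt)
            d = pt.distance(Point(cand))
            key = (d, priority, cand)
            if best is None or key[:2] < best[:2]:
                best = key
    if best is not None:
        return Relocation(best[2], True)
    # no axis-aligned route: Euclidean projection onto the nearest corridor
    cand = min((nearest_on(c.polygon.exterior, pt) for c in corridors),
               key=lambda q: pt.distance(Point(q)))
    return Relocation(cand, False)


def nearest_on(geom, pt: Point) -> tuple[float, float]:
    """Nearest point of a shapely geometry to ``pt``."""
    q = geom.interpolate(geom.project(pt)) if hasattr(geom, "project") \
        else min((g.interpolate(g.project(pt)) for g in geom.geoms),
                 key=lambda g: g.distance(pt))
    return (q.x, q.y)


def door_route(zone_a: str, zone_b: str, plan: FloorPlan,
               ) -> Optional[list[tuple[float, float]]]:
    """Ordered door anchors along the shortest zone path from a to b.

    Shortest means fewest doors; ties are broken by the total Euclidean
    distance between consecutive anchors.  Returns [] when a == b and
    None when the zones are disconnected.
    """
    if zone_a == zone_b:
        return []
    g = plan.adjacency
    if zone_a not in g or zone_b not in g or not nx.has_path(g, zone_a, zone_b):
        return None

    def anchors_of(path: list[str]) -> list[tuple[float, float]]:
        return [g.edges[u, v]["door"].anchor for u, v in zip(path, path[1:])]

    def chain_length(anchors: list[tuple[float, float]]) -> float:
        return sum(math.dist(a, b) for a, b in zip(anchors, anchors[1:]))

    best = min(nx.all_shortest_paths(g, zone_a, zone_b),
               key=lambda path: chain_length(anchors_of(path)))
    return anchors_of(best)


def _plan_bounds(plan: FloorPlan) -> tuple[float, float, float, float]:
    xs: list[float] = []
    ys: list[float] = []
    for z in plan.zones:
        minx, miny, maxx, maxy = z.polygon.bounds
        xs += [minx, maxx]
        ys += [miny, maxy]
    return min(xs), min(ys), max(xs), max(ys)


# ---------------------------------------------------------------------------
# JSON loader / writer

def load_floorplan(path) -> FloorPlan:
    with open(path) as fh:
        payload = json.load(fh)
    return floorplan_from_dict(payload)


def floorplan_from_dict(payload: dict) -> FloorPlan:
    walls = [Wall(w["orientation"], float(w["fixed_coord"]),
                  (float(w["span"][0]), float(w["span"][1])))
             for w in payload["walls"]]
    zones = []
    for z in payload["zones"]:
        poly = Polygon(z["polygon"])
        if poly.exterior.is_ccw is False:
            poly = Polygon(list(z["polygon"])[::-1])
        center = LineString(z["center_line"]) if z.get("center_line") else None
        zones.append(Zone(z["name"], z["kind"], poly, center))
    doors = [Door(tuple(d["anchor"]), tuple(d["connects"]))
             for d in payload["doors"]]
    return FloorPlan(walls, zones, doors)


def floorplan_to_dict(plan: FloorPlan) -> dict:
    return {
        "walls": [{"orientation": w.orientation, "fixed_coord": w.fixed_coord,
                   "span": list(w.span)} for w in plan.walls],
        "zones": [{
            "name": z.name, "kind": z.kind,
            "polygon": [list(c) for c in z.polygon.exterior.coords[:-1]],
            "center_line": ([list(c) for c in z.center_line.coords]
                            if z.center_line is not None else None),
        } for z in plan.zones],
        "doors": [{"anchor": list(d.anchor), "connects": list(d.connects)}
                  for d in plan.doors],
    }


def save_floorplan(path, plan: FloorPlan) -> None:
    with open(path, "w") as fh:
        json.dump(floorplan_to_dict(plan), fh, indent=2)
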