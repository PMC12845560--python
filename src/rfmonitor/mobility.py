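"""Daily gait and mobility indicators from filtered trajectories.

Instantaneous speed is v(t) = ||(vx, vy)|| converted to m/s.  Walking
samples are those with v above the low-speed threshold (0.2 m/s, shared
with the active/sedentary split).  Habitual gait speed is the median of v
over walking samples and maximum gait speed its 95th percentile; daily
distance integrates consecutive displacements between walking samples.
Time budgets accumulate the actual inter-sample intervals inside the
analysis window (default 08:00-22:00): intervals spanning a gap longer
than 5 min count toward no total, and stationary runs of at least 5 min
inside the charging zone are excluded from sedentary and monitored time
(device charging, not inactivity).  Each interval [t_i, t_{i+1}) is
labeled by the state at t_i.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .floorplan import FloorPlan

logger = logging.getLogger(__name__)

CM_PER_M = 100.0


@dataclass
class MobilitySummary:
    habitual_speed: Optional[float]   # m/s; None when no walking samples
    max_speed_p95: Optional[float]    # m/s
    distance: float                   # m
    active_time: float                # s
    sedentary_time: float             # s
    monitored_time: float             # s


def speed_series(traj: pd.DataFrame) -> np.ndarray:
    """Per-sample speed ||(vx, vy)|| in m/s."""
    v = np.hypot(traj["vx"].to_numpy(dtype=float),
                 traj["vy"].to_numpy(dtype=float))
    return v / CM_PER_M


def gait_metrics(v: np.ndarray, walking_mask: np.ndarray,
                 ) -> tuple[Optional[float], Optional[float]]:
    """(habitual, maximum) gait speed: median and 95th percentile of v over
    walking samples; (None, None) when the mask is empty."""
    w = np.asarray(v, dtype=float)[np.asarray(walking_mask, dtype=bool)]
    if w.size == 0:
        logger.info("no walking samples: gait speeds undefined")
        return None, None
    return float(np.median(w)), float(np.percentile(w, 95.0))


def walked_distance(traj: pd.DataFrame, threshold: float = 0.2,
                    max_dt: float = 300.0) -> float:
    """Walked distance (m): sum of Euclidean displacements between
    consecutive samples whose endpoint speeds both exceed ``threshold``
    (m/s) and whose spacing does not exceed ``max_dt`` seconds."""
    if len(traj) < 2:
        return 0.0
    t = traj["t"].to_numpy(dtype=float)
    xy = traj[["x", "y"]].to_numpy(dtype=float)
    v = speed_series(traj)
    dt = np.diff(t)
    steps = np.hypot(*(np.diff(xy, axis=0).T)) / CM_PER_M
    ok = (v[:-1] > threshold) & (v[1:] > threshold) & (dt <= max_dt)
    return float(np.sum(steps[ok]))


def time_budget(traj: pd.DataFrame, plan: Optional[FloorPlan],
                window: tuple[float, float],
                speed_threshold: float = 0.2,
                gap_limit: float = 300.0,
                charging_min: float = 300.0,
                ) -> tuple[float, float, float]:
    """(active, sedentary, monitored) seconds inside ``window``.

    Durations come from the actual inter-sample intervals; an interval
    longer than ``gap_limit`` is missing coverage and contributes nothing.
    Runs of consecutive low-speed samples inside the charging zone whose
    covered duration reaches ``charging_min`` are excluded from sedentary
    and monitored time.  Monitored time = active + sedentary.
    """
    lo, hi = window
    sel = traj[(traj["t"] >= lo) & (traj["t"] < hi)]
    if len(sel) < 2:
        return 0.0, 0.0, 0.0
    t = sel["t"].to_numpy(dtype=float)
    v = speed_series(sel)
    xy = sel[["x", "y"]].to_numpy(dtype=float)
    dt = np.diff(t)
    valid = dt <= gap_limit
    active_state = v[:-1] > speed_threshold

    charging_excluded = np.zeros(len(dt), dtype=bool)
    charging = plan.zones_of_kind("charging") if plan is not None else []
    if charging:
        in_charge = np.array([
            (v[i] < speed_threshold)
            and any(z.polygon.covers(Point(xy[i])) for z in charging)
            for i in range(len(sel))
        ])
        # maximal runs of charging-candidate start samples
        i = 0
        while i < len(dt):
            if in_charge[i]:
                j = i
                while j < len(dt) and in_charge[j]:
                    j += 1
                run_duration = float(np.sum(dt[i:j][valid[i:j]]))
                if run_duration >= charging_min:
                    charging_excluded[i:j] = True
                i = j
            else:
                i += 1

    keep = valid & ~charging_excluded
    active = float(np.sum(dt[keep & active_state]))
    sedentary = float(np.sum(dt[keep & ~active_state]))
    return active, sedentary, active + sedentary


def mobility_summary(traj: pd.DataFrame, plan: Optional[FloorPlan],
                     window: tuple[float, float],
                     speed_threshold: float = 0.2,
                     gap_limit: float = 300.0,
                     charging_min: float = 300.0) -> MobilitySummary:
    """All daily mobility indicators over the analysis window."""
    lo, hi = window
    sel = traj[(traj["t"] >= lo) & (traj["t"] < hi)].reset_index(drop=True)
    v = speed_series(sel)
    habitual, maximum = gait_metrics(v, v > speed_threshold)
    dist = walked_distance(sel, threshold=speed_threshold, max_dt=gap_limit)
    active, sedentary, monitored = time_budget(
        sel, plan, window, speed_threshold=speed_threshold,
        gap_limit=gap_limit, charging_min=charging_min)
    return MobilitySummary(habitual, maximum, dist, active, sedentary,
                           monitored)


def write_mobility_summary(path, summary: MobilitySummary,
                           extra: Optional[dict] = None) -> None:
    payload = dict(extra or {})
    payload.update(
        habitual_gait_speed_m_s=summary.habitual_speed,
        max_gait_speed_p95_m_s=summary.max_speed_p95,
        total_distance_m=summary.distance,
        active_time_s=summary.active_time,
        sedentary_time_s=summary.sedentary_time,
        monitored_time_s=summary.monitored_time,
    )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
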