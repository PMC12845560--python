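"""End-to-end day processing: radar occupancy analytics and UWB mobility
metrics composed into one JSON report.

A day directory may contain any subset of:

* ``bedroom_radar.csv``      — gate-energy frames (timestamp, presence,
  micro_g1..gN, macro_g1..gN)
* ``bathroom_presence.csv``  — ``timestamp,presence`` binary series
* ``light.csv``              — ``timestamp,value`` light-intensity series
* ``uwb_track.csv``          — raw UWB samples

Modalities are processed independently; a missing file yields a partial
report, never an error.  The report always embeds the exact thresholds and
configuration used, plus per-stage counters, for reproducibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import mobility, occupancy, radar_energy, stalta, uwb_preprocess
from .config import RunConfig
from .floorplan import FloorPlan
from .kalman import filter_track

logger = logging.getLogger(__name__)


def _day_window(hours: tuple[float, float], day_start: float,
                ) -> tuple[float, float]:
    base = day_start - (day_start % 86400.0)
    return base + hours[0] * 3600.0, base + hours[1] * 3600.0


def run_pipeline(day_dir, plan: Optional[FloorPlan],
                 config: Optional[RunConfig] = None) -> dict:
    """Process one day directory; returns the report dict."""
    config = config or RunConfig()
    day_dir = Path(day_dir)
    report: dict = {"config": config.model_dump(), "errors": [], "audit": {}}

    radar_path = day_dir / "bedroom_radar.csv"
    if radar_path.exists():
        try:
            report["radar"] = _radar_section(radar_path, config)
        except Exception as exc:  # malformed file: collect, continue
            report["errors"].append(f"bedroom_radar.csv: {exc}")
    else:
        report["radar"] = None

    presence_path = day_dir / "bathroom_presence.csv"
    light_path = day_dir / "light.csv"
    if presence_path.exists():
        try:
            report["visits"] = _visit_section(presence_path, light_path, config)
        except Exception as exc:
            report["errors"].append(f"bathroom_presence.csv: {exc}")
    else:
        report["visits"] = None

    uwb_path = day_dir / "uwb_track.csv"
    if uwb_path.exists():
        try:
            report["mobility"] = _mobility_section(uwb_path, plan, config)
        except Exception as exc:
            report["errors"].append(f"uwb_track.csv: {exc}")
    else:
        report["mobility"] = None

    return report


def _radar_section(path, config: RunConfig) -> dict:
    frames = radar_energy.read_day_file(path)
    micro = radar_energy.aggregate_gates(frames, "micro")
    macro = radar_energy.aggregate_gates(frames, "macro")
    window = _day_window(config.windows.daytime, micro.start_time)
    occ_res = stalta.detect_day(micro, config.stalta, window=window)
    act_res = stalta.detect_day(macro, config.stalta, window=window)
    summary = occupancy.occupancy_summary(
        occ_res.segments, act_res.segments, window)
    return {
        "excluded_day": occ_res.excluded or act_res.excluded,
        "occupancy_thresholds": _thr(occ_res.thresholds),
        "activity_thresholds": _thr(act_res.thresholds),
        "occupancy_segments": occ_res.segments.segments,
        "activity_segments": act_res.segments.segments,
        "pct_daytime_in_bedroom": summary.pct_daytime_in_bedroom,
        "pct_occupied_nonsedentary": summary.pct_occupied_nonsedentary,
        "nonsedentary_undefined": summary.undefined_nonsedentary,
    }


def _visit_section(presence_path, light_path, config: RunConfig) -> dict:
    df = pd.read_csv(presence_path)
    binned = radar_energy.bin_to_1hz(
        zip(df["timestamp"].to_numpy(), df["presence"].to_numpy()))
    if light_path and Path(light_path).exists():
        ldf = pd.read_csv(light_path)
        light = radar_energy.bin_to_1hz(
            zip(ldf["timestamp"].to_numpy(), ldf["value"].to_numpy()))
        sleep = occupancy.estimate_sleep_window(
            light, config.thresholds.dark_threshold,
            sustain_s=int(config.thresholds.sleep_sustain_s))
    else:
        sleep = occupancy.SleepWindow(None, None)
    counts = occupancy.count_bathroom_visits(
        binned, sleep, min_duration=config.thresholds.min_visit_s)
    return {
        "bedtime": sleep.bedtime, "waketime": sleep.waketime,
        "visits": len(counts.visits), "nocturia": counts.nocturia,
        "daytime": counts.daytime,
        "straddles_waketime": counts.straddles_waketime,
    }


def _mobility_section(path, plan: Optional[FloorPlan],
                      config: RunConfig) -> dict:
    raw = uwb_preprocess.read_track_csv(path)
    if plan is not None:
        track = uwb_preprocess.preprocess(
            raw, plan, max_gap=config.thresholds.max_gap_fill_s,
            alpha_R=config.kf.alpha_R)
    else:
        track = raw
    result = filter_track(track, plan, config.kf,
                          gap_split=config.thresholds.max_gap_fill_s)
    window = _day_window(config.windows.metrics,
                         float(track["t"].iloc[0]) if len(track) else 0.0)
    summary = mobility.mobility_summary(
        result.states, plan, window,
        speed_threshold=config.thresholds.speed_threshold_m_s,
        gap_limit=config.thresholds.metrics_gap_s,
        charging_min=config.thresholds.charging_min_s)
    return {
        "n_samples": int(len(track)),
        "n_interpolated": int(track["interpolated"].sum()) if len(track) else 0,
        "n_constrained_updates": result.n_constrained,
        "habitual_gait_speed_m_s": summary.habitual_speed,
        "max_gait_speed_p95_m_s": summary.max_speed_p95,
        "total_distance_m": summary.distance,
        "active_time_s": summary.active_time,
        "sedentary_time_s": summary.sedentary_time,
        "monitored_time_s": summary.monitored_time,
    }


def _thr(t: stalta.ThresholdSet) -> dict:
    return {"sigma1": t.sigma1, "sigma2": t.sigma2, "sigma3": t.sigma3,
            "provenance": sorted(t.provenance)}


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
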