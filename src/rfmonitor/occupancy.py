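"""Occupancy analytics: bathroom visits, nocturia, bedroom occupancy and
non-sedentary fractions, and the fixed-baseline diagnostic comparison.

The sleep window is estimated from the bedroom light-intensity signal:
bedtime is the last light-to-dark transition between 18:00 and 24:00
followed by at least 60 min of sustained darkness; wake time is the first
dark-to-light transition between 03:00 and 12:00 followed by at least
60 min of sustained light.  Bathroom presence runs of at least 30 s count
as visits; a visit whose start lies inside the sleep window is a nocturia
episode.  All interval logic uses half-open [start, end) seconds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .radar_energy import TimeSeries
from .stalta import SegmentList

logger = logging.getLogger(__name__)

DAY_S = 86_400.0


@dataclass
class SleepWindow:
    """Bedtime and next-morning wake time, absolute epoch seconds.

    Either endpoint is None when no qualifying light transition exists.
    """

    bedtime: Optional[float]
    waketime: Optional[float]


@dataclass
class VisitCounts:
    nocturia: int
    daytime: int
    visits: list[tuple[float, float]] = field(default_factory=list)
    straddles_waketime: bool = False  # a visit started asleep, ended awake


@dataclass
class OccupancySummary:
    pct_daytime_in_bedroom: float
    pct_occupied_nonsedentary: float
    undefined_nonsedentary: bool = False  # no occupied time in the window


@dataclass
class DiagnosticComparison:
    delta_t_occ: float  # minutes, signed: detected minus reference ON-time
    n_trans: int        # ON<->OFF transitions of the mask inside the window


def _tod_hours(t: float) -> float:
    return (t % DAY_S) / 3600.0


def estimate_sleep_window(
    light: TimeSeries,
    dark_threshold: float,
    sustain_s: int = 3600,
    bed_range: tuple[float, float] = (18.0, 24.0),
    wake_range: tuple[float, float] = (3.0, 12.0),
) -> SleepWindow:
    """Derive the sleep window from a 1 Hz light-intensity series.

    A transition qualifies only when the new state is sustained for
    ``sustain_s`` seconds entirely inside the record.
    """
    dark = np.asarray(light.values, dtype=float) < dark_threshold
    n = len(dark)
    times = light.times
    to_dark = np.flatnonzero(~dark[:-1] & dark[1:]) + 1
    to_light = np.flatnonzero(dark[:-1] & ~dark[1:]) + 1

    def sustained(idx: int, state: bool) -> bool:
        if idx + sustain_s > n:
            return False
        return bool(np.all(dark[idx:idx + sustain_s] == state))

    bedtime = None
    for idx in to_dark:
        if bed_range[0] <= _tod_hours(times[idx]) < bed_range[1] and sustained(idx, True):
            bedtime = float(times[idx])  # keep the last qualifying one
    waketime = None
    for idx in to_light:
        if wake_range[0] <= _tod_hours(times[idx]) < wake_range[1] and sustained(idx, False):
            waketime = float(times[idx])
            break  # first qualifying one
    return SleepWindow(bedtime, waketime)


def count_bathroom_visits(
    presence: TimeSeries,
    sleep: SleepWindow,
    min_duration: float = 30.0,
) -> VisitCounts:
    """Count bathroom visits and split them into nocturia vs daytime.

    Maximal runs of presence == 1 lasting at least ``min_duration`` seconds
    are visits; assignment to nocturia uses the visit *start* time.
    Missing presence samples are treated as absence (logged).
    """
    vals = np.asarray(presence.values, dtype=float)
    n_missing = int(np.count_nonzero(np.isnan(vals)))
    if n_missing:
        logger.info("presence series: %d missing samples treated as absence",
                    n_missing)
    present = np.nan_to_num(vals, nan=0.0) > 0.5
    runs = SegmentList.from_mask(present, presence.start_time)
    visits = [(a, b) for a, b in runs.segments if b - a >= min_duration]
    nocturia = daytime = 0
    straddle = False
    bed, wake = sleep.bedtime, sleep.waketime
    for a, b in visits:
        asleep = bed is not None and wake is not None and bed <= a < wake
        if asleep:
            nocturia += 1
            if b > wake:
                straddle = True
        else:
            daytime += 1
    return VisitCounts(nocturia, daytime, visits, straddle)


def occupancy_summary(
    occ: SegmentList,
    act: SegmentList,
    daytime: tuple[float, float],
) -> OccupancySummary:
    """Bedroom-occupancy fraction of daytime and non-sedentary fraction of
    occupied time, both as percentages over the given daytime interval."""
    lo, hi = daytime
    occ_c = occ.clip(lo, hi)
    act_c = act.clip(lo, hi)
    day_len = hi - lo
    t_occ = occ_c.total_duration()
    pct_bedroom = 100.0 * t_occ / day_len if day_len > 0 else 0.0
    if t_occ <= 0:
        return OccupancySummary(pct_bedroom, 0.0, undefined_nonsedentary=True)
    t_act = act_c.intersect(occ_c).total_duration()
    return OccupancySummary(pct_bedroom, 100.0 * t_act / t_occ)


def compare_to_reference(
    mask: SegmentList,
    ref: SegmentList,
    window: tuple[float, float],
) -> DiagnosticComparison:
    """Diagnostics of a segmentation against a reference annotation:
    signed occupied-time deviation (minutes) and the transition count of
    the detected mask inside the window."""
    lo, hi = window
    mask_c = mask.clip(lo, hi)
    ref_c = ref.clip(lo, hi)
    delta_min = (mask_c.total_duration() - ref_c.total_duration()) / 60.0
    n_trans = 0
    for a, b in mask_c.segments:
        if a > lo:
            n_trans += 1
        if b < hi:
            n_trans += 1
    return DiagnosticComparison(delta_min, n_trans)


def write_occupancy_report(path, *, visits: Optional[VisitCounts] = None,
                           summary: Optional[OccupancySummary] = None,
                           diagnostic: Optional[DiagnosticComparison] = None,
                           extra: Optional[dict] = None) -> None:
    payload: dict = dict(extra or {})
    if visits is not None:
        payload.update(visits=len(visits.visits), nocturia=visits.nocturia,
                       daytime=visits.daytime)
    if summary is not None:
        payload.update(pct_bedroom=summary.pct_daytime_in_bedroom,
                       pct_nonsedentary=summary.pct_occupied_nonsedentary,
                       nonsedentary_undefined=summary.undefined_nonsedentary)
    if diagnostic is not None:
        payload.update(delta_t_occ=diagnostic.delta_t_occ,
                       n_trans=diagnostic.n_trans)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
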