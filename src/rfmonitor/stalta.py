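"""Adaptive STA/LTA event detector for aggregated radar energy.

The detector compares a short forward moving average (STA, window T1) with
a long backward moving average (LTA, window T2) of the normalized energy
C(k) and segments the day with a two-threshold hysteresis state machine:

    activate   when STA > sigma1 and STA/LTA > sigma2
    deactivate when STA < sigma3 and STA/LTA < sigma2

The three thresholds adapt per day and per radar unit from the day's own
STA statistics: sigma1 is the 75th STA percentile, sigma3 comes from a
relative-slope rule on the STA ECDF (first value where the ECDF derivative
drops below a fraction alpha of its peak, falling back to the 15th
percentile), and sigma2 is a CFAR-style percentile of the background
STA/LTA ratio at false-alarm rate PFA, computed on low-energy samples with
guard bands around candidate activity, and clipped to a bounded range.
Percentiles use linear interpolation between closest order statistics
throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import StaLtaConfig
from .radar_energy import EnergySeries, EmptySeriesError, TimeSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Segment container

@dataclass
class SegmentList:
    """Disjoint, sorted, half-open [start, end) intervals in seconds.

    When built from a per-second mask, the grid (start_time, n) is retained
    so the boolean mask can be recovered.
    """

    segments: list[tuple[float, float]] = field(default_factory=list)
    grid_start: Optional[float] = None
    grid_len: Optional[int] = None

    def __post_init__(self) -> None:
        segs = sorted((float(a), float(b)) for a, b in self.segments)
        for a, b in segs:
            if not a < b:
                raise ValueError(f"degenerate segment [{a}, {b})")
        for (_, b0), (a1, _) in zip(segs, segs[1:]):
            if a1 < b0:
                raise ValueError("segments overlap")
        self.segments = segs

    @classmethod
    def from_mask(cls, mask: np.ndarray, start_time: float = 0.0) -> "SegmentList":
        mask = np.asarray(mask, dtype=bool)
        padded = np.concatenate(([False], mask, [False])).astype(np.int8)
        edges = np.flatnonzero(np.diff(padded))
        starts, ends = edges[0::2], edges[1::2]
        segs = [(start_time + a, start_time + b) for a, b in zip(starts, ends)]
        return cls(segs, grid_start=start_time, grid_len=len(mask))

    @property
    def mask(self) -> np.ndarray:
        if self.grid_start is None or self.grid_len is None:
            raise ValueError("SegmentList carries no grid; use to_mask()")
        return self.to_mask(self.grid_start, self.grid_len)

    def to_mask(self, start_time: float, n: int) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        for a, b in self.segments:
            i0 = max(0, int(np.ceil(a - start_time)))
            i1 = min(n, int(np.ceil(b - start_time)))
            out[i0:i1] = True
        return out

    def total_duration(self) -> float:
        return sum(b - a for a, b in self.segments)

    def clip(self, lo: float, hi: float) -> "SegmentList":
        segs = [(max(a, lo), min(b, hi)) for a, b in self.segments
                if max(a, lo) < min(b, hi)]
        return SegmentList(segs)

    def intersect(self, other: "SegmentList") -> "SegmentList":
        out = []
        for a0, b0 in self.segments:
            for a1, b1 in other.segments:
                lo, hi = max(a0, a1), min(b0, b1)
                if lo < hi:
                    out.append((lo, hi))
        return SegmentList(out)


@dataclass
class StaLtaSeries:
    """STA, LTA and guarded ratio r = STA / max(LTA, eps) on the 1 Hz grid."""

    start_time: float
    sta: np.ndarray
    lta: np.ndarray
    ratio: np.ndarray


@dataclass
class ThresholdSet:
    sigma1: float
    sigma2: float
    sigma3: float
    provenance: set[str] = field(default_factory=lambda: {"primary"})


@dataclass
class DetectionResult:
    thresholds: ThresholdSet
    segments: SegmentList
    stalta: Optional[StaLtaSeries] = None
    excluded: bool = False


# ---------------------------------------------------------------------------
# STA / LTA computation

def compute_sta_lta(series: EnergySeries | TimeSeries,
                    config: StaLtaConfig) -> StaLtaSeries:
    """Windowed means of C(k): STA forward over T1, LTA backward over T2.

    STA(t) averages C(t+1..t+T1); LTA(t) averages C(t-T2+1..t).  Near the
    record edges the effective window is shortened to the available
    samples; missing bins are excluded from the means; a window with no
    usable sample yields NaN.  The ratio is guarded by epsilon against a
    vanishing LTA.
    """
    values = np.asarray(series.values, dtype=float)
    n = len(values)
    if n < 2:
        raise EmptySeriesError("series must contain at least 2 samples")
    T1, T2, eps = config.T1, config.T2, config.epsilon
    sta = np.full(n, np.nan)
    lta = np.full(n, np.nan)
    for t in range(n):
        w = values[t + 1:t + 1 + T1]
        cnt = w.size - np.count_nonzero(np.isnan(w))
        if cnt:
            sta[t] = np.nansum(w) / cnt
        w = values[max(0, t - T2 + 1):t + 1]
        cnt = w.size - np.count_nonzero(np.isnan(w))
        if cnt:
            lta[t] = np.nansum(w) / cnt
    ratio = sta / np.maximum(lta, eps)
    return StaLtaSeries(series.start_time, sta, lta, ratio)


# ---------------------------------------------------------------------------
# Adaptive thresholds

def sigma1_from_sta(sta: np.ndarray, config: StaLtaConfig) -> float:
    """Activation level: day-specific percentile (default p75) of the STA."""
    sta = np.asarray(sta, dtype=float)
    if not np.any(np.isfinite(sta)):
        raise EmptySeriesError("sigma1 needs at least one finite STA sample")
    return float(np.nanpercentile(sta, config.p_sigma1))


def sigma3_from_ecdf(sta: np.ndarray, config: StaLtaConfig) -> tuple[float, str]:
    """Deactivation level from the ECDF relative-slope rule.

    The ECDF F of the STA is evaluated on a fixed uniform grid spanning
    [min, max]; its derivative is taken by central finite differences.
    sigma3 is the smallest grid value, strictly after the slope peak, where
    the slope falls to <= alpha * max slope.  Degenerate distributions or a
    missing crossing fall back to the conservative low percentile p15.

    Returns (sigma3, provenance) with provenance "primary" or "fallback_p15".
    """
    x = np.asarray(sta, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise EmptySeriesError("sigma3 needs finite STA samples")
    lo, hi = float(x.min()), float(x.max())
    if x.size < 8 or hi <= lo:
        return float(np.percentile(x, config.p_sigma3_fallback)), "fallback_p15"
    grid = np.linspace(lo, hi, config.ecdf_grid_points)
    xs = np.sort(x)
    F = np.searchsorted(xs, grid, side="right") / x.size
    slope = np.gradient(F, grid)
    peak = int(np.argmax(slope))
    M = slope[peak]
    after = np.flatnonzero(slope[peak + 1:] <= config.alpha * M)
    if after.size == 0:
        return float(np.percentile(x, config.p_sigma3_fallback)), "fallback_p15"
    return float(grid[peak + 1 + after[0]]), "primary"


def cfar_threshold(background_ratio: np.ndarray, pfa: float) -> float:
    """Percentile CFAR rule: the q = 100*(1-PFA) percentile of the
    background ratio, so that a fraction PFA of background exceeds it."""
    return float(np.percentile(np.asarray(background_ratio, dtype=float),
                               100.0 * (1.0 - pfa)))


def sigma2_cfar(stalta: StaLtaSeries, sigma1: float, sigma3: float,
                config: StaLtaConfig) -> tuple[Optional[float], set[str]]:
    """Sensitivity threshold from background-only ratio samples.

    Background B keeps samples with STA < sigma3 after excluding +/-Tg
    around every candidate-activity region (STA > sigma1).  If B is too
    small the low-energy limit is relaxed to max(sigma3, p35(STA)); if it
    is still too small the threshold is not updated.  The result is clipped
    to [sigma2_min, sigma2_max].

    Returns (sigma2 or None, provenance flags).
    """
    sta, ratio = stalta.sta, stalta.ratio
    finite = np.isfinite(sta) & np.isfinite(ratio)
    active = finite & (sta > sigma1)
    guard = _dilate(active, config.guard_s)
    flags: set[str] = set()

    bg = finite & ~guard & (sta < sigma3)
    if np.count_nonzero(bg) < config.min_background:
        limit = max(sigma3, float(np.nanpercentile(sta, config.p_bg_relax)))
        bg = finite & ~guard & (sta < limit)
        flags.add("relaxed_bg")
    if np.count_nonzero(bg) < config.min_background_relaxed:
        logger.info("sigma2 not updated: %d background samples",
                    int(np.count_nonzero(bg)))
        return None, {"not_updated"}
    raw = cfar_threshold(ratio[bg], config.pfa)
    clipped = float(np.clip(raw, config.sigma2_min, config.sigma2_max))
    if clipped != raw:
        flags.add("clipped")
    return clipped, flags


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation of a 1-D mask by +/- radius samples."""
    if radius <= 0 or not mask.any():
        return mask.copy()
    kernel = np.ones(2 * radius + 1, dtype=int)
    return np.convolve(mask.astype(int), kernel, mode="same") > 0


def enforce_hysteresis(sigma1: float, sigma3: float,
                       config: StaLtaConfig) -> tuple[float, bool]:
    """Guarantee sigma3 < sigma1, resetting a degenerate sigma3 to
    max(sigma_min, sigma1 - delta).  Returns (sigma3', was_fixed)."""
    if sigma3 >= sigma1:
        return max(config.sigma_min_floor, sigma1 - config.delta_hyst), True
    return sigma3, False


# ---------------------------------------------------------------------------
# Hysteresis segmentation

def segment_activity(stalta: StaLtaSeries, thresholds: ThresholdSet,
                     split_gap: Optional[int] = None) -> SegmentList:
    """Two-threshold hysteresis state machine over STA and ratio.

    Starts OFF; turns ON when STA > sigma1 and ratio > sigma2; turns OFF
    when STA < sigma3 and ratio < sigma2; otherwise holds state.  Missing
    samples hold state, but a missing run of length >= split_gap closes any
    open segment at the start of the run (independent sub-records).  An ON
    state at record end closes at the last sample.
    """
    s1, s2, s3 = thresholds.sigma1, thresholds.sigma2, thresholds.sigma3
    if not s3 < s1:
        raise ValueError("thresholds must satisfy sigma3 < sigma1")
    sta, ratio = stalta.sta, stalta.ratio
    n = len(sta)
    mask = np.zeros(n, dtype=bool)
    on = False
    miss_run = 0
    miss_start = 0
    for t in range(n):
        if np.isnan(sta[t]) or np.isnan(ratio[t]):
            if miss_run == 0:
                miss_start = t
            miss_run += 1
            if split_gap is not None and miss_run == split_gap and on:
                mask[miss_start:t + 1] = False
                on = False
            else:
                mask[t] = on
            continue
        miss_run = 0
        if not on and sta[t] > s1 and ratio[t] > s2:
            on = True
        elif on and sta[t] < s3 and ratio[t] < s2:
            on = False
        mask[t] = on
    return SegmentList.from_mask(mask, stalta.start_time)


# ---------------------------------------------------------------------------
# Per-day driver

def detect_day(series: EnergySeries, config: StaLtaConfig,
               window: Optional[tuple[float, float]] = None) -> DetectionResult:
    """Adapt thresholds on one day's record and segment it.

    ``window`` optionally restricts the record to an absolute [t0, t1)
    analysis interval (e.g. the wake-to-bed window) before anything is
    computed.  Records shorter than T2 (or with fewer than T2 usable
    samples) are excluded: thresholds are not updated and no segmentation
    is attempted.  Thresholds are computed once; there is no iteration.
    """
    if window is not None:
        series = series.slice_window(*window)
    usable = int(np.count_nonzero(np.isfinite(series.values)))
    if len(series) < config.T2 or usable < config.T2:
        thr = ThresholdSet(np.nan, np.nan, np.nan, {"not_updated"})
        return DetectionResult(thr, SegmentList([]), None, excluded=True)

    stalta = compute_sta_lta(series, config)
    sigma1 = sigma1_from_sta(stalta.sta, config)
    sigma3, s3_prov = sigma3_from_ecdf(stalta.sta, config)
    sigma3, fixed = enforce_hysteresis(sigma1, sigma3, config)
    sigma2, s2_flags = sigma2_cfar(stalta, sigma1, sigma3, config)
    provenance = {s3_prov} | s2_flags
    if fixed:
        provenance.add("hysteresis_fixed")
    if sigma2 is None:
        sigma2 = config.sigma2_default
    thresholds = ThresholdSet(sigma1, sigma2, sigma3, provenance)
    segments = segment_activity(stalta, thresholds, split_gap=config.T2)
    return DetectionResult(thresholds, segments, stalta, excluded=False)


def fixed_baseline_thresholds() -> ThresholdSet:
    """The constant-threshold baseline configuration, identical for all
    users and days: sigma1 = 0.25, sigma3 = 0.08, sigma2 = 1.5."""
    return ThresholdSet(0.25, 1.5, 0.08, {"fixed_baseline"})


# ---------------------------------------------------------------------------
# Report I/O

def _iso(t: float) -> str:
    return datetime.fromtimestamp(t, tz=timezone.utc).isoformat()


def write_threshold_report(path, thresholds: ThresholdSet,
                           window: Optional[tuple[float, float]] = None) -> None:
    payload = {
        "sigma1": thresholds.sigma1,
        "sigma2": thresholds.sigma2,
        "sigma3": thresholds.sigma3,
        "provenance": sorted(thresholds.provenance),
        "window": list(window) if window else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_segments_csv(path, segments: SegmentList, label: str = "active") -> None:
    rows = [{"start_iso": _iso(a), "end_iso": _iso(b), "label": label}
            for a, b in segments.segments]
    pd.DataFrame(rows, columns=["start_iso", "end_iso", "label"]).to_csv(
        path, index=False)
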