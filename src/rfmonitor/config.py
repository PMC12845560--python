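"""Run-time configuration for the radar and UWB pipelines.

All defaults correspond to the operating point of the deployed system:
1 Hz sampling, STA/LTA windows of 30 s / 300 s, a CFAR false-alarm target
of 1e-3, a nearly-constant-velocity filter with q_proc = 100 cm^2/s^3 and
10 cm line-of-sight measurement noise, and the 0.2 m/s walking threshold.
Configs are pydantic models: unknown keys are rejected and invariants are
enforced at construction time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, model_validator


class StaLtaConfig(BaseModel):
    """Parameters of the adaptive STA/LTA detector.

    T1/T2 are the short and long moving-average windows (seconds at 1 Hz).
    sigma1 is taken as the p_sigma1 percentile of the day's STA; sigma3 by
    the ECDF relative-slope rule with fraction ``alpha`` (falling back to the
    p_sigma3_fallback percentile); sigma2 by a CFAR percentile of the
    background STA/LTA ratio at false-alarm rate ``pfa``, guarded by
    ``guard_s`` seconds around high-STA regions and clipped to
    [sigma2_min, sigma2_max].
    """

    model_config = ConfigDict(extra="forbid")

    T1: int = 30
    T2: int = 300
    alpha: float = 0.2
    p_sigma1: float = 75.0
    p_sigma3_fallback: float = 15.0
    p_bg_relax: float = 35.0
    pfa: float = 1e-3
    guard_s: int = 60          # Tg; +/- seconds excluded around candidate activity
    sigma2_min: float = 0.5
    sigma2_max: float = 10.0
    sigma2_default: float = 1.5  # used when the CFAR update is not possible
    delta_hyst: float = 0.05
    sigma_min_floor: float = 0.0
    epsilon: float = 1e-6
    ecdf_grid_points: int = 512
    min_background: int = 10_000   # |B| needed for a stable 99.9th percentile
    min_background_relaxed: int = 1_000

    @model_validator(mode="after")
    def _check(self) -> "StaLtaConfig":
        if not (self.T2 > self.T1 > 0):
            raise ValueError("require T2 > T1 > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("require 0 < alpha < 1")
        if not (0.0 < self.pfa < 1.0):
            raise ValueError("require 0 < pfa < 1")
        if not (self.sigma2_min < self.sigma2_max):
            raise ValueError("require sigma2_min < sigma2_max")
        if not self.delta_hyst > 0:
            raise ValueError("require delta_hyst > 0")
        return self


class KfConfig(BaseModel):
    """Nearly-constant-velocity Kalman filter parameters (cm / s units)."""

    model_config = ConfigDict(extra="forbid")

    Ts: float = 1.0
    q_proc: float = 100.0        # white-acceleration intensity, cm^2/s^3
    sigma_meas: float = 10.0     # LOS position noise per axis, cm
    alpha_R: float = 4.0         # covariance inflation for interpolated samples
    init_pos_sigma: float = 10.0
    init_vel_sigma: float = 50.0
    safety_offset: float = 2.0   # cm inside the feasible side of a wall
    # numerical floor for V' S^-1 V: the modified-gain correction scales as
    # its inverse, so near-null innovations (below ~0.1 sigma Mahalanobis)
    # switch to the direct-substitution fallback before the covariance
    # update becomes numerically destructive
    epsilon_gate: float = 1e-2
    # bound on the modified-gain correction entries: sustained constraint
    # conflicts (measurements persistently beyond a wall) otherwise compound
    # the covariance update without bound; beyond the cap the update falls
    # back to direct substitution with the unmodified gain
    gain_correction_cap: float = 50.0

    @model_validator(mode="after")
    def _check(self) -> "KfConfig":
        if self.Ts <= 0 or self.q_proc <= 0:
            raise ValueError("require Ts > 0 and q_proc > 0")
        if self.alpha_R < 1:
            raise ValueError("require alpha_R >= 1")
        return self


class Windows(BaseModel):
    """Analysis windows, as (start, end) hours of day, half-open."""

    model_config = ConfigDict(extra="forbid")

    daytime: Tuple[float, float] = (7.0, 22.0)     # radar occupancy analysis
    diagnostic: Tuple[float, float] = (7.0, 22.0)  # fixed-baseline comparison
    metrics: Tuple[float, float] = (8.0, 22.0)     # UWB mobility metrics

    @model_validator(mode="after")
    def _check(self) -> "Windows":
        for name in ("daytime", "diagnostic", "metrics"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= 24):
                raise ValueError(f"window {name} must satisfy 0 <= start < end <= 24")
        return self


class Thresholds(BaseModel):
    """Rule constants shared across the analytics modules."""

    model_config = ConfigDict(extra="forbid")

    min_visit_s: float = 30.0        # minimum bathroom presence run
    speed_threshold_m_s: float = 0.2  # active / walking speed threshold
    max_gap_fill_s: float = 60.0     # UWB gaps shorter than this are filled
    metrics_gap_s: float = 300.0     # >5 min gaps excluded from time totals
    charging_min_s: float = 300.0    # >=5 min low-speed charging runs excluded
    sleep_sustain_s: float = 3600.0  # sustained dark/light requirement
    dark_threshold: float = 10.0     # light-intensity units; below = dark


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    stalta: StaLtaConfig = StaLtaConfig()
    kf: KfConfig = KfConfig()
    windows: Windows = Windows()
    thresholds: Thresholds = Thresholds()


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a RunConfig from a JSON file, or return full defaults.

    Unknown keys raise; any default can be overridden individually.
    """
    if path is None:
        return RunConfig()
    with open(path) as fh:
        payload = json.load(fh)
    return RunConfig.model_validate(payload)
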