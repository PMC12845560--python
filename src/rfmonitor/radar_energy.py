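"""Radar gate-energy ingestion and aggregation.

The mmWave module reports, once per second, a binary presence flag and the
motion energy (0-100) in N fixed range gates along the line of sight, for a
micromovement channel (breathing-scale motion) and a macromovement channel
(whole-body displacement).  This module bins frames onto a common 1 Hz grid
and collapses the gates into one normalized activity signal

    C(k) = (1/N) * sum_j c_j(k) / 100,     C(k) in [0, 1],

which is the input to the adaptive STA/LTA detector.  Missing seconds are
kept as missing (NaN) bins and are never imputed as zero energy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_N_GATES = 9


class EmptySeriesError(ValueError):
    """Raised when an operation receives no usable samples."""


@dataclass
class GateEnergyFrame:
    """One radar frame: timestamp, per-gate energies, binary presence."""

    timestamp: float
    micro_energy: np.ndarray
    macro_energy: np.ndarray
    presence: int = 0

    def __post_init__(self) -> None:
        self.micro_energy = np.asarray(self.micro_energy, dtype=float)
        self.macro_energy = np.asarray(self.macro_energy, dtype=float)


@dataclass
class TimeSeries:
    """A 1 Hz series on a regular grid; NaN marks missing bins."""

    start_time: float
    values: np.ndarray
    rate: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values), dtype=float)

    def slice_window(self, t_lo: float, t_hi: float) -> "TimeSeries":
        """Restrict to absolute times in [t_lo, t_hi)."""
        i0 = max(0, int(np.ceil(t_lo - self.start_time)))
        i1 = min(len(self.values), int(np.ceil(t_hi - self.start_time)))
        i1 = max(i0, i1)
        return type(self)(self.start_time + i0, self.values[i0:i1].copy())


class EnergySeries(TimeSeries):
    """Aggregated, normalized radar energy C(k); values in [0, 1] or NaN."""

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("EnergySeries values must lie in [0, 1]")


def aggregate_gates(
    frames: Sequence[GateEnergyFrame],
    channel: Literal["micro", "macro"] = "micro",
) -> EnergySeries:
    """Aggregate per-gate energies into the normalized signal C(k).

    Frames are first binned onto the 1 Hz grid (last frame wins within a
    bin); seconds with no frame yield missing bins.  A gate value outside
    [0, 100] rejects the input, reporting the offending frame index.
    """
    if not frames:
        raise EmptySeriesError("no frames to aggregate")
    attr = "micro_energy" if channel == "micro" else "macro_energy"
    samples = []
    for i, frame in enumerate(frames):
        gates = getattr(frame, attr)
        if gates is None or len(gates) == 0:
            raise ValueError(f"frame {i}: channel {channel!r} missing")
        if np.any(gates < 0.0) or np.any(gates > 100.0):
            raise ValueError(f"frame {i}: gate value outside [0, 100]")
        c = float(np.mean(gates) / 100.0)
        samples.append((frame.timestamp, c))
    ts = bin_to_1hz(samples)
    return EnergySeries(ts.start_time, ts.values)


def bin_to_1hz(samples: Iterable[tuple[float, float]]) -> TimeSeries:
    """Bin timestamped values onto a common 1 s grid.

    Bin b covers [t0 + b, t0 + b + 1).  Bins with no sample are NaN; when
    several samples fall in one bin the last (by timestamp) wins.  Unsorted
    input is sorted with a warning; exact duplicate timestamps are
    deduplicated (keeping the last occurrence).
    """
    pairs = list(samples)
    if not pairs:
        raise EmptySeriesError("no samples to bin")
    times = np.array([p[0] for p in pairs], dtype=float)
    vals = np.array([p[1] for p in pairs], dtype=float)
    if np.any(np.diff(times) < 0):
        warnings.warn("timestamps not sorted; sorting", stacklevel=2)
        order = np.argsort(times, kind="stable")
        times, vals = times[order], vals[order]
    start = float(np.floor(times[0]))
    bins = np.floor(times - start).astype(int)
    n = bins[-1] + 1
    out = np.full(n, np.nan)
    out[bins] = vals  # later samples overwrite earlier ones in the same bin
    return TimeSeries(start, out)


# ---------------------------------------------------------------------------
# Day-file I/O

def read_day_file(path, n_gates: int = DEFAULT_N_GATES) -> list[GateEnergyFrame]:
    """Read a radar day CSV: timestamp, presence, micro_g1.., macro_g1..."""
    df = pd.read_csv(path)
    micro_cols = [f"micro_g{j}" for j in range(1, n_gates + 1)]
    macro_cols = [f"macro_g{j}" for j in range(1, n_gates + 1)]
    frames = [
        GateEnergyFrame(
            timestamp=float(row["timestamp"]),
            micro_energy=row[micro_cols].to_numpy(dtype=float),
            macro_energy=row[macro_cols].to_numpy(dtype=float),
            presence=int(row["presence"]),
        )
        for _, row in df.iterrows()
    ]
    return frames


def write_day_file(path, frames: Sequence[GateEnergyFrame]) -> None:
    n_gates = len(frames[0].micro_energy) if frames else DEFAULT_N_GATES
    rows = []
    for f in frames:
        row = {"timestamp": f.timestamp, "presence": f.presence}
        for j in range(n_gates):
            row[f"micro_g{j + 1}"] = f.micro_energy[j]
            row[f"macro_g{j + 1}"] = f.macro_energy[j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_energy_csv(path, series: TimeSeries) -> None:
    """Write `timestamp,value` rows; missing bins get an empty value field."""
    df = pd.DataFrame({"timestamp": series.times, "value": series.values})
    df.to_csv(path, index=False, na_rep="")


def read_energy_csv(path) -> EnergySeries:
    df = pd.read_csv(path)
    ts = bin_to_1hz(zip(df["timestamp"].to_numpy(), df["value"].to_numpy()))
    return EnergySeries(ts.start_time, ts.values)
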