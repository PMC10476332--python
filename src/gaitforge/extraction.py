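"""Median gait-pattern extraction from raw time-series trials.

Raw trials (load + thigh/knee/ankle sampled every 5 ms) are segmented into
strides by detecting one landmark peak per gait cycle with a smoothed
z-score detector, each stride is linearly resampled onto the closed 0.5 %
phase grid, and the element-wise median across strides yields the trial's
representative 201 x 4 pattern.  No further processing (no normalization,
no offset removal) is applied at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .core import (
    CHANNELS,
    DataError,
    GaitPattern,
    InvalidSpecError,
    N_CHANNELS,
    SAMPLE_PERIOD,
)

__all__ = [
    "RawTrial",
    "PeakDetectorConfig",
    "zscore_peaks",
    "segment_cycles",
    "resample_cycle",
    "median_pattern",
    "extract_pattern",
]


@dataclass
class RawTrial:
    """A recorded multichannel trial with subject metadata.

    ``data`` is (n, 4) in :data:`~gaitforge.core.CHANNELS` order.  At least
    two full gait cycles are needed for segmentation to succeed.
    """

    data: np.ndarray
    sample_period: float = SAMPLE_PERIOD
    weight: float = 70.0
    mode: str = "lgw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise DataError("trial data must be (n, 4)")
        if self.sample_period <= 0 or self.weight <= 0:
            raise InvalidSpecError("sample_period and weight must be positive")

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]


@dataclass(frozen=True)
class PeakDetectorConfig:
    """Smoothed z-score peak detector settings.

    ``lag`` sets the rolling window, ``threshold`` the z-score trigger, and
    ``influence`` how strongly flagged samples update the rolling filter
    (0 freezes it, 1 is an ordinary rolling window).  The segmentation
    channel defaults to the vertical load, whose loading-response peak is
    the most robust once-per-stride landmark.
    """

    lag: int = 25
    threshold: float = 3.0
    influence: float = 0.1
    channel: str = "load"

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise InvalidSpecError("lag must be >= 1")
        if self.threshold <= 0:
            raise InvalidSpecError("threshold must be > 0")
        if not 0.0 <= self.influence <= 1.0:
            raise InvalidSpecError("influence must lie in [0, 1]")
        if self.channel not in CHANNELS:
            raise InvalidSpecError(f"unknown channel {self.channel!r}")


def zscore_peaks(signal, cfg: PeakDetectorConfig = PeakDetectorConfig()) -> List[int]:
    """Peak indices of a 1-D series under the smoothed z-score rule.

    A sample is flagged when it exceeds the influence-damped rolling mean by
    more than ``threshold`` rolling standard deviations (upward excursions
    only).  Flagged samples enter the rolling filter attenuated by
    ``influence``, so a sustained peak does not drag the baseline up.  Each
    maximal run of consecutive flagged samples collapses to the index of the
    run's maximum value — one landmark per excursion.
    """
    x = np.asarray(signal, dtype=float).ravel()
    lag = cfg.lag
    if x.size <= lag:
        raise DataError(f"signal of length {x.size} is too short for lag {lag}")

    filtered = x[:lag].astype(float).copy()
    mean = filtered.mean()
    std = filtered.std()
    flags = np.zeros(x.size, dtype=bool)
    window = list(filtered)
    for i in range(lag, x.size):
        if x[i] - mean > cfg.threshold * std:
            flags[i] = True
            new_val = cfg.influence * x[i] + (1 - cfg.influence) * window[-1]
        else:
            new_val = x[i]
        window.append(new_val)
        window.pop(0)
        arr = np.asarray(window)
        mean = arr.mean()
        std = arr.std()

    peaks: List[int] = []
    i = 0
    while i < x.size:
        if flags[i]:
            j = i
            while j + 1 < x.size and flags[j + 1]:
                j += 1
            run = np.arange(i, j + 1)
            peaks.append(int(run[np.argmax(x[run])]))
            i = j + 1
        else:
            i += 1
    return peaks


def segment_cycles(trial: RawTrial, peaks: Sequence[int]) -> List[np.ndarray]:
    """Split a trial into per-stride slices between consecutive peaks.

    Each slice spans [peak_i, peak_{i+1}] inclusive, so consecutive cycles
    share their boundary sample; n peaks yield n - 1 cycles.
    """
    peaks = list(peaks)
    if len(peaks) < 2:
        raise DataError("segmentation requires at least 2 peaks (>= 1 full cycle)")
    if any(b <= a for a, b in zip(peaks, peaks[1:])):
        raise DataError("peak indices must be strictly increasing")
    if peaks[0] < 0 or peaks[-1] >= trial.data.shape[0]:
        raise DataError("peak index outside the trial")
    return [trial.data[a : b + 1].copy() for a, b in zip(peaks, peaks[1:])]


def resample_cycle(cycle: np.ndarray) -> GaitPattern:
    """Linearly resample one stride onto the closed 201-node phase grid.

    Endpoints map exactly: phase 0 % is the cycle's first sample and 100 %
    its last.
    """
    cycle = np.asarray(cycle, dtype=float)
    if cycle.ndim != 2 or cycle.shape[1] != N_CHANNELS:
        raise DataError("cycle must be (n, 4)")
    n = cycle.shape[0]
    if n < 2:
        raise DataError("cannot resample a single-sample cycle")
    src = np.linspace(0.0, 100.0, n)
    dst = np.arange(201) * 0.5
    out = np.empty((201, N_CHANNELS))
    for c in range(N_CHANNELS):
        out[:, c] = np.interp(dst, src, cycle[:, c])
    return GaitPattern(out, units="physical")


def median_pattern(cycles: Sequence[GaitPattern]) -> GaitPattern:
    """Element-wise median across resampled cycles, per node and channel.

    Even counts use the arithmetic mean of the two central values (numpy's
    convention).  Nothing else — no normalization or offset removal — is
    applied.
    """
    if len(cycles) == 0:
        raise DataError("median_pattern requires at least one cycle")
    rows = {c.n_rows for c in cycles}
    if rows != {201}:
        raise DataError("all cycles must be on the 201-row grid")
    stack = np.stack([c.values for c in cycles])
    return GaitPattern(np.median(stack, axis=0), units="physical")


def extract_pattern(
    trial: RawTrial, cfg: PeakDetectorConfig = PeakDetectorConfig()
) -> GaitPattern:
    """Full trial-to-pattern pipeline: detect, segment, resample, median."""
    peaks = zscore_peaks(trial.channel(cfg.channel), cfg)
    cycles = segment_cycles(trial, peaks)
    return median_pattern([resample_cycle(c) for c in cycles])


# --- Trial CSV dialect: header t,load,thigh,knee,ankle + sidecar JSON ------


def write_trial_csv(path, trial: RawTrial) -> None:
    """Write `t,load,thigh,knee,ankle` plus a `.meta.json` sidecar."""
    import json

    import pandas as pd

    path = str(path)
    t = np.arange(trial.data.shape[0]) * trial.sample_period
    df = pd.DataFrame(trial.data, columns=list(CHANNELS))
    df.insert(0, "t", t)
    df.to_csv(path, index=False)
    with open(path + ".meta.json", "w") as fh:
        json.dump({"weight": trial.weight, "mode": trial.mode,
                   "sample_period": trial.sample_period}, fh)


def read_trial_csv(path) -> RawTrial:
    import json
    import os

    import pandas as pd

    path = str(path)
    df = pd.read_csv(path)
    expected = ["t", *CHANNELS]
    if list(df.columns) != expected:
        raise DataError(f"trial CSV must have columns {expected}, "
                        f"got {list(df.columns)}")
    meta = {}
    if os.path.exists(path + ".meta.json"):
        with open(path + ".meta.json") as fh:
            meta = json.load(fh)
    return RawTrial(
        df[list(CHANNELS)].to_numpy(),
        sample_period=float(meta.get("sample_period", SAMPLE_PERIOD)),
        weight=float(meta.get("weight", 70.0)),
        mode=str(meta.get("mode", "lgw")),
    )
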