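"""Domain types and shared geometry for gait patterns.

A *gait pattern* expresses one stride of multichannel gait data (vertical
load in kg plus thigh/knee/ankle angles in degrees) over gait-cycle percent
instead of time.  Two phase grids are in use:

* the **closed** grid 0, 0.5, ..., 100 % (201 rows), natural for patterns
  extracted from recorded strides where both the first and the repeated
  event sample are kept, and
* the **half-open** grid 0, 0.5, ..., 99.5 % (200 rows), used by the
  generative model, whose internal stride-2 stages need a length divisible
  by 8.

An 11-node *sketch* specifies a pattern coarsely, one node per 10 % of the
cycle; it is what a user can design by hand and what conditions the
generator.

All channels share a single affine normalization

    v_n = 0.1 * v / g + 0.5

with gain g = 36 for the three angle channels and, for the vertical load,
either the subject's body weight (benchmark-style data) or a fixed 48 kg
(bypass-style data).  The map centers zero at 0.5 and keeps plausible gait
data inside (0, 1), the output range of the generator's sigmoid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "N_CHANNELS",
    "ANGLE_GAIN",
    "BYPASS_LOAD_GAIN",
    "GaitForgeError",
    "InvalidSpecError",
    "MissingParameterError",
    "GridMismatchError",
    "DataError",
    "NormalizationSpec",
    "GaitPattern",
    "DiscretizedPattern",
    "TimeSeriesGait",
    "normalize_value",
    "denormalize_value",
    "normalize_pattern",
    "denormalize_pattern",
    "discretize",
    "interpolate_input",
    "validate_normalized",
    "read_pattern_csv",
    "write_pattern_csv",
    "read_sketch_csv",
    "write_sketch_csv",
]

#: Fixed channel order shared by every pattern and series container.
CHANNELS: tuple[str, ...] = ("load", "thigh", "knee", "ankle")
N_CHANNELS = len(CHANNELS)

#: Joint-angle normalization gain (degrees).
ANGLE_GAIN = 36.0
#: Constant vertical-load gain for bypass-style data (kg).
BYPASS_LOAD_GAIN = 48.0

#: Sample period of all time series (seconds).
SAMPLE_PERIOD = 0.005

IMPEDANCE_CHANNELS: tuple[str, ...] = ("k_knee", "b_knee", "k_ankle", "b_ankle")


class GaitForgeError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(GaitForgeError, ValueError):
    """A configuration value violates its contract (e.g. non-positive gain)."""


class MissingParameterError(GaitForgeError, ValueError):
    """A required parameter (e.g. subject weight in benchmark mode) is absent."""


class GridMismatchError(GaitForgeError, ValueError):
    """A pattern is on the wrong phase grid for the requested operation."""


class DataError(GaitForgeError, ValueError):
    """Malformed input data (shape, finiteness, file format)."""


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizationSpec:
    """Parameters of the affine channel normalization.

    ``load_gain_mode`` selects the vertical-load gain: ``"benchmark"`` uses
    the subject's body weight (so load is effectively body-weight-relative),
    ``"bypass"`` uses the fixed 48 kg constant, which preserves
    between-subject load variability.
    """

    angle_gain: float = ANGLE_GAIN
    load_gain_mode: Literal["benchmark", "bypass"] = "benchmark"
    offset: float = 0.5
    slope: float = 0.1

    def __post_init__(self) -> None:
        if self.angle_gain <= 0:
            raise InvalidSpecError("angle_gain must be strictly positive")
        if self.load_gain_mode not in ("benchmark", "bypass"):
            raise InvalidSpecError(f"unknown load_gain_mode {self.load_gain_mode!r}")

    def load_gain(self, weight: Optional[float] = None) -> float:
        if self.load_gain_mode == "bypass":
            return BYPASS_LOAD_GAIN
        if weight is None:
            raise MissingParameterError(
                "subject weight is required for benchmark-mode load normalization"
            )
        if weight <= 0:
            raise InvalidSpecError("subject weight must be strictly positive")
        return float(weight)

    def gains(self, weight: Optional[float] = None) -> np.ndarray:
        """Per-channel gain vector in :data:`CHANNELS` order."""
        return np.array(
            [self.load_gain(weight)] + [self.angle_gain] * 3, dtype=float
        )


def normalize_value(v, gain: float):
    """Affine normalization ``v_n = 0.1 * v / gain + 0.5``.

    Accepts scalars or arrays; ``gain`` must be strictly positive.
    """
    if np.any(np.asarray(gain) <= 0):
        raise InvalidSpecError("normalization gain must be strictly positive")
    return 0.1 * np.asarray(v, dtype=float) / gain + 0.5


def denormalize_value(v_n, gain: float):
    """Inverse of :func:`normalize_value`: ``v = (v_n - 0.5) * gain / 0.1``."""
    if np.any(np.asarray(gain) <= 0):
        raise InvalidSpecError("normalization gain must be strictly positive")
    return (np.asarray(v_n, dtype=float) - 0.5) * gain / 0.1


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


def _check_values(values: np.ndarray, n_rows: Sequence[int], what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != N_CHANNELS:
        raise DataError(f"{what} must be 2-D with {N_CHANNELS} channel columns, "
                        f"got shape {values.shape}")
    if values.shape[0] not in n_rows:
        raise DataError(f"{what} must have {n_rows} rows, got {values.shape[0]}")
    if not np.all(np.isfinite(values)):
        raise DataError(f"{what} contains non-finite values")
    return values


@dataclass
class GaitPattern:
    """Phase-indexed 4-channel matrix on the 0.5 % grid.

    ``values`` is (201, 4) on the closed grid 0..100 % or (200, 4) on the
    half-open grid 0..99.5 %.  ``units`` records whether channels are in
    physical units (kg / degrees) or normalized (0, 1) units.
    """

    values: np.ndarray
    units: Literal["physical", "normalized"] = "physical"

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, (200, 201), "GaitPattern values")
        if self.units not in ("physical", "normalized"):
            raise InvalidSpecError(f"unknown units {self.units!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def phase_grid(self) -> np.ndarray:
        """Phase nodes in percent: 0..100 (201 rows) or 0..99.5 (200 rows)."""
        return np.arange(self.n_rows) * 0.5

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, CHANNELS.index(name)]

    def drop_final_node(self) -> "GaitPattern":
        """Closed-grid (201-row) pattern without its 100 % row (200 rows)."""
        if self.n_rows != 201:
            raise GridMismatchError("drop_final_node requires a 201-row pattern")
        return GaitPattern(self.values[:200].copy(), units=self.units)


@dataclass
class DiscretizedPattern:
    """An 11 x 4 sketch: one node per 10 % of the gait cycle, 0..100 %."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, (11,), "DiscretizedPattern values")

    @property
    def node_grid(self) -> np.ndarray:
        return np.arange(11) * 10.0

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, CHANNELS.index(name)]


@dataclass
class TimeSeriesGait:
    """Multichannel gait series sampled every 5 ms.

    ``gait`` is (n, 4) in :data:`CHANNELS` order.  ``impedance``, when
    present, is (n, 4) holding normalized (k_knee, b_knee, k_ankle, b_ankle)
    in [0, 1], sample-aligned with the gait channels.  ``phase`` optionally
    annotates gait-cycle percent per sample.
    """

    gait: np.ndarray
    impedance: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    sample_period: float = SAMPLE_PERIOD

    def __post_init__(self) -> None:
        self.gait = np.asarray(self.gait, dtype=float)
        if self.gait.ndim != 2 or self.gait.shape[1] != N_CHANNELS:
            raise DataError("gait must be (n, 4)")
        if not np.all(np.isfinite(self.gait)):
            raise DataError("gait contains non-finite values")
        if self.impedance is not None:
            self.impedance = np.asarray(self.impedance, dtype=float)
            if self.impedance.shape != self.gait.shape:
                raise DataError("impedance channels must align with gait channels")
            if np.any(self.impedance < 0) or np.any(self.impedance > 1):
                raise DataError("impedance channels must lie within [0, 1]")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if self.phase.shape != (self.gait.shape[0],):
                raise DataError("phase annotation must have one value per sample")
        if self.sample_period <= 0:
            raise InvalidSpecError("sample_period must be positive")

    def __len__(self) -> int:
        return self.gait.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) * self.sample_period

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for i, name in enumerate(CHANNELS):
            cols[name] = self.gait[:, i]
        if self.impedance is not None:
            for i, name in enumerate(IMPEDANCE_CHANNELS):
                cols[name] = self.impedance[:, i]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Pattern-level normalization
# ---------------------------------------------------------------------------


def normalize_pattern(
    p: GaitPattern,
    spec: NormalizationSpec = NormalizationSpec(),
    weight: Optional[float] = None,
) -> GaitPattern:
    """Normalize a physical pattern channel-wise.

    ``weight`` (kg) is required when ``spec.load_gain_mode == "benchmark"``.
    """
    if p.units != "physical":
        raise InvalidSpecError("normalize_pattern expects a physical-units pattern")
    gains = spec.gains(weight)
    out = spec.slope * p.values / gains[None, :] + spec.offset
    return GaitPattern(out, units="normalized")


def denormalize_pattern(
    p: GaitPattern,
    spec: NormalizationSpec = NormalizationSpec(),
    weight: Optional[float] = None,
) -> GaitPattern:
    """Inverse of :func:`normalize_pattern`."""
    if p.units != "normalized":
        raise InvalidSpecError("denormalize_pattern expects a normalized pattern")
    gains = spec.gains(weight)
    out = (p.values - spec.offset) * gains[None, :] / spec.slope
    return GaitPattern(out, units="physical")


def validate_normalized(values: np.ndarray) -> bool:
    """True when every value lies strictly inside (0, 1).

    Intermediate math may leave this range; the generator's sigmoid
    guarantees it only for generated output.
    """
    values = np.asarray(values)
    return bool(np.all(values > 0) and np.all(values < 1))


# ---------------------------------------------------------------------------
# Sketch <-> continuous geometry
# ---------------------------------------------------------------------------


def discretize(p: GaitPattern) -> DiscretizedPattern:
    """Extract the 11-node sketch from a closed-grid (201-row) pattern.

    Nodes are exact rows at phases 0, 10, ..., 100 % (indices 0, 20, ..., 200).
    A 200-row pattern is rejected because its grid has no 100 % node.
    """
    if p.n_rows != 201:
        raise GridMismatchError(
            "discretize requires the closed 201-row grid (the 100% node is "
            "absent from a 200-row pattern)"
        )
    idx = np.arange(0, 201, 20)
    return DiscretizedPattern(p.values[idx].copy())


def interpolate_input(d: DiscretizedPattern) -> GaitPattern:
    """Linearly interpolate a sketch onto the half-open 200-row grid.

    Output phases are 0, 0.5, ..., 99.5 %; values at the shared node phases
    equal the sketch nodes exactly.  This is the conditioning signal fed to
    the generator.
    """
    target = np.arange(200) * 0.5
    out = np.empty((200, N_CHANNELS))
    for c in range(N_CHANNELS):
        out[:, c] = np.interp(target, d.node_grid, d.values[:, c])
    return GaitPattern(out, units="normalized" if validate_normalized(d.values)
                       else "physical")


# ---------------------------------------------------------------------------
# CSV I/O  (Pattern CSV dialect: header phase,load,thigh,knee,ankle)
# ---------------------------------------------------------------------------

_PATTERN_COLUMNS = ["phase", *CHANNELS]


def write_pattern_csv(path, p: GaitPattern) -> None:
    df = pd.DataFrame(p.values, columns=list(CHANNELS))
    df.insert(0, "phase", p.phase_grid)
    df.to_csv(path, index=False)


def read_pattern_csv(path, units: str = "physical") -> GaitPattern:
    df = pd.read_csv(path)
    if list(df.columns) != _PATTERN_COLUMNS:
        raise DataError(f"pattern CSV must have columns {_PATTERN_COLUMNS}, "
                        f"got {list(df.columns)}")
    return GaitPattern(df[list(CHANNELS)].to_numpy(), units=units)


def write_sketch_csv(path, d: DiscretizedPattern) -> None:
    df = pd.DataFrame(d.values, columns=list(CHANNELS))
    df.insert(0, "phase", d.node_grid)
    df.to_csv(path, index=False)


def read_sketch_csv(path) -> DiscretizedPattern:
    df = pd.read_csv(path)
    if list(df.columns) != _PATTERN_COLUMNS:
        raise DataError(f"sketch CSV must have columns {_PATTERN_COLUMNS}, "
                        f"got {list(df.columns)}")
    if len(df) != 11:
        raise DataError(f"sketch CSV must have 11 rows, got {len(df)}")
    return DiscretizedPattern(df[list(CHANNELS)].to_numpy())
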