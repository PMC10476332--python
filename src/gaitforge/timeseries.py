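"""From generated patterns to controller training corpora.

Sketch-level variation, phase-to-time resampling at the 5 ms controller
period, junction stitching with one or two bridging samples, per-mode
duration presets, and normalized impedance (stiffness/damping) profiles
aligned sample-for-sample with the gait channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import (
    DataError,
    DiscretizedPattern,
    GaitPattern,
    InvalidSpecError,
    N_CHANNELS,
    SAMPLE_PERIOD,
    TimeSeriesGait,
)

__all__ = [
    "VariationConfig",
    "StitchConfig",
    "ModePreset",
    "ImpedanceProfile",
    "ImpedanceRanges",
    "apply_variation",
    "timeseries_from_pattern",
    "stitch",
    "impedance_profile",
    "scale_to_physical",
    "build_dataset",
    "MODE_PRESETS",
]


@dataclass(frozen=True)
class VariationConfig:
    """Sketch-perturbation settings: U' = U + scale * sigma(U) * r.

    ``sigma(U)`` is the population standard deviation of the channel's 11
    sketch nodes; ``r`` is drawn uniformly from [-1, 1] independently per
    node (and channel).
    """

    scale: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise InvalidSpecError("variation scale must be >= 0")


@dataclass(frozen=True)
class StitchConfig:
    """Junction bridging: 1 or 2 interpolated samples (5 or 10 ms), chosen
    uniformly at random per junction."""

    sample_period: float = SAMPLE_PERIOD
    bridge_choices: Tuple[int, ...] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.bridge_choices) <= {0, 1, 2}:
            raise InvalidSpecError("bridging sample counts must be in {0, 1, 2}")
        if len(self.bridge_choices) == 0:
            raise InvalidSpecError("bridge_choices must be non-empty")


@dataclass(frozen=True)
class ModePreset:
    """Per-mode corpus recipe: duration range and corpus counts."""

    mode: str
    duration_range: Tuple[float, float]
    variations: int = 60
    datasets: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.duration_range
        if not 0 < lo < hi:
            raise InvalidSpecError("duration range must be positive with low < high")
        if self.variations < 1 or self.datasets < 1:
            raise InvalidSpecError("variations and datasets must be >= 1")


MODE_PRESETS = {
    "lgw": ModePreset("lgw", (1.0, 1.25)),
    "sts": ModePreset("sts", (5.0, 6.25)),
}


# ---------------------------------------------------------------------------
# Impedance profiles
# ---------------------------------------------------------------------------

# Normalized stiffness/damping knot tables over gait phase.  These are
# design fixtures: stance-phase-high / swing-phase-low stiffness with
# damping bumps around the stance-swing transitions, drawn to the
# qualitative shape of published joint-impedance estimates.  Values are our
# own, in [0, 1], periodic at the cycle boundary.
_IMPEDANCE_KNOTS = {
    "knee": {
        "stiffness": ([0, 10, 30, 50, 60, 70, 85, 100],
                      [0.85, 0.9, 0.7, 0.75, 0.3, 0.1, 0.15, 0.85]),
        "damping": ([0, 10, 40, 55, 65, 80, 92, 100],
                    [0.2, 0.15, 0.2, 0.55, 0.3, 0.2, 0.5, 0.2]),
    },
    "ankle": {
        "stiffness": ([0, 10, 30, 45, 55, 65, 80, 100],
                      [0.4, 0.5, 0.75, 0.9, 0.5, 0.15, 0.2, 0.4]),
        "damping": ([0, 12, 35, 50, 62, 75, 90, 100],
                    [0.3, 0.25, 0.3, 0.6, 0.35, 0.2, 0.25, 0.3]),
    },
}


@dataclass(frozen=True)
class ImpedanceProfile:
    """Normalized stiffness and damping curves over phase for one joint."""

    joint: str
    stiffness_knots: Tuple[Sequence[float], Sequence[float]]
    damping_knots: Tuple[Sequence[float], Sequence[float]]

    def curves(self, phases) -> np.ndarray:
        """(len(phases), 2) columns (stiffness, damping), clipped to [0, 1]."""
        phases = np.asarray(phases, dtype=float)
        phases = np.where(phases == 100.0, 100.0, np.mod(phases, 100.0))
        out = np.empty((phases.size, 2))
        for j, knots in enumerate((self.stiffness_knots, self.damping_knots)):
            interp = PchipInterpolator(np.asarray(knots[0], float),
                                       np.asarray(knots[1], float))
            out[:, j] = np.clip(interp(phases), 0.0, 1.0)
        return out


@dataclass(frozen=True)
class ImpedanceRanges:
    """Physical parameter ranges for the powered knee and ankle.

    Stiffness in Nm/deg, damping in Nm*s/deg.
    """

    knee_stiffness: Tuple[float, float] = (1.5, 5.0)
    knee_damping: Tuple[float, float] = (0.05, 0.5)
    ankle_stiffness: Tuple[float, float] = (3.0, 8.0)
    ankle_damping: Tuple[float, float] = (0.05, 0.15)

    def __post_init__(self) -> None:
        for lo, hi in (self.knee_stiffness, self.knee_damping,
                       self.ankle_stiffness, self.ankle_damping):
            if not lo < hi:
                raise InvalidSpecError("each impedance range needs low < high")

    def bounds(self, joint: str, kind: str) -> Tuple[float, float]:
        try:
            return getattr(self, f"{joint}_{kind}")
        except AttributeError:
            raise InvalidSpecError(
                f"unknown (joint, kind) = ({joint!r}, {kind!r})"
            ) from None


def impedance_profile(joint: str) -> ImpedanceProfile:
    """The shipped default normalized impedance profile for a joint."""
    try:
        knots = _IMPEDANCE_KNOTS[joint]
    except KeyError:
        raise InvalidSpecError(f"unknown joint {joint!r}") from None
    return ImpedanceProfile(joint, tuple(knots["stiffness"]), tuple(knots["damping"]))


def scale_to_physical(
    norm: float,
    joint: str,
    kind: str,
    ranges: ImpedanceRanges = ImpedanceRanges(),
):
    """Map a normalized [0, 1] impedance value into its physical range.

    Values outside [0, 1] are clamped (with a warning) before the linear
    map low + norm * (high - low).
    """
    lo, hi = ranges.bounds(joint, kind)
    arr = np.asarray(norm, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        import warnings

        warnings.warn(f"normalized {joint} {kind} outside [0,1]; clamping",
                      stacklevel=2)
        arr = np.clip(arr, 0.0, 1.0)
    out = lo + arr * (hi - lo)
    return float(out) if np.isscalar(norm) else out


# ---------------------------------------------------------------------------
# Variation / resampling / stitching
# ---------------------------------------------------------------------------


def apply_variation(
    sketch: DiscretizedPattern,
    cfg: VariationConfig = VariationConfig(),
    rng: Optional[np.random.Generator] = None,
) -> DiscretizedPattern:
    """Perturb each sketch node by scale * sigma(channel) * U(-1, 1).

    sigma is the population standard deviation over the channel's 11 nodes,
    so a constant channel stays constant regardless of the draw.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    u = sketch.values
    sigma = u.std(axis=0, ddof=0)
    r = rng.uniform(-1.0, 1.0, size=u.shape)
    return DiscretizedPattern(u + cfg.scale * sigma[None, :] * r)


def timeseries_from_pattern(
    p: GaitPattern, duration: float, sample_period: float = SAMPLE_PERIOD
) -> TimeSeriesGait:
    """Resample a 200-row pattern to ``round(duration / 5 ms)`` samples.

    The phase axis is mapped linearly onto the requested duration; e.g.
    1.2 s yields 240 samples, 1.0 s maps the 200 nodes one-to-one.
    """
    if p.n_rows != 200:
        raise DataError("timeseries_from_pattern expects the 200-row grid")
    if duration < 2 * sample_period:
        raise DataError("duration too short to resample (needs >= 2 samples)")
    n = int(round(duration / sample_period))
    src = np.linspace(0.0, 1.0, p.n_rows)
    dst = np.linspace(0.0, 1.0, n)
    out = np.empty((n, p.values.shape[1]))
    for c in range(p.values.shape[1]):
        out[:, c] = np.interp(dst, src, p.values[:, c])
    return TimeSeriesGait(out, sample_period=sample_period)


def _resample_matrix(values: np.ndarray, n: int) -> np.ndarray:
    src = np.linspace(0.0, 1.0, values.shape[0])
    dst = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(dst, src, values[:, c])
                            for c in range(values.shape[1])])


def _stitch_arrays(chunks: List[np.ndarray], bridges: List[int]) -> np.ndarray:
    parts = [chunks[0]]
    for k, nxt in zip(bridges, chunks[1:]):
        a = parts[-1][-1]
        b = nxt[0]
        if k > 0:
            w = (np.arange(1, k + 1) / (k + 1))[:, None]
            parts.append(a[None, :] * (1 - w) + b[None, :] * w)
        parts.append(nxt)
    return np.vstack(parts)


def stitch(
    series: Sequence[TimeSeriesGait],
    cfg: StitchConfig = StitchConfig(),
    rng: Optional[np.random.Generator] = None,
) -> TimeSeriesGait:
    """Concatenate series with linearly interpolated bridging samples.

    Each junction receives k samples (k drawn from ``bridge_choices``)
    spaced evenly between the two neighboring endpoints, for gait and — when
    present everywhere — impedance channels alike, so alignment is exact.
    Total length is the sum of the inputs plus the sum of the bridge counts.
    """
    if len(series) == 0:
        raise DataError("stitch requires at least one series")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    bridges = [int(rng.choice(cfg.bridge_choices)) for _ in series[1:]]
    gait = _stitch_arrays([s.gait for s in series], bridges)
    impedance = None
    if all(s.impedance is not None for s in series):
        impedance = _stitch_arrays([s.impedance for s in series], bridges)
    return TimeSeriesGait(gait, impedance=impedance,
                          sample_period=cfg.sample_period)


# ---------------------------------------------------------------------------
# Dataset building
# ---------------------------------------------------------------------------


def build_dataset(
    preset: ModePreset,
    make_pattern: Callable[[DiscretizedPattern], GaitPattern],
    sketch: DiscretizedPattern,
    seed: int = 0,
    variation: VariationConfig = VariationConfig(),
    stitch_cfg: StitchConfig = StitchConfig(),
    smooth: Optional[Callable[[GaitPattern], GaitPattern]] = None,
) -> List[TimeSeriesGait]:
    """Controller training corpora from one sketch and a pattern producer.

    For each of ``preset.datasets`` datasets: the sketch is perturbed
    ``preset.variations`` times, each variant passes through
    ``make_pattern`` (typically the trained generator, optionally wrapped
    with smoothing), gets a random duration from the preset range, and the
    joint impedance profiles are expanded to the same duration; the
    resulting segments are stitched with shared junction bridging so gait
    and impedance channels stay sample-aligned.
    """
    rng = np.random.default_rng(seed)
    knee = impedance_profile("knee")
    ankle = impedance_profile("ankle")
    phases = np.arange(200) * 0.5
    knee_curves = knee.curves(phases)
    ankle_curves = ankle.curves(phases)
    imp_pattern = np.column_stack(
        [knee_curves[:, 0], knee_curves[:, 1], ankle_curves[:, 0], ankle_curves[:, 1]]
    )

    datasets: List[TimeSeriesGait] = []
    for _ in range(preset.datasets):
        segments = []
        for _ in range(preset.variations):
            varied = apply_variation(sketch, variation, rng=rng)
            pattern = make_pattern(varied)
            if smooth is not None:
                pattern = smooth(pattern)
            duration = float(rng.uniform(*preset.duration_range))
            ts = timeseries_from_pattern(pattern, duration,
                                         stitch_cfg.sample_period)
            imp = _resample_matrix(imp_pattern, len(ts))
            segments.append(TimeSeriesGait(ts.gait, impedance=imp,
                                           sample_period=ts.sample_period))
        datasets.append(stitch(segments, stitch_cfg, rng=rng))
    return datasets
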