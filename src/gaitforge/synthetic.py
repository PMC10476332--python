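"""Parametric synthetic gait corpora.

Generates gait patterns and raw trials with the statistical structure of
able-bodied benchmark gait datasets — per-subject 201 x 4 cycle patterns
with periodic boundaries, near-zero vertical load during swing, and
subject-level weight/amplitude variability — so every downstream stage
(pattern extraction, generator training, controller training) can run
without external recordings.

The mode templates are fixed knot tables shipped with the package.  They
are design fixtures shaped to qualitative gait features (double-hump load
curve, mono-phasic thigh, biphasic knee, small ankle excursion); the exact
numbers are this package's own and carry no clinical meaning.  This is not
a biomechanically validated gait model: it exercises the pipeline, it does
not generate clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import (
    CHANNELS,
    DataError,
    DiscretizedPattern,
    GaitPattern,
    InvalidSpecError,
    N_CHANNELS,
    NormalizationSpec,
    SAMPLE_PERIOD,
    discretize,
    normalize_pattern,
)
from .extraction import RawTrial

__all__ = [
    "ModeTemplate",
    "SyntheticSubject",
    "MODE_TEMPLATES",
    "get_template",
    "sample_pattern",
    "sample_trial",
    "make_corpus",
]


# ---------------------------------------------------------------------------
# Mode templates
# ---------------------------------------------------------------------------

# Knot tables: {channel: (phase %, value)}.  Load values are fractions of
# body weight and are multiplied by the subject's weight at sampling time;
# angles are degrees.  First and last knot values are equal (periodic).
# Shape-preserving (PCHIP) interpolation between knots keeps the load
# non-negative and exactly zero across the swing window.

_LGW_KNOTS = {
    "load": ([0, 5, 12, 20, 30, 40, 50, 55, 60, 64, 90, 100],
             [0.0, 0.6, 1.05, 0.95, 0.78, 0.95, 1.0, 0.7, 0.15, 0.0, 0.0, 0.0]),
    "thigh": ([0, 10, 30, 50, 60, 75, 87, 100],
              [25.0, 18.0, 0.0, -12.0, -10.0, 5.0, 22.0, 25.0]),
    "knee": ([0, 10, 25, 40, 55, 62, 72, 82, 92, 100],
             [5.0, 18.0, 10.0, 5.0, 15.0, 40.0, 65.0, 45.0, 15.0, 5.0]),
    "ankle": ([0, 8, 30, 48, 58, 65, 75, 90, 100],
              [0.0, -6.0, 5.0, 10.0, 14.0, -12.0, -8.0, -3.0, 0.0]),
}

_STAIRS_UP_KNOTS = {
    "load": ([0, 8, 15, 35, 50, 58, 64, 68, 95, 100],
             [0.0, 0.8, 1.05, 0.9, 1.0, 0.6, 0.1, 0.0, 0.0, 0.0]),
    "thigh": ([0, 20, 45, 60, 80, 100],
              [45.0, 30.0, 10.0, 15.0, 50.0, 45.0]),
    "knee": ([0, 15, 40, 55, 70, 85, 100],
             [55.0, 35.0, 10.0, 8.0, 70.0, 80.0, 55.0]),
    "ankle": ([0, 15, 40, 55, 65, 80, 100],
              [-5.0, 5.0, 12.0, 18.0, -5.0, 2.0, -5.0]),
}

_STAIRS_DOWN_KNOTS = {
    "load": ([0, 6, 14, 30, 45, 55, 62, 66, 95, 100],
             [0.0, 0.9, 1.1, 0.85, 1.05, 0.8, 0.15, 0.0, 0.0, 0.0]),
    "thigh": ([0, 25, 50, 70, 85, 100],
              [10.0, 5.0, -5.0, 15.0, 15.0, 10.0]),
    "knee": ([0, 20, 40, 55, 70, 85, 100],
             [10.0, 15.0, 30.0, 60.0, 85.0, 40.0, 10.0]),
    "ankle": ([0, 20, 40, 55, 70, 85, 100],
              [15.0, 10.0, 0.0, -15.0, 5.0, 12.0, 15.0]),
}

# Sitting-to-standing and standing-to-sitting combined in a single cycle:
# rise over ~0-50 %, stand, sit back down over ~60-100 %.  There is no swing
# phase, so no swing window is declared and the load never drops to zero.
_STS_KNOTS = {
    "load": ([0, 15, 30, 50, 60, 75, 90, 100],
             [0.3, 0.8, 1.0, 1.0, 1.0, 0.6, 0.35, 0.3]),
    "thigh": ([0, 20, 40, 50, 60, 75, 90, 100],
              [85.0, 60.0, 15.0, 5.0, 5.0, 45.0, 80.0, 85.0]),
    "knee": ([0, 20, 40, 50, 60, 75, 90, 100],
             [90.0, 75.0, 25.0, 5.0, 5.0, 50.0, 85.0, 90.0]),
    "ankle": ([0, 25, 45, 60, 80, 100],
              [5.0, 12.0, 5.0, 2.0, 8.0, 5.0]),
}


@dataclass(frozen=True)
class ModeTemplate:
    """Smooth periodic per-channel curves over phase 0-100 %.

    ``knots`` maps each channel to (phases, values); load values are body
    weight fractions.  ``swing_window`` is the phase interval (lo, hi) where
    the load is near zero, or None for modes without a swing phase.
    """

    name: str
    knots: Dict[str, Tuple[Sequence[float], Sequence[float]]]
    swing_window: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            if ch not in self.knots:
                raise InvalidSpecError(f"template {self.name!r} missing channel {ch}")
            ph, vals = self.knots[ch]
            if len(ph) != len(vals) or len(ph) < 2:
                raise InvalidSpecError("knot phases/values must pair up")
            if ph[0] != 0 or ph[-1] != 100:
                raise InvalidSpecError("knots must span phase 0..100")
            if vals[0] != vals[-1]:
                raise InvalidSpecError(
                    f"template {self.name!r} channel {ch} is not periodic"
                )
        if np.any(np.asarray(self.knots["load"][1]) < 0):
            raise InvalidSpecError("load knots must be non-negative")

    def _interpolators(self):
        return {
            ch: PchipInterpolator(np.asarray(ph, float), np.asarray(v, float))
            for ch, (ph, v) in self.knots.items()
        }

    def curve(self, phases) -> np.ndarray:
        """(len(phases), 4) template values; load in body-weight fraction."""
        phases = np.asarray(phases, dtype=float)
        # wrap out-of-range phases but keep exact 100 at 100, not 0
        phases = np.where(phases == 100.0, 100.0, np.mod(phases, 100.0))
        interp = self._interpolators()
        out = np.column_stack([interp[ch](phases) for ch in CHANNELS])
        return out

    def baseline(self) -> np.ndarray:
        """Per-channel scaling baseline: the curve minimum on the fine grid."""
        grid = np.arange(201) * 0.5
        return self.curve(grid).min(axis=0)


MODE_TEMPLATES: Dict[str, ModeTemplate] = {
    "lgw": ModeTemplate("lgw", _LGW_KNOTS, swing_window=(66.0, 98.0)),
    "stairs_up": ModeTemplate("stairs_up", _STAIRS_UP_KNOTS, swing_window=(70.0, 93.0)),
    "stairs_down": ModeTemplate("stairs_down", _STAIRS_DOWN_KNOTS,
                                swing_window=(68.0, 93.0)),
    "sts": ModeTemplate("sts", _STS_KNOTS, swing_window=None),
}


def get_template(mode: Union[str, ModeTemplate]) -> ModeTemplate:
    if isinstance(mode, ModeTemplate):
        return mode
    try:
        return MODE_TEMPLATES[mode]
    except KeyError:
        raise InvalidSpecError(
            f"unknown mode {mode!r}; available: {sorted(MODE_TEMPLATES)}"
        ) from None


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSubject:
    """Subject-level variability parameters.

    ``amplitude`` scales each channel about the template baseline (the
    channel's curve minimum), ``phase_jitter`` is the std of the smooth
    monotone time warp's interior-knot perturbation (% gait cycle), and
    ``noise_std`` is additive white noise per channel (kg, deg, deg, deg).
    The defaults are the identity subject: sampling with them reproduces
    the template exactly.
    """

    weight: float = 70.0
    amplitude: Tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    phase_jitter: float = 0.0
    noise_std: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise InvalidSpecError("weight must be positive")
        if any(a <= 0 for a in self.amplitude):
            raise InvalidSpecError("amplitude scales must be positive")
        if self.phase_jitter < 0 or any(s < 0 for s in self.noise_std):
            raise InvalidSpecError("jitter/noise stds must be non-negative")

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "SyntheticSubject":
        """Draw a random subject representative of a benchmark cohort.

        Weight uniform on 55-95 kg, per-channel amplitude scales uniform on
        0.85-1.15, 1 % phase jitter, and small sensor-level noise (0.5 kg on
        the load cell, 0.5 deg on angles).
        """
        return cls(
            weight=float(rng.uniform(55.0, 95.0)),
            amplitude=tuple(rng.uniform(0.85, 1.15, size=4)),
            phase_jitter=1.0,
            noise_std=(0.5, 0.5, 0.5, 0.5),
        )


def _phase_warp(rng: np.random.Generator, jitter: float):
    """Smooth monotone warp [0,100] -> [0,100] with fixed endpoints.

    Interior anchors at 20/40/60/80 % are perturbed by N(0, jitter) and
    re-sorted with a minimum gap, then a shape-preserving cubic maps phase
    through them.  Endpoints are pinned, so periodicity survives the warp.
    """
    if jitter == 0.0:
        return lambda p: np.asarray(p, dtype=float)
    anchors = np.array([20.0, 40.0, 60.0, 80.0])
    warped = anchors + rng.normal(0.0, jitter, size=anchors.size)
    warped = np.clip(np.sort(warped), 1.0, 99.0)
    # enforce a strictly increasing sequence with 1% minimum spacing
    for i in range(1, warped.size):
        warped[i] = max(warped[i], warped[i - 1] + 1.0)
    warped = np.clip(warped, 1.0, 99.0)
    x = np.concatenate([[0.0], anchors, [100.0]])
    y = np.concatenate([[0.0], warped, [100.0]])
    interp = PchipInterpolator(x, y)
    return lambda p: np.asarray(interp(np.asarray(p, dtype=float)))


def _realize(
    tmpl: ModeTemplate,
    subj: SyntheticSubject,
    phases: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    phases = np.asarray(phases, dtype=float)
    phases = np.where(phases == 100.0, 100.0, np.mod(phases, 100.0))
    warp = _phase_warp(rng, subj.phase_jitter)
    vals = tmpl.curve(warp(phases))
    vals[:, 0] *= subj.weight  # load: body-weight fraction -> kg
    base = tmpl.baseline()
    base[0] *= subj.weight
    amp = np.asarray(subj.amplitude)
    vals = base[None, :] + amp[None, :] * (vals - base[None, :])
    noise = np.asarray(subj.noise_std)
    if np.any(noise > 0):
        vals = vals + rng.normal(0.0, 1.0, size=vals.shape) * noise[None, :]
    return vals


def sample_pattern(
    tmpl: Union[str, ModeTemplate],
    subj: SyntheticSubject = SyntheticSubject(),
    rng_seed: int = 0,
) -> GaitPattern:
    """One subject-specific 201-row pattern realization (deterministic per seed)."""
    tmpl = get_template(tmpl)
    rng = np.random.default_rng(rng_seed)
    phases = np.arange(201) * 0.5
    return GaitPattern(_realize(tmpl, subj, phases, rng), units="physical")


def sample_trial(
    tmpl: Union[str, ModeTemplate],
    subj: SyntheticSubject = SyntheticSubject(),
    n_cycles: int = 5,
    cycle_duration: float = 1.0,
    rng_seed: int = 0,
    phase_offset: float = 50.0,
) -> RawTrial:
    """Concatenate per-cycle realizations into a 5-ms-sampled raw trial.

    Each cycle gets its own warp/noise realization; phases are sampled on
    [0, 100) so periodic templates concatenate continuously.  Trial length
    is ``n_cycles * round(cycle_duration / 0.005)`` samples.

    ``phase_offset`` shifts where the recording starts within the cycle
    (default mid-stance): real recordings rarely begin exactly at heel
    strike, and starting away from the load peak also keeps the first
    landmark clear of the peak detector's warm-up window.
    """
    tmpl = get_template(tmpl)
    if n_cycles < 2:
        raise DataError("a trial needs at least 2 cycles for segmentation")
    if cycle_duration <= 0:
        raise InvalidSpecError("cycle_duration must be positive")
    rng = np.random.default_rng(rng_seed)
    n = int(round(cycle_duration / SAMPLE_PERIOD))
    phases = np.linspace(0.0, 100.0, n, endpoint=False) + phase_offset
    chunks = [_realize(tmpl, subj, phases, rng) for _ in range(n_cycles)]
    return RawTrial(np.vstack(chunks), sample_period=SAMPLE_PERIOD,
                    weight=subj.weight, mode=tmpl.name)


def make_corpus(
    modes: Sequence[Union[str, ModeTemplate]] = ("lgw",),
    subjects: Union[int, Sequence[SyntheticSubject]] = 5,
    reps: int = 10,
    rng_seed: int = 0,
    spec: NormalizationSpec = NormalizationSpec(load_gain_mode="benchmark"),
) -> List[Tuple[DiscretizedPattern, GaitPattern]]:
    """Normalized (sketch, target) training pairs for the generative model.

    For every mode x subject x rep a pattern is sampled, normalized with the
    subject's weight, its 11-node sketch extracted, and the 200-row form
    kept as the target.  Returns ``|modes| * |subjects| * reps`` pairs.
    """
    if len(modes) == 0 or reps < 1:
        raise InvalidSpecError("corpus config must be non-empty")
    rng = np.random.default_rng(rng_seed)
    if isinstance(subjects, int):
        if subjects < 1:
            raise InvalidSpecError("need at least one subject")
        subjects = [SyntheticSubject.sample(rng) for _ in range(subjects)]
    pairs: List[Tuple[DiscretizedPattern, GaitPattern]] = []
    for tmpl in map(get_template, modes):
        for subj in subjects:
            for _ in range(reps):
                seed = int(rng.integers(0, 2**31 - 1))
                p = sample_pattern(tmpl, subj, rng_seed=seed)
                p_n = normalize_pattern(p, spec, weight=subj.weight)
                pairs.append((discretize(p_n), p_n.drop_final_node()))
    return pairs
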