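"""Impedance-parameter prediction networks and the impedance law.

Two small sequence networks are trained independently on sliding windows of
the synthetic time-series corpora:

* the **equilibrium network** maps a 250 ms history (50 samples at 5 ms) of
  thigh angle and vertical load to the knee and ankle angles 100 ms
  (20 samples) ahead, which serve as the equilibrium angles of the
  impedance law;
* the **stiffness/damping network** maps a 250 ms history of all four gait
  channels to the four normalized impedance values (k_knee, b_knee,
  k_ankle, b_ankle) at the window's final sample.

Both end in sigmoid units, so raw outputs live in (0, 1); equilibrium
outputs are rescaled into the mechanical clamp ranges ([0, 120] deg knee,
[-8, 8] deg ankle) and stiffness/damping outputs into the physical
parameter ranges.  The low-level law converts a command into joint torque:

    tau = -K (theta - theta_eq) - b * theta_dot
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CHANNELS, DataError, InvalidSpecError, TimeSeriesGait, \
    denormalize_value, ANGLE_GAIN
from .nn import (
    Adam,
    Conv1D,
    Dense,
    GaussianNoise,
    LSTM,
    RMSProp,
    Sequential,
    mse_loss,
)
from .timeseries import ImpedanceRanges, scale_to_physical

__all__ = [
    "WindowConfig",
    "NetSpec",
    "EQ_NET_SPEC",
    "KB_NET_SPEC",
    "ClampRanges",
    "JointState",
    "ImpedanceCommand",
    "ControllerCorpus",
    "make_windows",
    "windows_from_datasets",
    "build_eq_net",
    "build_kb_net",
    "train_controllers",
    "clamp_equilibrium",
    "predict_command",
    "impedance_torque",
]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry at the fixed 5 ms sample period."""

    history: int = 50      # 250 ms
    lookahead: int = 20    # 100 ms
    sample_period: float = 0.005

    def __post_init__(self) -> None:
        if self.history < 1 or self.lookahead < 0:
            raise InvalidSpecError("history must be >= 1 and lookahead >= 0")


@dataclass(frozen=True)
class NetSpec:
    """Shared architecture of the two controller networks."""

    in_channels: int = 2
    noise_std: float = 0.02
    conv_filters: int = 32
    conv_kernel: int = 8
    lstm_units: int = 20
    dense_widths: Tuple[int, ...] = (30, 10)
    out_width: int = 2
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 15
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.out_width not in (2, 4):
            raise InvalidSpecError("controller output width is fixed at 2 or 4")
        if self.optimizer not in ("adam", "rmsprop"):
            raise InvalidSpecError(f"unknown optimizer {self.optimizer!r}")


EQ_NET_SPEC = NetSpec(in_channels=2, out_width=2, optimizer="adam")
KB_NET_SPEC = NetSpec(in_channels=4, out_width=4, optimizer="rmsprop")


@dataclass(frozen=True)
class ClampRanges:
    """Mechanical equilibrium-angle limits (degrees)."""

    knee: Tuple[float, float] = (0.0, 120.0)
    ankle: Tuple[float, float] = (-8.0, 8.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.knee, self.ankle):
            if not lo < hi:
                raise InvalidSpecError("clamp ranges need low < high")


@dataclass(frozen=True)
class JointState:
    """Instantaneous joint state: angle (deg) and angular velocity (deg/s)."""

    joint: str
    angle: float
    velocity: float

    def __post_init__(self) -> None:
        if self.joint not in ("knee", "ankle"):
            raise InvalidSpecError(f"unknown joint {self.joint!r}")
        if not (np.isfinite(self.angle) and np.isfinite(self.velocity)):
            raise DataError("joint state must be finite")


@dataclass(frozen=True)
class ImpedanceCommand:
    """Physical-unit impedance parameters for knee and ankle.

    Equilibrium angles are clamped degrees; stiffness (Nm/deg) and damping
    (Nm*s/deg) lie inside their mechanical ranges.
    """

    theta_eq_knee: float
    theta_eq_ankle: float
    k_knee: float
    b_knee: float
    k_ankle: float
    b_ankle: float

    def for_joint(self, joint: str) -> Tuple[float, float, float]:
        if joint == "knee":
            return self.k_knee, self.b_knee, self.theta_eq_knee
        if joint == "ankle":
            return self.k_ankle, self.b_ankle, self.theta_eq_ankle
        raise InvalidSpecError(f"unknown joint {joint!r}")


@dataclass
class ControllerCorpus:
    """Windowed training arrays for the two networks.

    ``eq_x`` is (N, history, 2) thigh/load histories, ``eq_y`` (N, 2) the
    future knee/ankle angles in degrees; ``kb_x`` is (N, history, 4)
    thigh/knee/ankle/load histories and ``kb_y`` (N, 4) the normalized
    impedance targets at the window end.
    """

    eq_x: np.ndarray
    eq_y: np.ndarray
    kb_x: np.ndarray
    kb_y: np.ndarray

    def __len__(self) -> int:
        return self.eq_x.shape[0]

    @staticmethod
    def concatenate(parts: Sequence["ControllerCorpus"]) -> "ControllerCorpus":
        return ControllerCorpus(
            *(np.concatenate([getattr(p, k) for p in parts])
              for k in ("eq_x", "eq_y", "kb_x", "kb_y"))
        )


_EQ_INPUTS = ("thigh", "load")
_KB_INPUTS = ("thigh", "knee", "ankle", "load")


def make_windows(
    series: TimeSeriesGait, cfg: WindowConfig = WindowConfig()
) -> ControllerCorpus:
    """Slide history windows over a normalized series with impedance channels.

    Window i covers samples [i, i + history); its equilibrium target is the
    knee/ankle pair ``lookahead`` samples past the window end (converted
    from normalized units to degrees with the joint-angle gain), and its
    impedance target is the normalized impedance vector at the window's
    final sample.  A series of length N yields N - history - lookahead + 1
    windows.
    """
    n = len(series)
    h, la = cfg.history, cfg.lookahead
    n_win = n - h - la + 1
    if n_win < 1:
        raise DataError(
            f"series of {n} samples is too short for history {h} + lookahead {la}"
        )
    if series.impedance is None:
        raise DataError("controller corpus requires aligned impedance channels")

    idx = {name: CHANNELS.index(name) for name in CHANNELS}
    win = np.lib.stride_tricks.sliding_window_view(series.gait, h, axis=0)
    win = win[:n_win]                       # (n_win, 4, h)
    eq_x = np.stack([win[:, idx[c], :] for c in _EQ_INPUTS], axis=2)
    kb_x = np.stack([win[:, idx[c], :] for c in _KB_INPUTS], axis=2)

    ends = np.arange(n_win) + h - 1
    target_norm = series.gait[ends + la][:, [idx["knee"], idx["ankle"]]]
    eq_y = denormalize_value(target_norm, ANGLE_GAIN)
    kb_y = series.impedance[ends]
    return ControllerCorpus(eq_x, eq_y, kb_x, kb_y)


def windows_from_datasets(
    datasets: Sequence[TimeSeriesGait],
    cfg: WindowConfig = WindowConfig(),
    stride: int = 1,
) -> ControllerCorpus:
    """Pool windows from several series, optionally thinned by ``stride``."""
    parts = []
    for s in datasets:
        c = make_windows(s, cfg)
        if stride > 1:
            c = ControllerCorpus(c.eq_x[::stride], c.eq_y[::stride],
                                 c.kb_x[::stride], c.kb_y[::stride])
        parts.append(c)
    return ControllerCorpus.concatenate(parts)


def _build_net(spec: NetSpec, seed: int) -> Sequential:
    rng = np.random.default_rng(seed)
    layers = [
        GaussianNoise(spec.noise_std, rng=np.random.default_rng(seed + 1)),
        Conv1D(spec.in_channels, spec.conv_filters, spec.conv_kernel, 1,
               activation="sigmoid", rng=rng),
        LSTM(spec.conv_filters, spec.lstm_units, activation="sigmoid", rng=rng),
    ]
    w = spec.lstm_units
    for d in spec.dense_widths:
        layers.append(Dense(w, d, activation="sigmoid", rng=rng))
        w = d
    layers.append(Dense(w, spec.out_width, activation="sigmoid", rng=rng))
    return Sequential(layers)


def build_eq_net(spec: NetSpec = EQ_NET_SPEC, seed: int = 0) -> Sequential:
    """(history, 2) -> 2 sigmoid units, rescaled to clamp ranges downstream."""
    if spec.out_width != 2:
        raise InvalidSpecError("equilibrium network must output 2 values")
    return _build_net(spec, seed)


def build_kb_net(spec: NetSpec = KB_NET_SPEC, seed: int = 0) -> Sequential:
    """(history, 4) -> 4 sigmoid units in (0, 1)."""
    if spec.out_width != 4:
        raise InvalidSpecError("stiffness/damping network must output 4 values")
    return _build_net(spec, seed)


def _eq_targets_to_unit(eq_y_deg: np.ndarray, clamps: ClampRanges) -> np.ndarray:
    # targets are clamped into the command ranges first: an equilibrium the
    # actuator can never be commanded to reach is not a meaningful target
    out = np.empty_like(eq_y_deg)
    for j, (lo, hi) in enumerate((clamps.knee, clamps.ankle)):
        out[:, j] = (np.clip(eq_y_deg[:, j], lo, hi) - lo) / (hi - lo)
    return out


def eq_unit_to_degrees(unit: np.ndarray, clamps: ClampRanges = ClampRanges()):
    """Map the equilibrium net's (0,1) outputs into degrees."""
    unit = np.atleast_2d(np.asarray(unit, dtype=float))
    out = np.empty_like(unit)
    for j, (lo, hi) in enumerate((clamps.knee, clamps.ankle)):
        out[:, j] = lo + unit[:, j] * (hi - lo)
    return out


def _train_one(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    spec: NetSpec,
    rng: np.random.Generator,
    out_scale: Optional[np.ndarray] = None,
) -> List[float]:
    """MSE training loop; ``out_scale`` expresses each sigmoid output in its
    physical units (chain rule through the linear range map), so the loss is
    an MSE in those units rather than in raw (0,1) space."""
    opt = Adam(model, lr=spec.learning_rate) if spec.optimizer == "adam" \
        else RMSProp(model, lr=spec.learning_rate)
    trace = []
    n = x.shape[0]
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            pred = model.forward(x[idx], train=True)
            if out_scale is None:
                loss, grad = mse_loss(pred, y[idx])
            else:
                loss, grad = mse_loss(pred * out_scale, y[idx] * out_scale)
                grad = grad * out_scale
            model.backward(grad)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if not np.isfinite(trace[-1]):
            raise FloatingPointError(
                f"non-finite training loss at epoch {len(trace)}"
            )
    return trace


def train_controllers(
    corpus: ControllerCorpus,
    eq_spec: NetSpec = EQ_NET_SPEC,
    kb_spec: NetSpec = KB_NET_SPEC,
    seed: int = 0,
    clamps: ClampRanges = ClampRanges(),
    kb_corpus: Optional[ControllerCorpus] = None,
) -> Tuple[Sequential, Sequential, Dict[str, List[float]]]:
    """Train the two networks independently (MSE, 15 epochs, batch 256).

    Equilibrium targets are clamped into the command ranges and scaled into
    the networks' (0, 1) output space, so the sigmoid head enforces the
    mechanical limits structurally; the equilibrium loss itself is an MSE
    in degrees (each output weighted by its clamp-range width via the chain
    rule), so the knee, with its 120-degree range, is not drowned out by
    the ankle.  The two networks train independently and need not share
    data; ``kb_corpus``, when given, supplies the stiffness/damping
    network's windows (e.g. a thinned set — its map is far easier to fit
    than the equilibrium map).  Returns (eq_net, kb_net, loss traces); the
    eq trace is in squared degrees.
    """
    if len(corpus) == 0:
        raise DataError("controller corpus is empty")
    kb_corpus = kb_corpus if kb_corpus is not None else corpus
    rng = np.random.default_rng(seed)
    eq_net = build_eq_net(eq_spec, seed=int(rng.integers(2**31 - 1)))
    kb_net = build_kb_net(kb_spec, seed=int(rng.integers(2**31 - 1)))
    eq_y_unit = _eq_targets_to_unit(corpus.eq_y, clamps)
    eq_scale = np.array([clamps.knee[1] - clamps.knee[0],
                         clamps.ankle[1] - clamps.ankle[0]])
    history = {
        "eq": _train_one(eq_net, corpus.eq_x, eq_y_unit, eq_spec, rng,
                         out_scale=eq_scale),
        "kb": _train_one(kb_net, kb_corpus.kb_x, kb_corpus.kb_y, kb_spec, rng),
    }
    return eq_net, kb_net, history


def clamp_equilibrium(
    knee_deg: float, ankle_deg: float, clamps: ClampRanges = ClampRanges()
) -> Tuple[float, float]:
    """Hard-limit raw equilibrium angles to the mechanical ranges."""
    return (
        float(np.clip(knee_deg, *clamps.knee)),
        float(np.clip(ankle_deg, *clamps.ankle)),
    )


def predict_command(
    eq_history: np.ndarray,
    kb_history: np.ndarray,
    eq_net: Sequential,
    kb_net: Sequential,
    ranges: ImpedanceRanges = ImpedanceRanges(),
    clamps: ClampRanges = ClampRanges(),
) -> ImpedanceCommand:
    """One inference step: histories -> physical impedance command.

    ``eq_history`` is (history, 2) thigh/load, ``kb_history`` (history, 4)
    thigh/knee/ankle/load, both in normalized units.  Noise layers are
    inactive at inference, so the map is deterministic; every output field
    is guaranteed inside its clamp/range bounds.
    """
    eq_history = np.asarray(eq_history, dtype=float)
    kb_history = np.asarray(kb_history, dtype=float)
    if eq_history.ndim != 2 or eq_history.shape[1] != 2:
        raise DataError("eq history must be (history, 2)")
    if kb_history.ndim != 2 or kb_history.shape[1] != 4:
        raise DataError("kb history must be (history, 4)")
    eq_unit = eq_net.forward(eq_history[None])[0]
    eq_deg = eq_unit_to_degrees(eq_unit[None], clamps)[0]
    theta_knee, theta_ankle = clamp_equilibrium(eq_deg[0], eq_deg[1], clamps)
    kb = kb_net.forward(kb_history[None])[0]
    return ImpedanceCommand(
        theta_eq_knee=theta_knee,
        theta_eq_ankle=theta_ankle,
        k_knee=scale_to_physical(float(kb[0]), "knee", "stiffness", ranges),
        b_knee=scale_to_physical(float(kb[1]), "knee", "damping", ranges),
        k_ankle=scale_to_physical(float(kb[2]), "ankle", "stiffness", ranges),
        b_ankle=scale_to_physical(float(kb[3]), "ankle", "damping", ranges),
    )


def impedance_torque(state: JointState, cmd: ImpedanceCommand) -> float:
    """Joint torque of the impedance law: tau = -K (theta - theta_eq) - b w."""
    k, b, theta_eq = cmd.for_joint(state.joint)
    return float(-k * (state.angle - theta_eq) - b * state.velocity)


def save_controllers(path, eq_net: Sequential, kb_net: Sequential) -> None:
    """Persist both networks' weights to a single .npz checkpoint."""
    arrays = {}
    for tag, model in (("eq", eq_net), ("kb", kb_net)):
        for i, layer in enumerate(model.layers):
            for k, v in layer.params.items():
                arrays[f"{tag}{i}_{k}"] = v
    np.savez(path, **arrays)


def load_controllers(
    path,
    eq_spec: NetSpec = EQ_NET_SPEC,
    kb_spec: NetSpec = KB_NET_SPEC,
) -> Tuple[Sequential, Sequential]:
    """Rebuild both networks from a checkpoint by :func:`save_controllers`."""
    data = np.load(path)
    eq_net = build_eq_net(eq_spec)
    kb_net = build_kb_net(kb_spec)
    for tag, model in (("eq", eq_net), ("kb", kb_net)):
        for i, layer in enumerate(model.layers):
            for k in layer.params:
                layer.params[k][...] = data[f"{tag}{i}_{k}"]
    return eq_net, kb_net
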