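"""Conditional generative model for gait patterns.

A Pix2Pix-style conditional GAN translates a linearly interpolated 11-node
sketch (the condition, 200 x 4 normalized) into a continuous 200 x 4 gait
pattern.  The generator is a stride-2 conv encoder (16-32-64 filters) and
transposed-conv decoder (32-16-4), followed by a width-200 dense layer with
sigmoid applied along the phase axis per channel, so outputs live in (0, 1).
The discriminator consumes condition and candidate concatenated along the
channel axis through three stride-2 convs (16-32-64) and an 80-unit LSTM
with LeakyReLU cell activation, ending in a scalar realness logit.

The generator objective keeps the Pix2Pix structure: the adversarial term
plus a lambda-weighted mean-absolute-error reconstruction term
(lambda = 1000 by default).  There is no latent noise input, so generation
is deterministic given the sketch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .core import (
    DataError,
    DiscretizedPattern,
    GaitPattern,
    InvalidSpecError,
    N_CHANNELS,
    interpolate_input,
)
from .nn import (
    Adam,
    Conv1D,
    ConvTranspose1D,
    Dense,
    LSTM,
    PhaseDense,
    Sequential,
    bce_with_logits,
    mae_loss,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "GANConfig",
    "TrainState",
    "build_generator",
    "build_discriminator",
    "gan_loss",
    "train",
    "generate",
    "smooth_output",
    "save_gan",
    "load_gan",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Encoder/decoder filter counts and the trailing dense width."""

    input_len: int = 200
    encoder_filters: Tuple[int, ...] = (16, 32, 64)
    decoder_filters: Tuple[int, ...] = (32, 16, 4)
    dense_width: int = 200
    kernel: int = 2
    stride: int = 2

    def __post_init__(self) -> None:
        down = self.stride ** len(self.encoder_filters)
        if self.input_len % down != 0:
            raise InvalidSpecError(
                f"input length {self.input_len} must be divisible by {down} "
                f"(reduced to 1/{down} through the encoder)"
            )
        if self.decoder_filters[-1] != N_CHANNELS:
            raise InvalidSpecError("last decoder stage must restore 4 channels")


@dataclass(frozen=True)
class DiscriminatorSpec:
    conv_filters: Tuple[int, ...] = (16, 32, 64)
    lstm_units: int = 80
    kernel: int = 2
    stride: int = 2


@dataclass(frozen=True)
class GANConfig:
    """Training hyperparameters.

    The printed defaults (lr 0.01, batch 64, 500 epochs, lambda 1000) are
    kept; ``learning_rate`` is exposed because 0.01 can diverge on some
    corpora, in which case 1e-3 is the documented fallback.
    """

    lambda_l1: float = 1000.0
    epochs: int = 500
    batch_size: int = 64
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise InvalidSpecError("lambda_l1 must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidSpecError("epochs and batch_size must be >= 1")


@dataclass
class TrainState:
    """Per-epoch loss traces recorded during adversarial training."""

    epochs: int = 0
    g_loss: List[float] = field(default_factory=list)
    g_adv: List[float] = field(default_factory=list)
    recon_mae: List[float] = field(default_factory=list)
    d_loss: List[float] = field(default_factory=list)

    def check_finite(self) -> None:
        for name in ("g_loss", "d_loss"):
            trace = getattr(self, name)
            if trace and not np.isfinite(trace[-1]):
                raise FloatingPointError(
                    f"non-finite {name} at epoch {len(trace)}; training aborted"
                )


def build_generator(
    spec: GeneratorSpec = GeneratorSpec(), seed: int = 0
) -> Sequential:
    """Sketch-to-pattern network: (B, 200, 4) -> (B, 200, 4) in (0, 1)."""
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = N_CHANNELS
    for f in spec.encoder_filters:
        layers.append(Conv1D(in_ch, f, spec.kernel, spec.stride,
                             activation="leaky_relu", rng=rng))
        in_ch = f
    for f in spec.decoder_filters:
        layers.append(ConvTranspose1D(in_ch, f, spec.kernel, spec.stride,
                                      activation="leaky_relu", rng=rng))
        in_ch = f
    layers.append(PhaseDense(spec.input_len, spec.dense_width,
                             activation="sigmoid", rng=rng))
    return Sequential(layers)


def build_discriminator(
    spec: DiscriminatorSpec = DiscriminatorSpec(), seed: int = 0
) -> Sequential:
    """Joint (condition, candidate) -> realness logit network.

    Inputs are concatenated along the channel axis before the first conv
    (the Pix2Pix conditioning convention), so the network sees (B, 200, 8).
    """
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = 2 * N_CHANNELS
    for f in spec.conv_filters:
        layers.append(Conv1D(in_ch, f, spec.kernel, spec.stride,
                             activation="leaky_relu", rng=rng))
        in_ch = f
    layers.append(LSTM(in_ch, spec.lstm_units, activation="leaky_relu", rng=rng))
    layers.append(Dense(spec.lstm_units, 1, activation="linear", rng=rng))
    return Sequential(layers)


def discriminate(disc: Sequential, condition: np.ndarray, candidate: np.ndarray,
                 train: bool = False) -> np.ndarray:
    if condition.shape != candidate.shape:
        raise DataError("condition and candidate shapes must match")
    return disc.forward(np.concatenate([condition, candidate], axis=2), train=train)


def gan_loss(
    real: np.ndarray,
    fake: np.ndarray,
    real_logits: np.ndarray,
    fake_logits: np.ndarray,
    cfg: GANConfig = GANConfig(),
) -> Tuple[float, float]:
    """(generator loss, discriminator loss) of the conditional objective.

    Generator: BCE(fake logits, 1) + lambda * MAE(real, fake).
    Discriminator: BCE(real logits, 1) + BCE(fake logits, 0).
    """
    adv, _ = bce_with_logits(fake_logits, 1.0)
    recon, _ = mae_loss(fake, real)
    d_real, _ = bce_with_logits(real_logits, 1.0)
    d_fake, _ = bce_with_logits(fake_logits, 0.0)
    return adv + cfg.lambda_l1 * recon, d_real + d_fake


def _accumulate(model: Sequential, stash: Optional[list]) -> list:
    if stash is None:
        return [{k: g.copy() for k, g in layer.grads.items()}
                for layer in model.layers]
    for layer, st in zip(model.layers, stash):
        for k, g in layer.grads.items():
            st[k] += g
    return stash


def _restore_grads(model: Sequential, stash: list) -> None:
    for layer, st in zip(model.layers, stash):
        layer.grads = st


def train(
    corpus: Sequence[Tuple[DiscretizedPattern, GaitPattern]],
    cfg: GANConfig = GANConfig(),
    gen_spec: GeneratorSpec = GeneratorSpec(),
    disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
) -> Tuple[Sequential, Sequential, TrainState]:
    """Alternating adversarial training on (sketch, target) pairs.

    Batch order and weight initialization are fully determined by
    ``cfg.seed``.  Raises ``FloatingPointError`` on a NaN loss, leaving the
    recorded traces in the returned state for diagnosis.
    """
    if len(corpus) == 0:
        raise DataError("training corpus is empty")
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(gen_spec, seed=int(rng.integers(2**31 - 1)))
    disc = build_discriminator(disc_spec, seed=int(rng.integers(2**31 - 1)))
    g_opt = Adam(gen, lr=cfg.learning_rate)
    d_opt = Adam(disc, lr=cfg.learning_rate)

    conds = np.stack([interpolate_input(s).values for s, _ in corpus])
    reals = np.stack([t.values for _, t in corpus])
    n = conds.shape[0]
    state = TrainState()

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        ep = {"g": [], "adv": [], "mae": [], "d": []}
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            cond, real = conds[idx], reals[idx]

            # --- discriminator update on real and fake pairs
            fake = gen.forward(cond)
            real_logits = discriminate(disc, cond, real, train=True)
            d_real, d_grad = bce_with_logits(real_logits, 1.0)
            disc.backward(d_grad)
            stash = _accumulate(disc, None)
            fake_logits = discriminate(disc, cond, fake, train=True)
            d_fake, d_grad = bce_with_logits(fake_logits, 0.0)
            disc.backward(d_grad)
            stash = _accumulate(disc, stash)
            _restore_grads(disc, stash)
            d_opt.step()

            # --- generator update through the (frozen) discriminator
            fake = gen.forward(cond, train=True)
            fake_logits = discriminate(disc, cond, fake)
            adv, dlogit = bce_with_logits(fake_logits, 1.0)
            recon, drecon = mae_loss(fake, real)
            djoint = disc.backward(dlogit)
            dfake = djoint[:, :, N_CHANNELS:] + cfg.lambda_l1 * drecon
            gen.backward(dfake)
            g_opt.step()

            g_total, d_total = gan_loss(real, fake, real_logits, fake_logits, cfg)
            ep["g"].append(g_total)
            ep["adv"].append(adv)
            ep["mae"].append(recon)
            ep["d"].append(d_total)

        state.epochs += 1
        state.g_loss.append(float(np.mean(ep["g"])))
        state.g_adv.append(float(np.mean(ep["adv"])))
        state.recon_mae.append(float(np.mean(ep["mae"])))
        state.d_loss.append(float(np.mean(ep["d"])))
        state.check_finite()

    return gen, disc, state


def generate(sketch: DiscretizedPattern, generator: Sequential) -> GaitPattern:
    """Forward a normalized sketch through the generator.

    The sketch is linearly interpolated onto the 200-row grid and
    translated; there is no noise input, so the map is deterministic.
    """
    if generator is None:
        raise DataError("no trained generator supplied")
    cond = interpolate_input(sketch).values[None]
    out = generator.forward(cond)[0]
    return GaitPattern(out, units="normalized")


def smooth_output(p: GaitPattern, smoothing: float = 0.1) -> GaitPattern:
    """Cubic smoothing spline per channel, evaluated back on the same grid.

    ``smoothing`` follows the p-convention of penalized smoothing splines
    (p * SSE + (1-p) * roughness): p=1 interpolates the data, p -> 0 tends
    to the least-squares line.  Internally this maps to the equivalent
    roughness weight lam = (1-p)/p of scipy's smoothing-spline objective.
    """
    if not 0.0 < smoothing <= 1.0:
        raise InvalidSpecError("smoothing parameter must lie in (0, 1]")
    x = p.phase_grid
    out = np.empty_like(p.values)
    lam = (1.0 - smoothing) / smoothing
    for c in range(p.values.shape[1]):
        spl = make_smoothing_spline(x, p.values[:, c], lam=lam)
        out[:, c] = spl(x)
    return GaitPattern(out, units=p.units)


def save_gan(path, gen: Sequential, disc: Optional[Sequential] = None) -> None:
    """Persist generator (and optionally discriminator) weights to .npz."""
    arrays = {}
    for i, layer in enumerate(gen.layers):
        for k, v in layer.params.items():
            arrays[f"g{i}_{k}"] = v
    if disc is not None:
        for i, layer in enumerate(disc.layers):
            for k, v in layer.params.items():
                arrays[f"d{i}_{k}"] = v
    np.savez(path, **arrays)


def load_gan(
    path,
    gen_spec: GeneratorSpec = GeneratorSpec(),
    disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
) -> Tuple[Sequential, Optional[Sequential]]:
    """Rebuild networks from a checkpoint written by :func:`save_gan`."""
    data = np.load(path)
    gen = build_generator(gen_spec)
    for i, layer in enumerate(gen.layers):
        for k in layer.params:
            layer.params[k][...] = data[f"g{i}_{k}"]
    disc = None
    if any(key.startswith("d0_") for key in data.files):
        disc = build_discriminator(disc_spec)
        for i, layer in enumerate(disc.layers):
            for k in layer.params:
                layer.params[k][...] = data[f"d{i}_{k}"]
    return gen, disc
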