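"""End-to-end orchestration with reproducibility plumbing.

``run_pipeline`` chains the stages — synthetic corpus, generator training,
sketch-conditioned generation, time-series dataset building, controller
training, and evaluation — writing every artifact plus a manifest holding
the configuration, the seeds, and a SHA-256 hash of each produced file.
The same configuration and seed reproduce the same manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import yaml

from .controller import (
    EQ_NET_SPEC,
    KB_NET_SPEC,
    WindowConfig,
    save_controllers,
    train_controllers,
    windows_from_datasets,
)
from .core import (
    DataError,
    GaitPattern,
    InvalidSpecError,
    NormalizationSpec,
    discretize,
    normalize_pattern,
    write_pattern_csv,
    write_sketch_csv,
)
from .gan import GANConfig, generate, save_gan, smooth_output, train
from .metrics import SSIMConfig, evaluate_pair
from .synthetic import SyntheticSubject, make_corpus, sample_pattern
from .timeseries import MODE_PRESETS, ModePreset, StitchConfig, build_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("gaitforge")


@dataclass
class PipelineConfig:
    """One document configuring every stage; CLI flags override file values."""

    seed: int = 0
    out_dir: str = "gaitforge_out"
    # synthetic corpus
    modes: Tuple[str, ...] = ("lgw", "stairs_up")
    subjects: int = 5
    reps: int = 10
    # generator training
    gan: GANConfig = field(default_factory=GANConfig)
    # dataset building
    preset_mode: str = "lgw"
    datasets: int = 2
    variations: int = 10
    smoothing: float = 0.1
    # controller training
    window: WindowConfig = field(default_factory=WindowConfig)
    window_stride: int = 1
    # evaluation
    ssim: SSIMConfig = field(default_factory=SSIMConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kwargs = dict(doc)
        for key, sub in (("gan", GANConfig), ("window", WindowConfig),
                         ("ssim", SSIMConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "modes" in kwargs:
            kwargs["modes"] = tuple(kwargs["modes"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise InvalidSpecError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute all stages; returns (and writes) the artifact manifest.

    Any stage failure is re-raised with a stage tag in the message so the
    caller can tell where the run aborted.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    artifacts: List[Path] = []
    stage = "setup"
    try:
        stage = "corpus"
        log.info("building synthetic corpus: %s", cfg.modes)
        corpus_seed = int(rng.integers(2**31 - 1))
        corpus = make_corpus(cfg.modes, cfg.subjects, cfg.reps,
                             rng_seed=corpus_seed)

        stage = "gan-training"
        gan_cfg = dataclasses.replace(cfg.gan, seed=int(rng.integers(2**31 - 1)))
        log.info("training generator: %d pairs, %d epochs",
                 len(corpus), gan_cfg.epochs)
        gen, disc, state = train(corpus, gan_cfg)
        ckpt = out / "gan.npz"
        save_gan(ckpt, gen, disc)
        artifacts.append(ckpt)

        stage = "generation"
        preset = ModePreset(cfg.preset_mode,
                            MODE_PRESETS[cfg.preset_mode].duration_range,
                            variations=cfg.variations, datasets=cfg.datasets)
        tmpl_pattern = sample_pattern(cfg.preset_mode, SyntheticSubject(),
                                      rng_seed=0)
        norm = normalize_pattern(tmpl_pattern, NormalizationSpec(), weight=70.0)
        sketch = discretize(norm)
        sketch_path = out / f"{cfg.preset_mode}_sketch.csv"
        write_sketch_csv(sketch_path, sketch)
        artifacts.append(sketch_path)
        generated = smooth_output(generate(sketch, gen), cfg.smoothing)
        gen_path = out / f"{cfg.preset_mode}_generated.csv"
        write_pattern_csv(gen_path, generated)
        artifacts.append(gen_path)

        stage = "dataset-building"
        data_seed = int(rng.integers(2**31 - 1))
        datasets = build_dataset(
            preset,
            make_pattern=lambda s: generate(s, gen),
            sketch=sketch,
            seed=data_seed,
            stitch_cfg=StitchConfig(seed=data_seed),
            smooth=lambda p: smooth_output(p, cfg.smoothing),
        )
        for i, ts in enumerate(datasets):
            p = out / f"dataset_{i:02d}.csv"
            ts.to_frame().to_csv(p, index=False)
            artifacts.append(p)

        stage = "controller-training"
        windows = windows_from_datasets(datasets, cfg.window,
                                        stride=cfg.window_stride)
        log.info("training controllers on %d windows", len(windows))
        eq_net, kb_net, history = train_controllers(
            windows, seed=int(rng.integers(2**31 - 1))
        )
        ctrl_path = out / "controllers.npz"
        save_controllers(ctrl_path, eq_net, kb_net)
        artifacts.append(ctrl_path)

        stage = "evaluation"
        ref = norm.drop_final_node()
        report = evaluate_pair(ref, generated, ssim_cfg=cfg.ssim)
        report_path = out / "report.json"
        report.to_json(report_path)
        artifacts.append(report_path)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stage_seeds": {"corpus": corpus_seed, "gan": gan_cfg.seed,
                        "dataset": data_seed},
        "gan_final_losses": {"g": state.g_loss[-1], "d": state.d_loss[-1],
                             "recon_mae": state.recon_mae[-1]},
        "controller_final_losses": {k: v[-1] for k, v in history.items()},
        "overall_r2": report.overall_r2,
        "overall_ssim": report.overall_ssim,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
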