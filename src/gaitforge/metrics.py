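"""Evaluation metrics for gait patterns.

Implements the quality measures used to judge synthetic gait patterns
against reference data: coefficient of determination, RMSE, a 1-D
structural similarity index with per-position dissimilarity maps, the
start/end discontinuity of a cyclic pattern, and RMS jerk as a smoothness
measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Literal

import numpy as np

from .core import CHANNELS, DataError, GaitPattern, InvalidSpecError

__all__ = [
    "SSIMConfig",
    "MetricReport",
    "r_squared",
    "rmse",
    "ssim_1d",
    "discontinuity",
    "jerk",
    "evaluate_pair",
]


@dataclass(frozen=True)
class SSIMConfig:
    """Sliding-window SSIM parameters.

    Defaults follow the image-processing convention on normalized (0,1)
    signals: uniform 11-sample window, dynamic range L=1, C1=(0.01 L)^2,
    C2=(0.03 L)^2.
    """

    window: int = 11
    dynamic_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise InvalidSpecError("SSIM window must be odd and >= 3")
        if self.dynamic_range <= 0:
            raise InvalidSpecError("dynamic range must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def r_squared(ref, est) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot about ref's mean."""
    ref = np.asarray(ref, dtype=float).ravel()
    est = np.asarray(est, dtype=float).ravel()
    if ref.shape != est.shape:
        raise DataError("r_squared requires equal-length inputs")
    if ref.size < 2:
        raise DataError("r_squared requires at least two samples")
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("r_squared is undefined for a constant reference")
    ss_res = float(np.sum((ref - est) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(ref, est) -> float:
    """Root-mean-square error, in the channel's own units."""
    ref = np.asarray(ref, dtype=float).ravel()
    est = np.asarray(est, dtype=float).ravel()
    if ref.shape != est.shape:
        raise DataError("rmse requires equal-length inputs")
    return float(np.sqrt(np.mean((ref - est) ** 2)))


def _sliding_windows(x: np.ndarray, w: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, w)


def ssim_1d(ref, est, cfg: SSIMConfig = SSIMConfig()) -> tuple[np.ndarray, float]:
    """Windowed structural similarity along one channel.

    Returns ``(map, overall)`` where ``map`` holds the SSIM of each
    full sliding window (length ``n - window + 1``) and ``overall`` is its
    mean.  ``1 - map`` is the dissimilarity map used for per-phase
    inspection.  Uniform (unweighted) windows; window statistics use the
    sample (divide-by-w-1) convention.
    """
    ref = np.asarray(ref, dtype=float).ravel()
    est = np.asarray(est, dtype=float).ravel()
    if ref.shape != est.shape:
        raise DataError("ssim_1d requires equal-length inputs")
    w = cfg.window
    if ref.size < w:
        raise DataError("ssim_1d window longer than the series")
    rw = _sliding_windows(ref, w)
    ew = _sliding_windows(est, w)
    mu_r = rw.mean(axis=1)
    mu_e = ew.mean(axis=1)
    # unbiased variances/covariance (image-convention, matches scikit-image)
    var_r = rw.var(axis=1, ddof=1)
    var_e = ew.var(axis=1, ddof=1)
    cov = ((rw - mu_r[:, None]) * (ew - mu_e[:, None])).sum(axis=1) / (w - 1)
    c1, c2 = cfg.c1, cfg.c2
    num = (2 * mu_r * mu_e + c1) * (2 * cov + c2)
    den = (mu_r**2 + mu_e**2 + c1) * (var_r + var_e + c2)
    smap = num / den
    return smap, float(smap.mean())


DiscontinuityMode = Literal["benchmark", "generated_raw", "generated_interp"]


def discontinuity(p: GaitPattern, mode: DiscontinuityMode) -> np.ndarray:
    """Per-channel gap between the end and the start of a cyclic pattern.

    * ``benchmark`` (201-row): |last row - first row|; a perfectly periodic
      extracted pattern gives 0.
    * ``generated_raw`` (200-row): |last row - first row| of the generator
      output, which has no 100 % sample.
    * ``generated_interp`` (200-row): the gap after inserting one midpoint
      bridging sample between the last and first rows, i.e. exactly half of
      ``generated_raw``.
    """
    if mode == "benchmark":
        if p.n_rows != 201:
            raise _grid_error(mode, p)
        return np.abs(p.values[-1] - p.values[0])
    if mode == "generated_raw":
        if p.n_rows != 200:
            raise _grid_error(mode, p)
        return np.abs(p.values[-1] - p.values[0])
    if mode == "generated_interp":
        if p.n_rows != 200:
            raise _grid_error(mode, p)
        mid = 0.5 * (p.values[-1] + p.values[0])
        return np.abs(mid - p.values[0])
    raise InvalidSpecError(f"unknown discontinuity mode {mode!r}")


def _grid_error(mode: str, p: GaitPattern) -> DataError:
    return DataError(
        f"discontinuity mode {mode!r} is incompatible with a {p.n_rows}-row pattern"
    )


def jerk(channel, step: float = 0.5) -> float:
    """RMS jerk of one channel over the gait cycle.

    J = sqrt(1/2 * sum of squared third derivatives), with the third
    derivative taken by the central five-point stencil
    (-1/2, 1, 0, -1, 1/2) / step^3 with respect to gait-cycle percent
    (``step`` in percent; pass a time step to differentiate in seconds).
    Boundary samples, where the stencil does not fit, are excluded.
    Constant, linear and quadratic signals give exactly 0.
    """
    x = np.asarray(channel, dtype=float).ravel()
    if x.size < 5:
        raise DataError("jerk requires at least 5 samples for the third difference")
    if step <= 0:
        raise InvalidSpecError("step must be positive")
    d3 = (-0.5 * x[:-4] + x[1:-3] - x[3:-1] + 0.5 * x[4:]) / step**3
    return float(np.sqrt(0.5 * np.sum(d3**2)))


@dataclass
class MetricReport:
    """Per-channel metric summary for a (reference, estimate) pattern pair."""

    r2: Dict[str, float]
    rmse: Dict[str, float]
    ssim: Dict[str, float]
    ssim_map: Dict[str, list]
    jerk_ref: Dict[str, float]
    jerk_est: Dict[str, float]
    discontinuity_ref: Dict[str, float]
    discontinuity_est: Dict[str, float]
    overall_r2: float = field(default=float("nan"))
    overall_ssim: float = field(default=float("nan"))

    def to_json(self, path=None) -> str:
        payload = {"schema": "gaitforge-metric-report/1", **self.__dict__}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "MetricReport":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        payload.pop("schema", None)
        return cls(**payload)


def evaluate_pair(
    ref: GaitPattern,
    est: GaitPattern,
    ssim_cfg: SSIMConfig = SSIMConfig(),
    jerk_step: float = 0.5,
) -> MetricReport:
    """All metrics for a compatible (reference, estimate) pattern pair.

    Discontinuity uses the mode matching each pattern's own row count
    (``benchmark`` for 201 rows, ``generated_raw`` for 200).
    """
    if ref.n_rows != est.n_rows:
        raise DataError("evaluate_pair requires patterns on the same grid")
    r2 = {}
    errs = {}
    ssims = {}
    smaps = {}
    j_ref = {}
    j_est = {}
    for i, name in enumerate(CHANNELS):
        r = ref.values[:, i]
        e = est.values[:, i]
        r2[name] = r_squared(r, e)
        errs[name] = rmse(r, e)
        smap, s = ssim_1d(r, e, ssim_cfg)
        ssims[name] = s
        smaps[name] = smap.tolist()
        j_ref[name] = jerk(r, jerk_step)
        j_est[name] = jerk(e, jerk_step)
    mode = "benchmark" if ref.n_rows == 201 else "generated_raw"
    d_ref = dict(zip(CHANNELS, discontinuity(ref, mode)))
    d_est = dict(zip(CHANNELS, discontinuity(est, mode)))
    return MetricReport(
        r2=r2,
        rmse=errs,
        ssim=ssims,
        ssim_map=smaps,
        jerk_ref=j_ref,
        jerk_est=j_est,
        discontinuity_ref=d_ref,
        discontinuity_est=d_est,
        overall_r2=float(np.mean(list(r2.values()))),
        overall_ssim=float(np.mean(list(ssims.values()))),
    )
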