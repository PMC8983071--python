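"""Quantitative evaluation: PSNR, windowed SSIM, and the degradation protocol.

Because registered clinical/micro pairs do not exist, the quantitative
protocol degrades each micro-domain HR image with bicubic interpolation to
the LR size, super-resolves it with the trained G1, and compares the result
against the original HR image.

PSNR uses the normalized data range 2.0 by default and reports identical
images at a 100 dB cap so means stay finite.  The reference SSIM is the
windowed standard form (11×11 Gaussian window, σ = 1.5); the global-moment
form used inside the training loss is logged alongside for transparency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .imaging import ImagePatch, bicubic_resample, nearest_upsample
from .losses import SSIMConstants, ssim_global
from .training import infer

__all__ = ["EvalReport", "psnr", "ssim_windowed", "evaluate_protocol", "evaluate_pairs"]

PSNR_CAP_DB = 100.0


@dataclass
class EvalReport:
    """Per-image and mean PSNR/SSIM of one evaluation run."""

    psnr_values: list[float]
    ssim_values: list[float]
    ssim_global_values: list[float]
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.psnr_values)

    @property
    def mean_psnr(self) -> float:
        return float(np.mean(self.psnr_values))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim_values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "psnr": self.psnr_values,
                "ssim": self.ssim_values,
                "ssim_global": self.ssim_global_values,
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "n": self.n,
            "mean_psnr": self.mean_psnr,
            "mean_ssim": self.mean_ssim,
            "per_image": self.to_frame().to_dict(orient="list"),
            "config": self.config,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def psnr(a, b, data_range: float = 2.0) -> float:
    """10·log10(range² / MSE) in dB; zero-MSE reported as the 100 dB cap."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(data_range**2 / mse))


def ssim_windowed(a, b, data_range: float = 2.0) -> float:
    """Mean local SSIM over an 11×11 Gaussian window (σ = 1.5)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError("images must be at least 11x11 for windowed SSIM")
    return float(
        structural_similarity(
            a, b, data_range=data_range,
            gaussian_weights=True, sigma=1.5, win_size=11,
            use_sample_covariance=False,
        )
    )


def _hr_array(img) -> np.ndarray:
    return img.data if isinstance(img, ImagePatch) else np.asarray(img, dtype=np.float64)


def evaluate_protocol(hr_images, G1, scale: int, config: dict | None = None) -> EvalReport:
    """Bicubic-degradation protocol: HR → bicubic ↓s → G1 → compare to HR."""
    psnrs, ssims, globals_ = [], [], []
    for img in hr_images:
        hr = _hr_array(img)
        h, w = hr.shape
        if h % scale or w % scale:
            raise ValueError(f"HR size {h}x{w} not divisible by scale {scale}")
        lr = np.clip(bicubic_resample(hr, (h // scale, w // scale)), -1.0, 1.0)
        if hasattr(G1, "eval"):  # a trained network module
            sr = infer(lr, G1).data
        else:  # a plain LR -> SR callable (stub / baseline)
            sr = np.asarray(G1(lr), dtype=np.float64)
        psnrs.append(psnr(sr, hr))
        ssims.append(ssim_windowed(sr, hr))
        globals_.append(ssim_global(sr, hr, SSIMConstants()))
    cfg = {"scale": scale, "metric": "psnr[2.0]/ssim[11x11 gaussian]",
           **(config or {})}
    return EvalReport(psnrs, ssims, globals_, cfg)


def evaluate_pairs(pairs, sr_fn, config: dict | None = None) -> EvalReport:
    """Evaluate any LR→SR function on registered (HR, LR) phantom pairs.

    ``sr_fn`` maps a 2-D LR array to a 2-D SR array — e.g. the trained G1 via
    :func:`~microsr.training.infer`, or a bicubic/nearest upsampling baseline.
    """
    psnrs, ssims, globals_ = [], [], []
    for pair in pairs:
        hr = pair.hr.data
        sr = np.asarray(sr_fn(pair.lr.data), dtype=np.float64)
        psnrs.append(psnr(sr, hr))
        ssims.append(ssim_windowed(sr, hr))
        globals_.append(ssim_global(sr, hr, SSIMConstants()))
    return EvalReport(psnrs, ssims, globals_, config or {})


def bicubic_upsample_baseline(scale: int):
    """LR→SR baseline: bicubic upsampling by ``scale``."""

    def sr_fn(lr: np.ndarray) -> np.ndarray:
        h, w = lr.shape
        return np.clip(bicubic_resample(lr, (h * scale, w * scale)), -1.0, 1.0)

    return sr_fn


def nearest_upsample_baseline(scale: int):
    """LR→SR baseline: nearest-neighbour upsampling by ``scale``."""

    def sr_fn(lr: np.ndarray) -> np.ndarray:
        return nearest_upsample(lr, scale)

    return sr_fn
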