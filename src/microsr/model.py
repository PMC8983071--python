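"""Estimator interface to SR-CycleGAN.

:class:`SRCycleGAN` presents the unpaired trainer as a scikit-learn-style
estimator: ``fit(X, y)`` takes a stack of clinical LR patches ``X`` and an
*unpaired* stack of micro HR patches ``y`` (there is no per-row
correspondence — ``y`` plays the role of the target domain, not of labels),
``transform(X)`` super-resolves new clinical patches with the trained G1.
All hyperparameters are constructor arguments so the estimator composes
with ``sklearn`` model selection; fitted state lives in trailing-underscore
attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .losses import LossWeights
from .networks import NetworkConfig, Variant
from .training import TrainConfig, fit as _fit, infer as _infer

__all__ = ["SRCycleGAN"]


class SRCycleGAN(BaseEstimator, TransformerMixin):
    """Unpaired clinical-CT → micro-CT super-resolution model.

    Parameters mirror the published configuration; the defaults here are the
    desk-scale (CPU-sized) setting, while ``scale_k=3, n_resblocks=9,
    base_channels=64, epochs=200`` reproduces the full-scale architecture.

    Parameters
    ----------
    scale_k : int
        Upscaling exponent; the scale factor is ``2**scale_k``.
    n_resblocks, base_channels, head_kernels, norm, variant
        Generator architecture knobs (see :class:`~microsr.networks.NetworkConfig`).
    lambda1 … lambda7 : float
        Loss weights (SSIM ×2, downsample, upsample, adversarial ×2, cycle).
    epochs, batch_size, lr0, decay_start_epoch, patches_per_epoch
        Optimization schedule; ``decay_start_epoch=None`` means half of
        ``epochs``.
    disc_channels : int or None
        Discriminator base width; ``None`` follows ``base_channels``.
    pool_size : int
        Capacity of the generated-image history pool (0 disables).
    random_state : int
        Seed for weight init, shuffling and pooling.

    Attributes
    ----------
    nets_ : NetworkBundle
        The four trained networks.
    history_ : list of dict
        Per-step loss breakdown rows.
    lr_size_ : int
        Training LR patch side; ``transform`` accepts any valid size
        (the generators are fully convolutional).
    """

    def __init__(
        self,
        scale_k: int = 2,
        n_resblocks: int = 2,
        base_channels: int = 8,
        head_kernels: tuple[int, int] = (3, 3),
        tail_kernel: int = 3,
        norm: str = "instance",
        variant: str = "sr",
        lambda1: float = 1.0,
        lambda2: float = 1.0,
        lambda3: float = 0.7,
        lambda4: float = 0.3,
        lambda5: float = 1.0,
        lambda6: float = 1.0,
        lambda7: float = 1.0,
        epochs: int = 31,
        batch_size: int = 4,
        lr0: float = 2e-4,
        decay_start_epoch: int | None = None,
        patches_per_epoch: int | None = None,
        disc_channels: int | None = None,
        pool_size: int = 50,
        gan_mode: str = "lsgan",
        random_state: int = 0,
    ):
        self.scale_k = scale_k
        self.n_resblocks = n_resblocks
        self.base_channels = base_channels
        self.head_kernels = head_kernels
        self.tail_kernel = tail_kernel
        self.norm = norm
        self.variant = variant
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.lambda4 = lambda4
        self.lambda5 = lambda5
        self.lambda6 = lambda6
        self.lambda7 = lambda7
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.decay_start_epoch = decay_start_epoch
        self.patches_per_epoch = patches_per_epoch
        self.disc_channels = disc_channels
        self.pool_size = pool_size
        self.gan_mode = gan_mode
        self.random_state = random_state

    # ------------------------------------------------------------------ api
    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            scale_k=self.scale_k,
            n_resblocks=self.n_resblocks,
            head_kernels=tuple(self.head_kernels),
            tail_kernel=self.tail_kernel,
            base_channels=self.base_channels,
            norm=self.norm,
            variant=Variant(self.variant),
        )

    def loss_weights(self) -> LossWeights:
        return LossWeights(
            self.lambda1, self.lambda2, self.lambda3, self.lambda4,
            self.lambda5, self.lambda6, self.lambda7,
        )

    def train_config(self, out_dir=None) -> TrainConfig:
        decay = self.decay_start_epoch
        if decay is None:
            decay = max(1, self.epochs // 2) if self.epochs > 1 else 0
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr0=self.lr0,
            decay_start_epoch=decay,
            pool_size=self.pool_size,
            seed=self.random_state,
            patches_per_epoch=self.patches_per_epoch,
            gan_mode=self.gan_mode,
            out_dir=str(out_dir) if out_dir else None,
        )

    def fit(self, X, y, out_dir=None, log_path=None):
        """Train on unpaired stacks X (N, n, n) clinical, y (M, s·n, s·n) micro."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3 or y.ndim != 3:
            raise ValueError("X and y must be 3-D stacks of 2-D patches")
        state = _fit(
            list(X), list(y),
            self.train_config(out_dir),
            self.network_config(),
            self.loss_weights(),
            disc_channels=self.disc_channels,
            log_path=log_path,
        )
        self.nets_ = state.nets
        self.history_ = state.history
        self.lr_size_ = X.shape[-1]
        self.n_iter_ = len(state.history)
        return self

    def transform(self, X) -> np.ndarray:
        """Super-resolve clinical patches with the trained G1."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 2
        patches = _infer(X[None] if single else X, self.nets_.G1)
        out = np.stack([p.data for p in patches])
        return out[0] if single else out

    predict = transform

    def _check_fitted(self):
        if not hasattr(self, "nets_"):
            raise AttributeError("this SRCycleGAN instance is not fitted yet")
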