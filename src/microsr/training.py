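"""Optimization of SR-CycleGAN.

One training step performs a joint Adam update of both generators on the
total objective, then one update per discriminator on pooled generated
images (a 50-image history pool, the usual stabilizer for unpaired GAN
training).  The learning rate stays at its initial value for the first half
of training and decays linearly to zero over the second half.  All
randomness flows from explicit seeds, so identical configuration reproduces
identical loss trajectories and checkpoints; training is resumable from any
periodic checkpoint.

Published schedule defaults: Adam at 1e-5 (betas 0.5/0.999), mini-batch 4,
200 epochs with decay starting at epoch 100, 10,000 patches per domain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import MICRO, ImagePatch
from .losses import (
    LossBreakdown,
    LossWeights,
    adversarial_loss_d,
    total_loss,
)
from .networks import (
    NetworkBundle,
    NetworkConfig,
    build_networks,
    load_checkpoint,
    save_checkpoint,
)
from .nn import Adam, Tensor

__all__ = ["TrainConfig", "ImagePool", "lr_schedule", "train_step", "fit", "infer"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 4
    lr0: float = 1e-5
    decay_start_epoch: int = 100
    betas: tuple[float, float] = (0.5, 0.999)
    pool_size: int = 50
    seed: int = 0
    patches_per_epoch: int | None = None  # default: full pass over the set
    gan_mode: str = "lsgan"
    checkpoint_every: int = 1  # epochs
    out_dir: str | None = None

    def __post_init__(self):
        if not self.decay_start_epoch < self.epochs:
            raise ValueError("decay_start_epoch must be < epochs")
        if self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("batch_size must be >= 1 and lr0 > 0")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["betas"] = list(self.betas)
        return d


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at a 1-based epoch: flat, then linear to 0 at the end."""
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [1, {cfg.epochs}]")
    if epoch <= cfg.decay_start_epoch:
        return cfg.lr0
    span = cfg.epochs - cfg.decay_start_epoch
    return cfg.lr0 * (cfg.epochs - epoch) / span


class ImagePool:
    """History buffer of generated images (CycleGAN-lineage stabilizer).

    With probability 1/2 a query returns (and replaces) a stored past fake
    instead of the current one, decorrelating discriminator updates.
    Deterministic under a fixed RNG; capacity 0 disables pooling.
    """

    def __init__(self, capacity: int):
        self.capacity = int(capacity)
        self.images: list[np.ndarray] = []

    def query(self, batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.capacity == 0:
            return batch
        out = []
        for img in batch:
            if len(self.images) < self.capacity:
                self.images.append(img.copy())
                out.append(img)
            elif rng.random() < 0.5:
                idx = int(rng.integers(len(self.images)))
                out.append(self.images[idx].copy())
                self.images[idx] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


@dataclass
class TrainState:
    """Everything train_step mutates, bundled for fit/resume."""

    nets: NetworkBundle
    opt_g: Adam
    opt_d1: Adam
    opt_d2: Adam
    pool_sr: ImagePool
    pool_lr: ImagePool
    rng: np.random.Generator
    history: list[dict] = field(default_factory=list)


def _as_batch(patches) -> np.ndarray:
    """Stack patches/arrays into an (N, 1, H, W) float batch."""
    arrs = [p.data if isinstance(p, ImagePatch) else np.asarray(p) for p in patches]
    from .nn.layers import DTYPE

    return np.stack(arrs)[:, None, :, :].astype(DTYPE)


def make_state(
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    lr_size: int,
    disc_channels: int | None = None,
) -> TrainState:
    nets = build_networks(net_cfg, lr_size, train_cfg.seed, disc_channels=disc_channels)
    g_params = list(nets.G1.parameters()) + list(nets.G2.parameters())
    opt_g = Adam(g_params, lr=train_cfg.lr0, betas=train_cfg.betas)
    opt_d1 = Adam(nets.D1.parameters(), lr=train_cfg.lr0, betas=train_cfg.betas)
    opt_d2 = Adam(nets.D2.parameters(), lr=train_cfg.lr0, betas=train_cfg.betas)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0x7EA1]))
    return TrainState(
        nets, opt_g, opt_d1, opt_d2,
        ImagePool(train_cfg.pool_size), ImagePool(train_cfg.pool_size), rng,
    )


def train_step(
    batch_x: np.ndarray,
    batch_y: np.ndarray,
    state: TrainState,
    weights: LossWeights = LossWeights(),
    gan_mode: str = "lsgan",
) -> LossBreakdown:
    """One generator update followed by one update per discriminator.

    ``batch_x``: clinical LR patches (N, 1, n, n); ``batch_y``: micro HR
    patches (N, 1, s·n, s·n).  Returns the pre-update loss breakdown.
    """
    nets = state.nets
    s = nets.config.scale
    if batch_x.shape[-1] * s != batch_y.shape[-1]:
        raise ValueError(
            f"batch size mismatch: LR {batch_x.shape[-1]} x scale {s} != "
            f"HR {batch_y.shape[-1]}"
        )
    from .nn.layers import DTYPE

    x = Tensor(np.asarray(batch_x, dtype=DTYPE))
    y = Tensor(np.asarray(batch_y, dtype=DTYPE))

    # ---- generators -----------------------------------------------------
    nets.G1.train(), nets.G2.train(), nets.D1.train(), nets.D2.train()
    x_sr = nets.G1(x)
    y_lr = nets.G2(y)
    x_rec = nets.G2(x_sr)
    y_rec = nets.G1(y_lr)
    d1_fake = nets.D1(x_sr)
    d2_fake = nets.D2(y_lr)
    breakdown = total_loss(
        x, x_sr, y, y_lr, x_rec, y_rec, d1_fake, d2_fake,
        weights=weights, gan_mode=gan_mode,
    )
    state.opt_g.zero_grad()
    nets.D1.zero_grad(), nets.D2.zero_grad()  # G loss also reaches D params
    if breakdown.graph is not None:
        breakdown.graph.backward()
    state.opt_g.step()

    # ---- discriminators (on detached, pooled fakes) ---------------------
    sr_pool = state.pool_sr.query(x_sr.data, state.rng)
    lr_pool = state.pool_lr.query(y_lr.data, state.rng)
    for D, opt, real, fake in (
        (nets.D1, state.opt_d1, y, Tensor(sr_pool)),
        (nets.D2, state.opt_d2, x, Tensor(lr_pool)),
    ):
        d_loss = adversarial_loss_d(D(real.detach()), D(fake), mode=gan_mode)
        opt.zero_grad()
        d_loss.backward()
        opt.step()
    return breakdown


def fit(
    clinical_patches,
    micro_patches,
    train_cfg: TrainConfig,
    net_cfg: NetworkConfig,
    weights: LossWeights = LossWeights(),
    disc_channels: int | None = None,
    resume_from=None,
    log_path=None,
    callback=None,
) -> TrainState:
    """Train on two unpaired patch sets; returns the final state.

    Each epoch shuffles both domains independently (unpaired sampling) and
    runs ceil(patches_per_epoch / batch_size) steps.  Periodic checkpoints
    (with optimizer state) and a CSV loss log are written when ``out_dir`` /
    ``log_path`` are set; resuming from a checkpoint reproduces the
    uninterrupted trajectory.
    """
    if len(clinical_patches) == 0 or len(micro_patches) == 0:
        raise ValueError("both patch sets must be non-empty")
    bx = _as_batch(clinical_patches)
    by = _as_batch(micro_patches)
    lr_size = bx.shape[-1]
    if bx.shape[-1] * net_cfg.scale != by.shape[-1]:
        raise ValueError("micro patches must be scale x the clinical patch size")

    start_epoch = 1
    if resume_from is not None:
        state, meta = _restore(resume_from, train_cfg, lr_size, disc_channels)
        start_epoch = int(meta["epoch"]) + 1
    else:
        state = make_state(net_cfg, train_cfg, lr_size, disc_channels)

    n_per_epoch = train_cfg.patches_per_epoch or len(clinical_patches)
    steps = -(-n_per_epoch // train_cfg.batch_size)  # ceil
    out_dir = Path(train_cfg.out_dir) if train_cfg.out_dir else None
    log_rows: list[dict] = []

    for epoch in range(start_epoch, train_cfg.epochs + 1):
        lr = lr_schedule(epoch, train_cfg)
        state.opt_g.lr = state.opt_d1.lr = state.opt_d2.lr = lr
        # per-epoch shuffles seeded by (seed, epoch) so resume lines up
        ex = np.random.default_rng(
            np.random.SeedSequence([train_cfg.seed, epoch, 0])
        ).permutation(len(bx))
        ey = np.random.default_rng(
            np.random.SeedSequence([train_cfg.seed, epoch, 1])
        ).permutation(len(by))
        B = train_cfg.batch_size
        for step in range(steps):
            sel = np.arange(step * B, (step + 1) * B)
            ix = np.take(ex, sel % len(bx))
            iy = np.take(ey, sel % len(by))
            breakdown = train_step(bx[ix], by[iy], state, weights,
                                   gan_mode=train_cfg.gan_mode)
            row = {"epoch": epoch, "step": step, "lr": lr, **breakdown.as_dict()}
            state.history.append(row)
            log_rows.append(row)
            if callback is not None:
                callback(row)
        if out_dir and epoch % train_cfg.checkpoint_every == 0:
            extra_arrays = {}
            if state.pool_sr.images:
                extra_arrays["pool_sr"] = np.stack(state.pool_sr.images)
            if state.pool_lr.images:
                extra_arrays["pool_lr"] = np.stack(state.pool_lr.images)
            save_checkpoint(
                out_dir / f"checkpoint_epoch{epoch:04d}.zip",
                state.nets,
                extra_meta={
                    "epoch": epoch,
                    # out_dir is a runtime path, not training state
                    "train_config": {k: v for k, v in train_cfg.to_dict().items()
                                     if k != "out_dir"},
                    "loss_weights": weights.to_dict(),
                    "disc_channels": disc_channels,
                    "rng_state": state.rng.bit_generator.state,
                },
                optim_states={
                    "g": state.opt_g.state_dict(),
                    "d1": state.opt_d1.state_dict(),
                    "d2": state.opt_d2.state_dict(),
                },
                extra_arrays=extra_arrays,
            )
    if log_path is not None:
        _write_log(log_path, log_rows)
    return state


def _restore(path, train_cfg: TrainConfig, lr_size: int, disc_channels):
    bundle, meta, optim_states, extra = load_checkpoint(
        path, lr_size, seed=train_cfg.seed, disc_channels=disc_channels
    )
    state = make_state(bundle.config, train_cfg, lr_size, disc_channels)
    state.nets = bundle
    # rebind optimizers to the restored parameters
    g_params = list(bundle.G1.parameters()) + list(bundle.G2.parameters())
    state.opt_g = Adam(g_params, lr=train_cfg.lr0, betas=train_cfg.betas)
    state.opt_d1 = Adam(bundle.D1.parameters(), lr=train_cfg.lr0, betas=train_cfg.betas)
    state.opt_d2 = Adam(bundle.D2.parameters(), lr=train_cfg.lr0, betas=train_cfg.betas)
    if optim_states:
        state.opt_g.load_state_dict(optim_states["g"])
        state.opt_d1.load_state_dict(optim_states["d1"])
        state.opt_d2.load_state_dict(optim_states["d2"])
    # restore the pool contents and the pool/update RNG mid-stream state
    if "pool_sr" in extra:
        state.pool_sr.images = [a for a in extra["pool_sr"]]
    if "pool_lr" in extra:
        state.pool_lr.images = [a for a in extra["pool_lr"]]
    if "rng_state" in meta:
        state.rng.bit_generator.state = meta["rng_state"]
    return state, meta


def _write_log(path, rows: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not rows:
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def infer(patches, G1, scale: int | None = None) -> list[ImagePatch]:
    """Run the trained G1 on clinical patches; norm layers in eval mode.

    Accepts a single :class:`ImagePatch`, a list, or an (N, H, W) array of
    normalized values; returns micro-domain patches, order preserved.
    """
    single = isinstance(patches, ImagePatch) or (
        isinstance(patches, np.ndarray) and patches.ndim == 2
    )
    items = [patches] if single else list(patches)
    for p in items:
        arr = p.data if isinstance(p, ImagePatch) else np.asarray(p)
        if np.abs(arr).max() > 1.0 + 1e-9:
            raise ValueError("inference input must be normalized to [-1, 1]")
        if isinstance(p, ImagePatch) and not p.normalized:
            raise ValueError("inference input must be normalized")
    batch = _as_batch(items)
    G1.eval()
    out = G1(Tensor(batch)).data[:, 0]
    results = [ImagePatch(np.clip(a, -1.0, 1.0), domain=MICRO) for a in out]
    return results[0] if single else results
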