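"""Loss terms of SR-CycleGAN.

The total objective couples seven weighted terms:

    L_total = λ1·L_S(x, f↓(x_SR)) + λ2·L_S(y, f↑(y_LR))
            + λ3·L_D(x, x_SR)     + λ4·L_U(y, y_LR)
            + λ5·L_GAN(x_SR, y)   + λ6·L_GAN(y_LR, x)
            + λ7·L_cyc

where x is a clinical LR patch, x_SR = G1(x), y a micro HR patch,
y_LR = G2(y), f↓ is non-overlapping average pooling and f↑ nearest
upsampling.  The multi-modality super-resolution (MMSR) part — the two SSIM
losses plus the downsample and upsample losses — is what ties images of
different sizes (and modalities) together; without it the unpaired
adversarial objective is free to output images unrelated to the input.

SSIM here uses *global* per-image moments (one μ, σ per image), in the
standard Wang et al. form with 2·μ_a·μ_b in the numerator so that
SSIM(x, x) = 1.  Adversarial terms default to least-squares GAN
(the CycleGAN-lineage choice); binary cross-entropy is available as a
switch.  Squared ℓ2 norms are averaged per pixel so the λ weights are
resolution-independent.

Every function accepts plain NumPy arrays (returning floats) or autodiff
:class:`~microsr.nn.Tensor` inputs (returning scalar tensors on the tape).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .nn import Tensor, as_tensor, avg_pool2d, nearest_upsample2d

__all__ = [
    "LossWeights",
    "SSIMConstants",
    "LossBreakdown",
    "ssim_global",
    "ssim_loss",
    "downsample_loss",
    "upsample_loss",
    "adversarial_loss_g",
    "adversarial_loss_d",
    "adversarial_losses",
    "cycle_loss",
    "mmsr_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """λ1…λ7 with the published defaults."""

    lambda1: float = 1.0  # SSIM loss of G1
    lambda2: float = 1.0  # SSIM loss of G2
    lambda3: float = 0.7  # downsample loss
    lambda4: float = 0.3  # upsample loss
    lambda5: float = 1.0  # GAN loss of G1/D1
    lambda6: float = 1.0  # GAN loss of G2/D2
    lambda7: float = 1.0  # cycle-consistency loss

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "LossWeights":
        return cls(**d)


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilizers C1 = (K1·L)², C2 = (K2·L)² for data range L."""

    data_range: float = 2.0  # [-1, 1] images
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM constants must be positive")


DEFAULT_SSIM = SSIMConstants()


@dataclass
class LossBreakdown:
    """Per-term scalar values of one objective evaluation."""

    ssim_g1: float  # L_S(x, f↓(x_SR))
    ssim_g2: float  # L_S(y, f↑(y_LR))
    downsample: float  # L_D
    upsample: float  # L_U
    gan_g1: float
    gan_g2: float
    cycle: float
    total: float
    graph: Tensor | None = field(default=None, repr=False, compare=False)

    FIELDS = ("ssim_g1", "ssim_g2", "downsample", "upsample",
              "gan_g1", "gan_g2", "cycle", "total")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}

    def weighted_sum(self, w: LossWeights) -> float:
        return (
            w.lambda1 * self.ssim_g1
            + w.lambda2 * self.ssim_g2
            + w.lambda3 * self.downsample
            + w.lambda4 * self.upsample
            + w.lambda5 * self.gan_g1
            + w.lambda6 * self.gan_g2
            + w.lambda7 * self.cycle
        )


# ------------------------------------------------------------------ helpers


def _prep(a) -> tuple[Tensor, bool]:
    """Return (NCHW tensor, was_plain_numpy)."""
    plain = not isinstance(a, Tensor)
    t = as_tensor(a)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, *t.shape[1:])
    elif t.ndim != 4:
        raise ValueError("expected a 2-D image, a 3-D stack or an NCHW batch")
    return t, plain


def _finish(t: Tensor, plain: bool):
    return t.item() if plain else t


def _check_finite(t: Tensor, name: str) -> None:
    if not np.isfinite(t.data).all():
        raise ValueError(f"non-finite values in {name}")


def _mse(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return ((a - b) ** 2).mean()


def _match_scale(ref: Tensor, img: Tensor) -> Tensor:
    """Bring ``img`` to ``ref``'s spatial size with f↓ (pool) or f↑ (nearest)."""
    rh, ih = ref.shape[-2], img.shape[-2]
    rw, iw = ref.shape[-1], img.shape[-1]
    if (rh, rw) == (ih, iw):
        return img
    if ih > rh:
        if ih % rh or iw % rw or ih // rh != iw // rw:
            raise ValueError(
                f"incompatible sizes: {ih}x{iw} is not an integer multiple "
                f"of {rh}x{rw}"
            )
        return avg_pool2d(img, ih // rh)
    if rh % ih or rw % iw or rh // ih != rw // iw:
        raise ValueError(
            f"incompatible sizes: {rh}x{rw} is not an integer multiple of {ih}x{iw}"
        )
    return nearest_upsample2d(img, rh // ih)


# ---------------------------------------------------------------- SSIM loss


def ssim_global(a, b, constants: SSIMConstants = DEFAULT_SSIM):
    """Whole-image-moment SSIM, averaged over the batch if batched.

    (2·μa·μb + C1)(2·σab + C2) / ((μa² + μb² + C1)(σa² + σb² + C2));
    symmetric, ≤ 1, and exactly 1 for identical images.
    """
    ta, pa = _prep(a)
    tb, pb = _prep(b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
    ax = (1, 2, 3)
    mu_a = ta.mean(axis=ax, keepdims=True)
    mu_b = tb.mean(axis=ax, keepdims=True)
    da = ta - mu_a
    db = tb - mu_b
    var_a = (da**2).mean(axis=ax, keepdims=True)
    var_b = (db**2).mean(axis=ax, keepdims=True)
    cov = (da * db).mean(axis=ax, keepdims=True)
    c1, c2 = constants.c1, constants.c2
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return _finish((num / den).mean(), pa and pb)


def ssim_loss(ref, img, constants: SSIMConstants = DEFAULT_SSIM):
    """L_S: 1 − SSIM(ref, img brought to ref's size via f↓ or f↑).

    With ``ref = x`` (LR) and ``img = x_SR`` this is Eq. L_S(x, f↓(x_SR));
    with ``ref = y`` (HR) and ``img = y_LR`` it is L_S(y, f↑(y_LR)).
    """
    tr, pr = _prep(ref)
    ti, pi = _prep(img)
    matched = _match_scale(tr, ti)
    return _finish(1.0 - ssim_global(tr, matched, constants), pr and pi)


# -------------------------------------------------------- pixel-wise losses


def downsample_loss(x, x_sr):
    """L_D: per-pixel mean of (x − f↓(x_SR))²."""
    tx, px = _prep(x)
    ts, ps = _prep(x_sr)
    if ts.shape[-2] < tx.shape[-2]:
        raise ValueError("x_sr must be at least as large as x")
    return _finish(_mse(tx, _match_scale(tx, ts)), px and ps)


def upsample_loss(y, y_lr):
    """L_U: per-pixel mean of (y − f↑(y_LR))²."""
    ty, py = _prep(y)
    tl, pl = _prep(y_lr)
    if tl.shape[-2] > ty.shape[-2]:
        raise ValueError("y_lr must be no larger than y")
    return _finish(_mse(ty, _match_scale(ty, tl)), py and pl)


# ------------------------------------------------------------- adversarial


def adversarial_loss_g(d_fake, mode: str = "lsgan"):
    """Generator-side loss from discriminator scores on generated images."""
    t, plain = _prep(d_fake)
    _check_finite(t, "discriminator scores")
    if mode == "lsgan":
        out = ((t - 1.0) ** 2).mean()
    elif mode == "bce":
        p = _sigmoid(t)
        out = (-(_log(p))).mean()
    else:
        raise ValueError(f"unknown GAN mode {mode!r}")
    return _finish(out, plain)


def adversarial_loss_d(d_real, d_fake, mode: str = "lsgan"):
    """Discriminator-side loss: ½·mean((D(real)−1)²) + ½·mean(D(fake)²)."""
    tr, pr = _prep(d_real)
    tf, pf = _prep(d_fake)
    _check_finite(tr, "real scores")
    _check_finite(tf, "fake scores")
    if mode == "lsgan":
        out = 0.5 * ((tr - 1.0) ** 2).mean() + 0.5 * (tf**2).mean()
    elif mode == "bce":
        out = 0.5 * (-(_log(_sigmoid(tr)))).mean() + 0.5 * (
            -(_log(1.0 - _sigmoid(tf)))
        ).mean()
    else:
        raise ValueError(f"unknown GAN mode {mode!r}")
    return _finish(out, pr and pf)


def adversarial_losses(d_scores_real, d_scores_fake, role: str, mode: str = "lsgan"):
    """Dispatch on ``role`` ∈ {"generator", "discriminator"}."""
    role = role.lower()
    if role == "generator":
        return adversarial_loss_g(d_scores_fake, mode=mode)
    if role == "discriminator":
        return adversarial_loss_d(d_scores_real, d_scores_fake, mode=mode)
    raise ValueError(f"unknown role {role!r}")


def _sigmoid(t: Tensor) -> Tensor:
    return 1.0 / (1.0 + (-t).exp())


def _log(t: Tensor) -> Tensor:
    # numerically clipped log for the BCE option
    clipped = np.clip(t.data, 1e-12, None)
    out = Tensor(np.log(clipped), _parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g / clipped)

    out._backward = bwd
    return out


# ------------------------------------------------------------------- cycle


def cycle_loss(x, x_rec, y, y_rec):
    """L_cyc: MSE(x, G2(G1(x))) + MSE(y, G1(G2(y)))."""
    tx, px = _prep(x)
    txr, _ = _prep(x_rec)
    ty, py = _prep(y)
    tyr, _ = _prep(y_rec)
    return _finish(_mse(tx, txr) + _mse(ty, tyr), px and py)


# ---------------------------------------------------------------- combined


def mmsr_loss(x, x_sr, y, y_lr, weights: LossWeights = LossWeights(),
              constants: SSIMConstants = DEFAULT_SSIM):
    """Multi-modality super-resolution loss (the λ1–λ4 terms)."""
    out = (
        weights.lambda1 * ssim_loss(x, x_sr, constants)
        + weights.lambda2 * ssim_loss(y, y_lr, constants)
        + weights.lambda3 * downsample_loss(x, x_sr)
        + weights.lambda4 * upsample_loss(y, y_lr)
    )
    return out


def total_loss(
    x,
    x_sr,
    y,
    y_lr,
    x_rec,
    y_rec,
    d1_fake_scores,
    d2_fake_scores,
    weights: LossWeights = LossWeights(),
    constants: SSIMConstants = DEFAULT_SSIM,
    gan_mode: str = "lsgan",
) -> LossBreakdown:
    """Full generator objective; returns the per-term breakdown.

    ``d1_fake_scores``/``d2_fake_scores`` are the discriminator score maps on
    x_SR and y_LR.  The ``graph`` field holds the scalar tensor for backprop
    when any input lives on the autodiff tape.
    """
    terms = {
        "ssim_g1": ssim_loss(x, x_sr, constants),
        "ssim_g2": ssim_loss(y, y_lr, constants),
        "downsample": downsample_loss(x, x_sr),
        "upsample": upsample_loss(y, y_lr),
        "gan_g1": adversarial_loss_g(d1_fake_scores, mode=gan_mode),
        "gan_g2": adversarial_loss_g(d2_fake_scores, mode=gan_mode),
        "cycle": cycle_loss(x, x_rec, y, y_rec),
    }
    w = weights
    lam = (w.lambda1, w.lambda2, w.lambda3, w.lambda4, w.lambda5, w.lambda6, w.lambda7)
    total = None
    for lam_i, term in zip(lam, terms.values()):
        contrib = lam_i * term
        total = contrib if total is None else total + contrib
    if isinstance(total, Tensor):
        scalars = {k: (v.item() if isinstance(v, Tensor) else float(v))
                   for k, v in terms.items()}
        return LossBreakdown(**scalars, total=total.item(), graph=total)
    return LossBreakdown(**{k: float(v) for k, v in terms.items()},
                         total=float(total), graph=None)
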