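"""Core imaging types and operators.

Two intensity domains are handled throughout the package:

* ``CLINICAL`` — Hounsfield-scale chest CT (air ≈ −1000 H.U., bone ≈ +2500
  H.U., ~0.6 mm voxels),
* ``MICRO`` — micro-focus CT of resected lung specimens on a scanner-specific
  scale (≈ [0, 15000], ~50 μm voxels).

Intensities are clipped to the domain window and affinely compressed to
[−1, 1] before any network sees them.  The module also provides the two
resampling operators used inside the multi-modality super-resolution loss —
non-overlapping average pooling ``f↓`` and nearest-neighbour upsampling
``f↑`` — plus Keys bicubic resampling (a = −0.5, reflect boundaries), a
coarse region-growing lung mask, and seeded random patch extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

__all__ = [
    "DomainName",
    "IntensityDomain",
    "CLINICAL",
    "MICRO",
    "CTVolume",
    "ImagePatch",
    "BinaryMask",
    "normalize_intensity",
    "denormalize_intensity",
    "average_pool_downsample",
    "nearest_upsample",
    "bicubic_resample",
    "lung_mask",
    "extract_patches",
]


class DomainName(str, Enum):
    CLINICAL = "clinical"
    MICRO = "micro"


@dataclass(frozen=True)
class IntensityDomain:
    """Native intensity window of an acquisition domain.

    ``clip_low``/``clip_high`` are the window endpoints in native units;
    values outside are clipped before the affine map onto [−1, 1].
    """

    name: DomainName
    clip_low: float
    clip_high: float

    def __post_init__(self):
        if not self.clip_low < self.clip_high:
            raise ValueError(
                f"clip_low ({self.clip_low}) must be < clip_high ({self.clip_high})"
            )


#: Clinical chest CT window: air (−1000 H.U.) to bone (+2500 H.U.).
CLINICAL = IntensityDomain(DomainName.CLINICAL, -1000.0, 2500.0)
#: Micro-CT scanner window: 0 to the cancer-tissue level (~15000).
MICRO = IntensityDomain(DomainName.MICRO, 0.0, 15000.0)


@dataclass
class CTVolume:
    """3-D native-intensity volume, indexed (z, y, x), with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    domain: IntensityDomain

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a 3-D array with all dimensions >= 1")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ImagePatch:
    """2-D grayscale patch (row-major, origin top-left) with a domain tag."""

    data: np.ndarray
    domain: IntensityDomain
    normalized: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("patch must be 2-D")
        if self.normalized:
            lo, hi = self.data.min(), self.data.max()
            if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
                raise ValueError(
                    f"normalized patch has values outside [-1, 1]: [{lo}, {hi}]"
                )

    @property
    def shape(self):
        return self.data.shape


@dataclass
class BinaryMask:
    """Boolean mask aligned with its source image/volume."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim not in (2, 3):
            raise ValueError("mask must be 2-D or 3-D")


# --------------------------------------------------------------- intensity


def normalize_intensity(v, domain: IntensityDomain) -> np.ndarray:
    """Clip to the domain window and map affinely onto [−1, 1].

    ``clip_low`` maps to −1 and ``clip_high`` to +1; the map is monotone and
    invertible on the clipped range (see :func:`denormalize_intensity`).
    """
    arr = v.data if isinstance(v, CTVolume) else np.asarray(v)
    arr = np.asarray(arr, dtype=np.float64)
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite intensity at index {idx}")
    lo, hi = domain.clip_low, domain.clip_high
    clipped = np.clip(arr, lo, hi)
    return 2.0 * (clipped - lo) / (hi - lo) - 1.0


def denormalize_intensity(a, domain: IntensityDomain, tol: float = 1e-6) -> np.ndarray:
    """Exact inverse of :func:`normalize_intensity` on the clipped range."""
    arr = np.asarray(a, dtype=np.float64)
    if arr.min() < -1.0 - tol or arr.max() > 1.0 + tol:
        raise ValueError(
            f"values outside [-1, 1] beyond tolerance {tol}: "
            f"range [{arr.min()}, {arr.max()}]"
        )
    arr = np.clip(arr, -1.0, 1.0)
    lo, hi = domain.clip_low, domain.clip_high
    return (arr + 1.0) / 2.0 * (hi - lo) + lo


# --------------------------------------------------------------- resampling


def average_pool_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """``f↓``: mean over non-overlapping factor×factor blocks."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    f = int(factor)
    if f < 1:
        raise ValueError("factor must be >= 1")
    H, W = img.shape
    if H % f or W % f:
        raise ValueError(
            f"image size {H}x{W} must be divisible by the pooling factor {f}"
        )
    return img.reshape(H // f, f, W // f, f).mean(axis=(1, 3))


def nearest_upsample(img: np.ndarray, factor: int) -> np.ndarray:
    """``f↑``: replicate each pixel over a factor×factor block."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    f = int(factor)
    if f < 1:
        raise ValueError("factor must be >= 1")
    return np.repeat(np.repeat(img, f, axis=0), f, axis=1)


def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic-convolution kernel; reproduces polynomials up to degree 1."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    m2 = (t > 1) & (t < 2)
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


def _reflect(idx: np.ndarray, n: int) -> np.ndarray:
    """Fold indices into [0, n) by mirror reflection (no edge repeat)."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * (n - 1)
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - idx, idx)


def _bicubic_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix applying 1-D Keys interpolation."""
    # pixel-area coordinate convention: output centre i maps to
    # (i + 0.5) * n_in / n_out - 0.5 in input coordinates
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    base = np.floor(src).astype(int)
    mat = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    for k in range(-1, 3):  # the 4 taps of the 4x4 support
        tap = base + k
        w = _keys_kernel(src - tap)
        cols = _reflect(tap, n_in)
        np.add.at(mat, (rows, cols), w)
    return mat


def bicubic_resample(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Keys bicubic (a = −0.5) resampling with reflect boundary handling.

    Each interior output sample is a weighted sum of a 4×4 source
    neighbourhood; the kernel reproduces constant and linear images exactly.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    ho, wo = int(out_shape[0]), int(out_shape[1])
    if ho < 1 or wo < 1:
        raise ValueError("output shape components must be >= 1")
    ry = _bicubic_matrix(img.shape[0], ho)
    rx = _bicubic_matrix(img.shape[1], wo)
    return ry @ img @ rx.T


# --------------------------------------------------------------- lung mask

_LUNG_AIR_HU = -400.0  # threshold separating aerated lung from soft tissue


def lung_mask(volume: CTVolume) -> BinaryMask:
    """Coarse lung segmentation of a clinical (Hounsfield-scale) chest volume.

    Region growing from all low-intensity voxels (< −400 H.U.) interior to
    the body — implemented as connected-component labelling of the threshold
    mask with border-touching components (outside air) removed — followed by
    per-slice morphological hole filling so vessels inside the lung are kept.
    """
    if volume.domain.name is not DomainName.CLINICAL:
        raise ValueError("lung_mask expects a CLINICAL-domain volume in H.U.")
    air = volume.data < _LUNG_AIR_HU
    labels, n = ndimage.label(air)
    if n == 0:
        raise ValueError("no lung region")
    # outside air touches the in-plane (x/y) edges; lungs may legitimately
    # extend through the first/last axial slice, so z faces are not excluded
    border = np.zeros_like(air)
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = np.unique(labels[border & air])
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[touching] = False
    mask = keep[labels]
    if not mask.any():
        raise ValueError("no lung region")
    filled = np.empty_like(mask)
    for z in range(mask.shape[0]):
        filled[z] = ndimage.binary_fill_holes(mask[z])
    return BinaryMask(filled)


# ----------------------------------------------------------- patch sampling

_MASK_COVERAGE = 0.5  # minimum in-mask fraction for an accepted patch


def extract_patches(
    source,
    size: int,
    n: int,
    seed: int,
    mask: BinaryMask | None = None,
    domain: IntensityDomain | None = None,
) -> list[ImagePatch]:
    """Sample ``n`` normalized square patches from axial slices.

    ``source`` is a :class:`CTVolume` (native units; normalized on output) or
    a 3-D stack of already-normalized slices with ``domain`` given.  Top-left
    positions are uniform over all valid (slice, y, x) triples; with a mask,
    a patch is accepted only when ≥50% of its pixels fall inside the mask.
    The same seed always reproduces the same patch set.
    """
    if isinstance(source, CTVolume):
        stack = normalize_intensity(source.data, source.domain)
        dom = source.domain
    else:
        stack = np.asarray(source, dtype=np.float64)
        if domain is None:
            raise ValueError("domain is required for a raw slice stack")
        dom = domain
    if stack.ndim != 3:
        raise ValueError("source must be 3-D (z, y, x)")
    size = int(size)
    if n < 1:
        raise ValueError("n must be >= 1")
    nz, ny, nx = stack.shape
    if size > ny or size > nx:
        raise ValueError(f"patch size {size} does not fit inside {ny}x{nx} slices")
    if mask is not None and mask.data.shape != stack.shape:
        raise ValueError("mask shape must match the source volume")

    rng = np.random.default_rng(seed)
    patches: list[ImagePatch] = []
    rejections = 0
    limit = 1000 * n
    attempts = 0
    while len(patches) < n:
        z = int(rng.integers(0, nz))
        y = int(rng.integers(0, ny - size + 1))
        x = int(rng.integers(0, nx - size + 1))
        attempts += 1
        if mask is not None:
            cov = mask.data[z, y : y + size, x : x + size].mean()
            if cov < _MASK_COVERAGE:
                rejections += 1
                if rejections >= limit:
                    rate = len(patches) / attempts
                    raise RuntimeError(
                        f"patch sampling stalled: acceptance rate {rate:.2e} "
                        f"after {rejections} rejections"
                    )
                continue
        patches.append(
            ImagePatch(
                stack[z, y : y + size, x : x + size].copy(),
                domain=dom,
                normalized=True,
                meta={"z": z, "y": y, "x": x, "seed": seed},
            )
        )
    return patches
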