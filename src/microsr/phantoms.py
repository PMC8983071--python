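"""Synthetic lung phantoms for the two CT domains.

Real training data for this method — clinical chest CT and micro-CT of
resected lung specimens — cannot ship with the package, so a seeded
generator provides both domains with the statistical structure the method
assumes:

* **micro-domain HR phantoms** contain the structures the method is judged
  on visually: bright disks ("vessels"), annuli with dark lumina
  ("bronchi"), and a granular two-mode background ("alveolar" septa vs.
  air).  The pixel histogram concentrates in the upper part of the
  normalized range, like real specimen micro-CT.
* **clinical-domain LR counterparts** are produced by a forward model:
  Gaussian blur (scanner PSF) → average-pool by the scale factor → a
  monotone affine intensity remap (the clinical scale compresses soft-tissue
  contrast relative to the specimen scanner scale) → additive noise.  The
  remap keeps structure ordering but shifts the histogram, so the two
  domains are statistically well separated — the premise that makes the
  multi-modality loss necessary.

Unpaired training sets draw the two domains from disjoint seed pools (no
hidden pairing); paired sets, where the LR image *is* the degraded HR image,
exist only for oracle evaluation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .imaging import CLINICAL, MICRO, ImagePatch, average_pool_downsample

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "generate_micro_phantom",
    "degrade_to_clinical",
    "make_unpaired_sets",
    "make_paired_eval_set",
]

# intensity modes of the micro domain (normalized units)
_TISSUE_MODE = 0.45
_AIR_MODE = -0.55
_VESSEL_LEVEL = 0.75
_WALL_LEVEL = 0.65
_LUMEN_LEVEL = -0.65


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom family.

    ``hr_size`` must be divisible by the scale factor ``s``.  The affine
    remap (``remap_gain``, ``remap_offset``) is the monotone clinical
    intensity map; ``psf_sigma`` is the degradation blur in HR pixels and
    ``noise_sigma`` the clinical additive-noise level in normalized units.
    """

    hr_size: int = 256
    s: int = 8
    n_vessels: tuple[int, int] = (2, 5)
    n_bronchi: tuple[int, int] = (1, 3)
    alveolar_grain: float = 3.0  # correlation length of the texture, HR px
    air_fraction: float = 0.45  # fraction of background below the septum mode
    psf_sigma: float = 1.0
    noise_sigma: float = 0.03
    remap_gain: float = 0.32
    remap_offset: float = -0.70

    def __post_init__(self):
        if self.hr_size % self.s:
            raise ValueError("hr_size must be divisible by s")
        if self.psf_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if not 0 < self.remap_gain <= 1.5:
            raise ValueError("remap_gain must be positive")

    @property
    def lr_size(self) -> int:
        return self.hr_size // self.s

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PhantomPair:
    """A registered (HR micro, LR clinical) pair for oracle evaluation only."""

    hr: ImagePatch
    lr: ImagePatch
    seed: int
    spec_hash: str


def _disk(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, r: float) -> np.ndarray:
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def generate_micro_phantom(spec: PhantomSpec, seed: int) -> ImagePatch:
    """Seeded micro-domain HR phantom (vessels, bronchi, alveolar texture)."""
    n = spec.hr_size
    if n < 8 * spec.s or n < 32:
        raise ValueError(f"hr_size {n} too small for the requested structures")
    rng = np.random.default_rng(seed)

    # alveolar background: correlated noise split into septa vs. air modes
    noise = rng.normal(size=(n, n))
    smooth = ndimage.gaussian_filter(noise, spec.alveolar_grain)
    thr = np.quantile(smooth, spec.air_fraction)
    img = np.where(
        smooth > thr,
        _TISSUE_MODE + 0.12 * rng.normal(size=(n, n)),
        _AIR_MODE + 0.10 * rng.normal(size=(n, n)),
    )

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    structures = []

    n_v = int(rng.integers(spec.n_vessels[0], spec.n_vessels[1] + 1))
    for _ in range(max(1, n_v)):  # >= 1 vessel always
        r = rng.uniform(0.02, 0.06) * n
        cy, cx = rng.uniform(r, n - r, size=2)
        img[_disk(yy, xx, cy, cx, r)] = _VESSEL_LEVEL + rng.normal(0, 0.03)
        structures.append(("vessel", cy, cx, r))

    n_b = int(rng.integers(spec.n_bronchi[0], spec.n_bronchi[1] + 1))
    for _ in range(max(1, n_b)):  # >= 1 bronchus always
        r_out = rng.uniform(0.06, 0.12) * n
        r_in = r_out * rng.uniform(0.5, 0.7)
        cy, cx = rng.uniform(r_out, n - r_out, size=2)
        wall = _disk(yy, xx, cy, cx, r_out) & ~_disk(yy, xx, cy, cx, r_in)
        lumen = _disk(yy, xx, cy, cx, r_in)
        img[wall] = _WALL_LEVEL + rng.normal(0, 0.03)
        img[lumen] = _LUMEN_LEVEL + rng.normal(0, 0.03)
        structures.append(("bronchus", cy, cx, r_out, r_in))

    img = np.clip(img, -1.0, 1.0)
    return ImagePatch(
        img, domain=MICRO, normalized=True,
        meta={"seed": seed, "structures": structures, "spec_hash": spec.spec_hash()},
    )


def degrade_to_clinical(hr: ImagePatch, spec: PhantomSpec,
                        rng: np.random.Generator | None = None) -> ImagePatch:
    """Forward model mapping a micro HR phantom to its clinical LR twin.

    blur → f↓ by s → monotone affine remap → additive Gaussian noise.
    Deterministic given (hr, spec) when ``noise_sigma`` is 0 or an RNG is
    derived from the HR phantom's seed (the default).
    """
    data = hr.data
    if spec.psf_sigma > 0:
        data = ndimage.gaussian_filter(data, spec.psf_sigma, mode="reflect")
    lr = average_pool_downsample(data, spec.s)
    lr = spec.remap_gain * lr + spec.remap_offset
    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(hr.meta.get("seed", 0)), 0x5EED])
            )
        lr = lr + rng.normal(0.0, spec.noise_sigma, size=lr.shape)
    lr = np.clip(lr, -1.0, 1.0)
    return ImagePatch(lr, domain=CLINICAL, normalized=True,
                      meta={"source_seed": hr.meta.get("seed"),
                            "spec_hash": spec.spec_hash()})


def make_unpaired_sets(
    spec: PhantomSpec, n_clinical: int, n_micro: int, seed: int
) -> tuple[list[ImagePatch], list[ImagePatch]]:
    """Unpaired training sets from disjoint phantom seed pools.

    The micro set is the HR phantoms of one seed pool; the clinical set is
    the degraded phantoms of a *different* pool, so no clinical image has a
    micro counterpart.
    """
    if n_clinical < 1 or n_micro < 1:
        raise ValueError("set sizes must be >= 1")
    ss = np.random.SeedSequence(seed)
    micro_seeds = [int(s) for s in
                   np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31, n_micro)]
    clin_seeds = [int(s) + 2**31 for s in
                  np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31, n_clinical)]
    if set(micro_seeds) & set(clin_seeds):
        raise ValueError("overlapping phantom seed pools")
    micro = [generate_micro_phantom(spec, s) for s in micro_seeds]
    clinical = [
        degrade_to_clinical(generate_micro_phantom(spec, s), spec)
        for s in clin_seeds
    ]
    return clinical, micro


def make_paired_eval_set(spec: PhantomSpec, n: int, seed: int) -> list[PhantomPair]:
    """n registered (HR, LR) pairs for evaluation / parameter recovery only."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE7A1]))
    seeds = [int(s) for s in rng.integers(2**31, 2**32 - 1, n)]
    pairs = []
    for s in seeds:
        hr = generate_micro_phantom(spec, s)
        lr = degrade_to_clinical(hr, spec)
        pairs.append(PhantomPair(hr=hr, lr=lr, seed=s, spec_hash=spec.spec_hash()))
    return pairs
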