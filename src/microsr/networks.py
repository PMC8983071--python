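"""SR-CycleGAN network builders.

The super-resolving generator ``G1`` maps an n×n clinical patch to a
(2^k·n)×(2^k·n) micro-CT-scale patch.  Relative to a conventional CycleGAN
generator, its stride-2 downblocks are removed (a 32×32 input would otherwise
be crushed to 4×4 feature maps) and k sub-pixel-shuffle upsampling stages are
appended.  The downscaling generator ``G2`` is its inverse: the same head
convolutions plus k stride-2 downblocks.  Discriminators are 70×70-receptive-
field PatchGANs emitting a 2-D score map.

Ablation variants match the configurations the method is compared against:

* ``SR_WITH_DOWNBLOCKS`` — keeps the k downblocks in front (bottlenecking a
  32×32 input to 4×4 at k=3) and therefore needs 2k shuffle stages,
* ``UPBLOCKS_BASELINE`` — a conventional CycleGAN generator (downblocks +
  mirror upblocks) with k extra deconvolution upblocks appended.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    PixelShuffle,
    ReLU,
    ResBlock,
    Sequential,
    Tanh,
    Tensor,
)

__all__ = [
    "Variant",
    "NetworkConfig",
    "NetworkBundle",
    "build_generator_sr",
    "build_generator_down",
    "build_discriminator",
    "build_variant",
    "build_networks",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


class Variant(str, Enum):
    SR_NO_DOWNBLOCKS = "sr"
    SR_WITH_DOWNBLOCKS = "downblocks"
    UPBLOCKS_BASELINE = "upblocks"


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``scale_k`` sets the scale factor 2^k; defaults follow the main 8×
    configuration: 9 residual blocks at 64 channels, head kernels 3×3 then
    7×7, batch normalization.
    """

    scale_k: int = 3
    n_resblocks: int = 9
    head_kernels: tuple[int, int] = (3, 7)
    tail_kernel: int = 7
    base_channels: int = 64
    norm: str = "batch"  # "batch" | "instance"
    variant: Variant = Variant.SR_NO_DOWNBLOCKS

    def __post_init__(self):
        if self.scale_k < 1:
            raise ValueError("scale_k must be >= 1 (scale factor 2^k >= 2)")
        if self.n_resblocks < 1:
            raise ValueError("n_resblocks must be >= 1")
        if any(k % 2 == 0 for k in (*self.head_kernels, self.tail_kernel)):
            raise ValueError("kernel sizes must be odd")
        if self.norm not in ("batch", "instance"):
            raise ValueError("norm must be 'batch' or 'instance'")
        object.__setattr__(self, "variant", Variant(self.variant))

    @property
    def scale(self) -> int:
        return 2**self.scale_k

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant"] = self.variant.value
        d["head_kernels"] = list(self.head_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["head_kernels"] = tuple(d.get("head_kernels", (3, 7)))
        return cls(**d)


@dataclass
class NetworkBundle:
    """The four trained/trainable networks of one SR-CycleGAN run."""

    G1: Module  # LR (clinical) -> SR (micro-scale)
    G2: Module  # HR (micro) -> LR (clinical-like)
    D1: Module  # discriminates the micro / HR domain
    D2: Module  # discriminates the clinical / LR domain
    config: NetworkConfig

    def train(self):
        for net in (self.G1, self.G2, self.D1, self.D2):
            net.train()
        return self

    def eval(self):
        for net in (self.G1, self.G2, self.D1, self.D2):
            net.eval()
        return self


def _norm_layer(cfg: NetworkConfig, n_ch: int) -> Module:
    return BatchNorm2d(n_ch) if cfg.norm == "batch" else InstanceNorm2d(n_ch)


def _head(cfg: NetworkConfig, rng) -> list[Module]:
    c = cfg.base_channels
    k1, k2 = cfg.head_kernels
    return [
        Conv2d(1, c, k1, rng, pad_mode="reflect"),
        _norm_layer(cfg, c),
        ReLU(),
        Conv2d(c, c, k2, rng, pad_mode="reflect"),
        _norm_layer(cfg, c),
        ReLU(),
    ]


def _resblocks(cfg: NetworkConfig, rng) -> list[Module]:
    return [ResBlock(cfg.base_channels, rng, norm=cfg.norm) for _ in range(cfg.n_resblocks)]


def _up_stage(cfg: NetworkConfig, rng) -> list[Module]:
    c = cfg.base_channels
    # ICNR init: the shuffle starts as nearest upsampling (no checkerboard)
    return [
        Conv2d(c, 4 * c, 3, rng, pad_mode="reflect", icnr_r=2),
        PixelShuffle(2),
        ReLU(),
    ]


def _down_block(cfg: NetworkConfig, rng) -> list[Module]:
    c = cfg.base_channels
    return [
        Conv2d(c, c, 3, rng, stride=2, pad=1, pad_mode="zero"),
        _norm_layer(cfg, c),
        ReLU(),
    ]


def _tail(cfg: NetworkConfig, rng) -> list[Module]:
    return [Conv2d(cfg.base_channels, 1, cfg.tail_kernel, rng, pad_mode="reflect"), Tanh()]


class _Generator(Sequential):
    """Generator wrapper enforcing the spatial-size contract."""

    def __init__(self, layers, scale_num: int, scale_den: int, min_input: int):
        super().__init__(*layers)
        self.scale_num = scale_num
        self.scale_den = scale_den
        self.min_input = min_input

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[-2], x.shape[-1]
        if H < self.min_input or W < self.min_input:
            raise ValueError(
                f"input {H}x{W} smaller than the minimum size {self.min_input}"
            )
        if H % self.scale_den or W % self.scale_den:
            raise ValueError(
                f"input {H}x{W} must be divisible by {self.scale_den}"
            )
        return super().forward(x)


def build_generator_sr(cfg: NetworkConfig, rng: np.random.Generator) -> Module:
    """G1 (no downblocks): head convs, resblocks, k shuffle stages, tanh tail."""
    if cfg.variant is not Variant.SR_NO_DOWNBLOCKS:
        raise ValueError("build_generator_sr requires variant SR_NO_DOWNBLOCKS")
    layers = _head(cfg, rng) + _resblocks(cfg, rng)
    for _ in range(cfg.scale_k):
        layers += _up_stage(cfg, rng)
    layers += _tail(cfg, rng)
    return _Generator(layers, scale_num=cfg.scale, scale_den=1,
                      min_input=max(cfg.head_kernels))


def build_generator_down(cfg: NetworkConfig, rng: np.random.Generator) -> Module:
    """G2: head convs, k stride-2 downblocks, resblocks, tanh tail."""
    layers = _head(cfg, rng)
    for _ in range(cfg.scale_k):
        layers += _down_block(cfg, rng)
    layers += _resblocks(cfg, rng) + _tail(cfg, rng)
    return _Generator(layers, scale_num=1, scale_den=cfg.scale,
                      min_input=cfg.scale)


def build_variant(cfg: NetworkConfig, rng: np.random.Generator) -> Module:
    """Ablation G1 variants (see module docstring)."""
    if cfg.variant is Variant.SR_WITH_DOWNBLOCKS:
        layers = _head(cfg, rng)
        for _ in range(cfg.scale_k):
            layers += _down_block(cfg, rng)
        layers += _resblocks(cfg, rng)
        for _ in range(2 * cfg.scale_k):
            layers += _up_stage(cfg, rng)
        layers += _tail(cfg, rng)
        return _Generator(layers, scale_num=cfg.scale, scale_den=cfg.scale,
                          min_input=cfg.scale)
    if cfg.variant is Variant.UPBLOCKS_BASELINE:
        c = cfg.base_channels
        layers = _head(cfg, rng)
        for _ in range(cfg.scale_k):
            layers += _down_block(cfg, rng)
        layers += _resblocks(cfg, rng)
        for _ in range(2 * cfg.scale_k):  # k to undo downblocks + k appended
            layers += [ConvTranspose2d(c, c, rng), _norm_layer(cfg, c), ReLU()]
        layers += _tail(cfg, rng)
        return _Generator(layers, scale_num=cfg.scale, scale_den=cfg.scale,
                          min_input=cfg.scale)
    raise ValueError(f"unknown ablation variant {cfg.variant}")


def build_discriminator(
    domain_size: int,
    rng: np.random.Generator,
    base_channels: int = 64,
    norm: str = "batch",
) -> Module:
    """PatchGAN discriminator emitting a 2-D real/fake score map.

    The standard 70×70-receptive-field layout (three stride-2 stages) is used
    when the input is large enough; for small domains the number of stride-2
    stages shrinks so the score map keeps at least a few patch decisions.
    """
    if domain_size < 16:
        raise ValueError("discriminator domain size must be >= 16")
    n_strided = min(3, max(1, int(np.log2(domain_size / 8))))
    c = base_channels
    Norm = BatchNorm2d if norm == "batch" else InstanceNorm2d
    layers: list[Module] = [
        Conv2d(1, c, 4, rng, stride=2, pad=1, pad_mode="zero"),
        LeakyReLU(0.2),
    ]
    ch = c
    for _ in range(n_strided - 1):
        nxt = min(ch * 2, 8 * c)
        layers += [
            Conv2d(ch, nxt, 4, rng, stride=2, pad=1, pad_mode="zero"),
            Norm(nxt),
            LeakyReLU(0.2),
        ]
        ch = nxt
    nxt = min(ch * 2, 8 * c)
    layers += [
        Conv2d(ch, nxt, 4, rng, stride=1, pad=1, pad_mode="zero"),
        Norm(nxt),
        LeakyReLU(0.2),
        Conv2d(nxt, 1, 4, rng, stride=1, pad=1, pad_mode="zero"),
    ]
    return Sequential(*layers)


def build_networks(
    cfg: NetworkConfig,
    lr_size: int,
    seed: int,
    disc_channels: int | None = None,
) -> NetworkBundle:
    """Instantiate all four networks with seeded Gaussian(0, 0.02) init."""
    rng = np.random.default_rng(seed)
    if cfg.variant is Variant.SR_NO_DOWNBLOCKS:
        G1 = build_generator_sr(cfg, rng)
    else:
        G1 = build_variant(cfg, rng)
    G2 = build_generator_down(cfg, rng)
    dc = disc_channels if disc_channels is not None else cfg.base_channels
    D1 = build_discriminator(lr_size * cfg.scale, rng, base_channels=dc, norm=cfg.norm)
    D2 = build_discriminator(max(lr_size, 16), rng, base_channels=dc, norm=cfg.norm)
    return NetworkBundle(G1, G2, D1, D2, cfg)


# ------------------------------------------------------------- checkpoints


def save_checkpoint(
    path, bundle: NetworkBundle, extra_meta: dict | None = None,
    optim_states: dict | None = None, extra_arrays: dict | None = None,
) -> None:
    """Write a single zip archive: four weight sets + config as embedded JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "network_config": bundle.config.to_dict(),
        **(extra_meta or {}),
    }
    with zipfile.ZipFile(path, "w") as zf:
        _write_member(zf, "meta.json", json.dumps(meta, indent=2).encode())
        for name in ("G1", "G2", "D1", "D2"):
            for key, arr in getattr(bundle, name).state_dict().items():
                _write_member(zf, f"{name}/{key}.npy", _npy_bytes(arr))
        if optim_states:
            for key, arr in _flatten_optim(optim_states).items():
                _write_member(zf, f"optim/{key}.npy", _npy_bytes(arr))
        if extra_arrays:
            for key, arr in extra_arrays.items():
                _write_member(zf, f"extra/{key}.npy", _npy_bytes(arr))


def load_checkpoint(path, lr_size: int, seed: int = 0,
                    disc_channels: int | None = None):
    """Rebuild a :class:`NetworkBundle` (and metadata) from an archive."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        cfg = NetworkConfig.from_dict(meta["network_config"])
        if disc_channels is None:
            disc_channels = meta.get("disc_channels")
        bundle = build_networks(cfg, lr_size, seed, disc_channels=disc_channels)
        members: dict[str, dict[str, np.ndarray]] = {}
        for entry in zf.namelist():
            if not entry.endswith(".npy"):
                continue
            group, key = entry.split("/", 1)
            arr = np.load(io.BytesIO(zf.read(entry)))
            members.setdefault(group, {})[key[: -len(".npy")]] = arr
        for name in ("G1", "G2", "D1", "D2"):
            getattr(bundle, name).load_state_dict(members.get(name, {}))
        optim_states = (
            _unflatten_optim(members["optim"]) if "optim" in members else None
        )
        extra_arrays = members.get("extra", {})
    return bundle, meta, optim_states, extra_arrays


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.save(buf, np.asarray(arr))
    return buf.getvalue()


def _write_member(zf: zipfile.ZipFile, name: str, payload: bytes) -> None:
    # fixed timestamp so identical state yields byte-identical archives
    info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, payload)


def _flatten_optim(states: dict) -> dict[str, np.ndarray]:
    flat: dict[str, np.ndarray] = {}
    for key, st in states.items():
        flat[f"{key}.lr"] = np.array(st["lr"])
        flat[f"{key}.t"] = np.array(st["t"])
        for i, a in enumerate(st["m"]):
            flat[f"{key}.m.{i}"] = a
        for i, a in enumerate(st["v"]):
            flat[f"{key}.v.{i}"] = a
    return flat


def _unflatten_optim(flat: dict[str, np.ndarray]) -> dict:
    states: dict[str, dict] = {}
    for name, arr in flat.items():
        key, field = name.split(".", 1)
        st = states.setdefault(key, {"m": {}, "v": {}})
        if field == "lr":
            st["lr"] = float(arr)
        elif field == "t":
            st["t"] = int(arr)
        else:
            kind, idx = field.split(".")
            st[kind][int(idx)] = arr
    for st in states.values():
        st["m"] = [st["m"][i] for i in sorted(st["m"])]
        st["v"] = [st["v"][i] for i in sorted(st["v"])]
    return states
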