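"""Run configuration: a single YAML file merging all component configs.

Sections map one-to-one onto the component dataclasses (``network``,
``train``, ``loss_weights``, ``phantom``, ``paths``).  Unknown keys are
rejected before any computation.  Two presets ship with the package:
``full`` (the 8×, 64-channel, 200-epoch configuration) and ``tiny``
(the CPU-sized 4× configuration used throughout the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .losses import LossWeights
from .networks import NetworkConfig
from .phantoms import PhantomSpec
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "PRESETS"]


@dataclass
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    paths: dict = field(default_factory=dict)
    disc_channels: int | None = None
    lr_patch_size: int = 32

    def resolved(self) -> dict:
        """Full config as a plain dict (for logging)."""
        return {
            "network": self.network.to_dict(),
            "train": self.train.to_dict(),
            "loss_weights": self.loss_weights.to_dict(),
            "phantom": {f.name: getattr(self.phantom, f.name)
                        for f in fields(self.phantom)},
            "paths": dict(self.paths),
            "disc_channels": self.disc_channels,
            "lr_patch_size": self.lr_patch_size,
        }


PRESETS: dict[str, dict] = {
    # full-scale configuration (GPU-intended)
    "full": {
        "network": {"scale_k": 3, "n_resblocks": 9, "base_channels": 64},
        "train": {"epochs": 200, "batch_size": 4, "lr0": 1e-5,
                  "decay_start_epoch": 100},
        "phantom": {"hr_size": 256, "s": 8},
        "lr_patch_size": 32,
    },
    # CPU-sized configuration for desk-scale runs and CI
    "tiny": {
        "network": {"scale_k": 2, "n_resblocks": 2, "base_channels": 8,
                    "head_kernels": [3, 3], "tail_kernel": 3, "norm": "instance"},
        "train": {"epochs": 2, "batch_size": 4, "lr0": 2e-4,
                  "decay_start_epoch": 1, "pool_size": 16},
        "phantom": {"hr_size": 64, "s": 4},
        "disc_channels": 8,
        "lr_patch_size": 16,
    },
}

_SECTION_TYPES = {
    "network": NetworkConfig,
    "train": TrainConfig,
    "loss_weights": LossWeights,
    "phantom": PhantomSpec,
}


def _build_section(cls, payload: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(payload)
    for key in ("betas", "head_kernels", "n_vessels", "n_bronchi"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path=None, preset: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a validated :class:`RunConfig` from preset, YAML file, overrides.

    Later sources win: preset < file < overrides.
    """
    import copy

    merged: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        _deep_update(merged, copy.deepcopy(PRESETS[preset]))
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        _deep_update(merged, loaded)
    if overrides:
        _deep_update(merged, overrides)

    known_top = set(_SECTION_TYPES) | {"paths", "disc_channels", "lr_patch_size"}
    unknown = set(merged) - known_top
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    sections = {
        name: _build_section(cls, merged.get(name, {}))
        for name, cls in _SECTION_TYPES.items()
    }
    return RunConfig(
        network=sections["network"],
        train=sections["train"],
        loss_weights=sections["loss_weights"],
        phantom=sections["phantom"],
        paths=merged.get("paths", {}),
        disc_channels=merged.get("disc_channels"),
        lr_patch_size=merged.get("lr_patch_size", 32),
    )


def _deep_update(dst: dict, src: dict) -> None:
    for k, v in src.items():
        if isinstance(v, dict) and isinstance(dst.get(k), dict):
            _deep_update(dst[k], v)
        else:
            dst[k] = v
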