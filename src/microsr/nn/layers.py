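"""Neural-network layers on top of the autodiff engine.

Conventions follow the CycleGAN lineage: reflection padding inside generators,
zero padding inside discriminators, batch normalization with running statistics
(instance norm available as a switch), Gaussian(0, 0.02) weight initialization
from a caller-supplied seeded RNG.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (
    Tensor,
    avg_pool2d,
    conv2d,
    dilate2d,
    nearest_upsample2d,
    pad2d,
    pixel_shuffle,
)

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "ResBlock",
    "PixelShuffle",
    "AvgPool",
    "NearestUpsample",
]

INIT_STD = 0.02  # DCGAN/CycleGAN convention
DTYPE = np.float32  # parameter/activation precision of the training stack


class Module:
    """Minimal module base: parameter traversal, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> Iterator[Tensor]:
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
        for child in self.children():
            yield from child.parameters()

    def buffers(self) -> Iterator[np.ndarray]:
        for name, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                yield v
        for child in self.children():
            yield from child.buffers()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- state (weights + running stats) as a flat {path: array} dict --------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[path] = v.data.copy()
            elif isinstance(v, np.ndarray):
                out[path] = v.copy()
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix=f"{path}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(prefix=f"{path}.{i}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                if v.data.shape != state[path].shape:
                    raise ValueError(f"shape mismatch loading {path}")
                v.data[...] = state[path]
            elif isinstance(v, np.ndarray):
                v[...] = state[path]
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix=f"{path}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{path}.{i}.")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution with same/valid padding and seeded Gaussian init.

    ``icnr_r`` activates ICNR initialization (Aitken et al.) for a conv that
    feeds a sub-pixel shuffle of factor r: all r^2 sub-pixel channels of an
    output group start identical, so the shuffle initially acts as nearest
    upsampling and the checkerboard artifact of naive sub-pixel convolution
    is avoided.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        pad_mode: str = "reflect",
        bias: bool = True,
        icnr_r: int | None = None,
    ):
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.stride = int(stride)
        self.pad = (kernel - 1) // 2 if pad is None else int(pad)
        self.pad_mode = pad_mode
        if icnr_r is None:
            w = rng.normal(0.0, INIT_STD, size=(out_ch, in_ch, kernel, kernel))
        else:
            r2 = icnr_r * icnr_r
            if out_ch % r2:
                raise ValueError("out_ch must be divisible by icnr_r^2")
            seed_w = rng.normal(0.0, INIT_STD, size=(out_ch // r2, in_ch, kernel, kernel))
            w = np.repeat(seed_w, r2, axis=0)
        self.weight = Tensor(w.astype(DTYPE), requires_grad=True)
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        if self.pad:
            x = pad2d(x, self.pad, mode=self.pad_mode)
        return conv2d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose2d(Module):
    """Stride-2 deconvolution (upblock): zero-dilate then convolve.

    Doubles the spatial size; equivalent to a transposed convolution with
    stride 2, kernel 3, output padding 1.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.kernel = kernel
        self.weight = Tensor(
            rng.normal(0.0, INIT_STD, size=(out_ch, in_ch, kernel, kernel)).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        up = dilate2d(x, 2)  # (2H-1, 2W-1)
        p = (self.kernel - 1) // 2
        up = pad2d(up, p + 1, mode="zero")
        y = conv2d(up, self.weight, self.bias, stride=1)
        # trim to exactly 2H x 2W
        N, C, H, W = y.shape
        target_h, target_w = 2 * x.shape[-2], 2 * x.shape[-1]
        if (H, W) != (target_h, target_w):
            data = y.data[:, :, :target_h, :target_w]
            src = y
            out = Tensor(data, _parents=(src,))

            def bwd(g):
                if src.requires_grad:
                    gg = np.zeros_like(src.data)
                    gg[:, :, :target_h, :target_w] = g
                    src._accumulate(gg)

            out._backward = bwd
            return out
        return y


class _NormBase(Module):
    def __init__(self, n_ch: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones((1, n_ch, 1, 1), dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_ch, 1, 1), dtype=DTYPE), requires_grad=True)


class BatchNorm2d(_NormBase):
    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(n_ch, eps)
        self.momentum = momentum
        self.running_mean = np.zeros((1, n_ch, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, n_ch, 1, 1), dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data - self.running_mean)
            self.running_var += self.momentum * (var.data - self.running_var)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return self.gamma * xhat + self.beta


class InstanceNorm2d(_NormBase):
    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return self.gamma * xhat + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class PixelShuffle(Module):
    def __init__(self, r: int):
        super().__init__()
        self.r = r

    def forward(self, x: Tensor) -> Tensor:
        return pixel_shuffle(x, self.r)


class AvgPool(Module):
    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.factor)


class NearestUpsample(Module):
    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return nearest_upsample2d(x, self.factor)


class ResBlock(Module):
    """Residual block: two 3x3 convs with norm, ReLU after the first, skip add."""

    def __init__(self, n_ch: int, rng: np.random.Generator, norm: str = "batch"):
        super().__init__()
        Norm = BatchNorm2d if norm == "batch" else InstanceNorm2d
        self.conv1 = Conv2d(n_ch, n_ch, 3, rng, pad_mode="reflect")
        self.norm1 = Norm(n_ch)
        self.conv2 = Conv2d(n_ch, n_ch, 3, rng, pad_mode="reflect")
        self.norm2 = Norm(n_ch)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h
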