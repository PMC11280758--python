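"""Neural-network layers built on the autodiff engine.

Layers follow the familiar Module pattern: parameters are discovered by
recursing through attributes, ``train()``/``eval()`` toggle batch-norm
behaviour, and ``state_dict``/``load_state_dict`` move weights as plain
numpy arrays (saved with ``np.savez``).
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- parameter / submodule discovery ---------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialization ----------------------------------------------------
    def _buffers(self) -> Iterator[Tuple[str, str, np.ndarray]]:
        for m_name, m in self._named_modules():
            for b in getattr(m, "_buffer_names", ()):
                yield m_name, b, getattr(m, b)

    def _named_modules(self, prefix: str = "") -> Iterator[Tuple[str, "Module"]]:
        yield prefix.rstrip("."), self
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value._named_modules(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{name}.{i}.")

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for m_name, b_name, arr in self._buffers():
            key = f"{m_name}.{b_name}" if m_name else b_name
            state[f"__buf__.{key}"] = np.asarray(arr).copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {
            (f"{m}.{b}" if m else b): (m, b) for m, b, _ in self._buffers()
        }
        mods = dict(self._named_modules())
        for key, arr in state.items():
            if key.startswith("__buf__."):
                ref = key[len("__buf__."):]
                if ref not in buffers:
                    raise KeyError(f"unknown buffer {ref!r}")
                m_name, b_name = buffers[ref]
                setattr(mods[m_name], b_name, np.asarray(arr).copy())
            else:
                if key not in params:
                    raise KeyError(f"unknown parameter {key!r}")
                if params[key].shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: "
                        f"{params[key].shape} vs {arr.shape}"
                    )
                params[key].data = np.asarray(arr, dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        k, s, p = self.kernel, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = ad.im2col(x, k, k, s, p)                        # (N, C*k*k, L)
        w_mat = self.weight.reshape(self.out_ch, self.in_ch * k * k)
        out = ad.matmul(w_mat, cols)                            # (N, OC, L)
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_ch, 1)
        return out.reshape(n, self.out_ch, oh, ow)


class ConvTranspose2d(Module):
    """Transposed (fractionally strided) convolution, the deconvolution used
    to restore resolution in the decoder."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (in_ch, out_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        k, s, p = self.kernel, self.stride, self.pad
        oh = (h - 1) * s - 2 * p + k
        ow = (w - 1) * s - 2 * p + k
        x_flat = x.reshape(n, c, h * w)
        w_mat = self.weight.reshape(self.in_ch, self.out_ch * k * k)
        cols = ad.matmul(w_mat.transpose(1, 0), x_flat)         # (N, OC*k*k, L)
        out = ad.col2im(cols, (oh, ow), self.out_ch, k, k, s, p)
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_ch, 1, 1)
        return out


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = float(np.prod([x.shape[i] for i in axes]))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var * (m / max(m - 1.0, 1.0))
            )
            xhat = ad.normalize(x, axes, self.eps)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - mu) / ad.sqrt(var + self.eps)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class BatchNorm1d(Module):
    """Batch norm over (N, C) feature matrices (used inside the codebook)."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} features, got {x.shape[-1]}")
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = float(np.prod([x.shape[i] for i in axes]))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var * (m / max(m - 1.0, 1.0))
            )
            xhat = ad.normalize(x, axes, self.eps)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
            xhat = (x - mu) / ad.sqrt(var + self.eps)
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return ad.normalize(x, -1, self.eps) * self.gamma + self.beta


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_dim, self.out_dim = in_dim, out_dim
        bound = np.sqrt(1.0 / in_dim)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(in_dim, out_dim)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = ad.im2col(x, k, k, s, p).reshape(n, c, k * k, oh * ow)
        return cols.max(axis=2).reshape(n, c, oh, ow)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class CBR(Module):
    """3x3 convolution -> batch norm -> ReLU, the basic fusion block."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(self.bn(self.conv(x)))
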