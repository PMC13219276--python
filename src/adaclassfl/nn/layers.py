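"""Neural-network layers on top of the autodiff engine.

Modules mirror the familiar container conventions: named parameters and
persistent buffers, a train/eval flag, ``state_dict``/``load_state_dict``
round-tripping plain numpy arrays (the currency the federated server and
clients exchange).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d

__all__ = [
    "Parameter", "Module", "Sequential", "Identity", "ReLU", "SiLU",
    "Conv2d", "BatchNorm2d", "LayerNorm", "Linear", "Dropout",
    "MultiHeadSelfAttention", "GlobalAvgPool2d",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- registry ----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        if not hasattr(self, "_buffer_names"):
            self._buffer_names = []
        self._buffer_names.append(name)
        setattr(self, name, value)

    # -- modes -------------------------------------------------------------
    def train(self):
        self.training = True
        for m in self._children():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._children():
            m.eval()
        return self

    def _children(self):
        for val in vars(self).items():
            pass
        for val in vars(self).values():
            if isinstance(val, Module):
                yield val
            elif isinstance(val, (list, tuple)):
                yield from (v for v in val if isinstance(v, Module))

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=np.float64).copy()
            elif name in bufs:
                self._set_buffer(name, np.asarray(arr).copy())
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj, parts = self, dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], value)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = list(modules)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class BatchNorm2d(Module):
    """Per-channel normalization with learned scale/shift and running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.weight + self.bias


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias

    def forward(self, x):
        out = x @ self.weight
        return out if self.bias is None else out + self.bias


class Dropout(Module):
    """Inverted dropout; active only in training mode. The mask is drawn from
    an rng set on the module (``set_rng``) so runs stay reproducible."""

    def __init__(self, p: float = 0.2):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (B, N, D) sequences."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if dim % n_heads:
            raise ValueError("embedding dim must be divisible by n_heads")
        rng = rng or np.random.default_rng(0)
        self.n_heads = n_heads
        self.dim = dim
        self.q = Linear(dim, dim, rng=rng)
        self.k = Linear(dim, dim, rng=rng)
        self.v = Linear(dim, dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)

    def forward(self, x):
        B, N, D = x.shape
        h, dh = self.n_heads, D // self.n_heads

        def split(t):  # (B, N, D) -> (B, h, N, dh)
            return t.reshape(B, N, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        att = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


class GlobalAvgPool2d(Module):
    def forward(self, x):
        return x.mean(axis=(2, 3))
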