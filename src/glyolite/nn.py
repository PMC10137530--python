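"""Minimal neural-network module system over the autograd engine."""

from __future__ import annotations

import numpy as np

from . import ops
from .tensor import Parameter, Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "BatchNorm2d", "MaxPool2d",
    "UpsampleNearest2", "SiLU", "ReLU", "Identity", "autopad",
]


def autopad(k: int, p: int | None = None) -> int:
    return k // 2 if p is None else p


class Module:
    def __init__(self):
        self.training = True

    # -- registry -----------------------------------------------------------
    def children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self.children():
            yield from child.named_buffers(prefix + cname + ".")

    def modules(self):
        yield self
        for _, child in self.children():
            yield from child.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        for name, p in self.named_parameters():
            p.data = np.asarray(d[name], dtype=np.float32)
        for name, _ in self.named_buffers():
            obj, attr = self._resolve(name)
            setattr(obj, attr, np.asarray(d[name]))

    def _resolve(self, dotted: str):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def __getitem__(self, i):
        return self.mods[i]

    def __len__(self):
        return len(self.mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, g: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c1 % g or c2 % g:
            raise ValueError(f"channels ({c1}->{c2}) not divisible by groups={g}")
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = autopad(k, p)
        rng = rng or np.random.default_rng()
        fan_in = c1 // g * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (c2, c1 // g, k, k)).astype(np.float32)
        )
        self.bias = (
            Parameter(rng.uniform(-bound, bound, c2).astype(np.float32))
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.weight, self.bias, self.s, self.p, self.g)

    def children(self):
        yield from ()

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias


class BatchNorm2d(Module):
    """Batch normalisation; eps 1e-3, momentum 0.03 (detector convention)."""

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xhat = (x - mu) / Tensor(sd)
        w = self.weight.reshape(1, self.c, 1, 1)
        b = self.bias.reshape(1, self.c, 1, 1)
        return xhat * w + b


class MaxPool2d(Module):
    def __init__(self, k: int, s: int | None = None, p: int = 0,
                 ceil_mode: bool = False):
        super().__init__()
        self.k, self.s, self.p, self.ceil_mode = k, s or k, p, ceil_mode

    def forward(self, x):
        return ops.max_pool2d(x, self.k, self.s, self.p, self.ceil_mode)


class UpsampleNearest2(Module):
    def forward(self, x):
        return ops.upsample_nearest2(x)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Identity(Module):
    def forward(self, x):
        return x
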