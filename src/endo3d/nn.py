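"""Minimal neural-network layer and optimiser toolkit over :mod:`endo3d.autodiff`.

Layers hold :class:`Parameter` tensors; a :class:`Module` tree exposes them
through ``parameters()`` for the Adam optimiser.  Weight initialisation is
driven by an explicit ``numpy.random.Generator`` so that identical seeds give
bit-identical networks.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: child modules/parameters are discovered via attributes."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _iter_params(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            for m in _iter_modules(v):
                yield from m.modules()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = list(self.parameters())
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _iter_params(v):
    if isinstance(v, Parameter):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _iter_params(item)


def _iter_modules(v):
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _iter_modules(item)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 2,
                 padding: int = 1, output_padding: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        self.weight = Parameter(_kaiming(rng, (c_in, c_out, k, k), c_in * k * k))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride,
                                self.padding, self.output_padding)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            return xc / (var + self.eps).sqrt() * g + b
        mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
        var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        return (x - mu) / (var + self.eps).sqrt() * g + b


def set_training(module: Module, flag: bool) -> None:
    for m in module.modules():
        if hasattr(m, "training"):
            m.training = flag


class Adam:
    """Adam optimiser (Kingma & Ba) with the usual bias correction."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
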