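"""Module containers: convolution, linear, and parameter bookkeeping."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor


class Module:
    """Minimal module base: recursive parameter discovery over attributes."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            params.extend(_collect(v))
        return params

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _collect(v):
    if isinstance(v, Parameter):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    if isinstance(v, dict):
        out = []
        for item in v.values():
            out.extend(_collect(item))
        return out
    return []


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, rng: np.random.Generator,
                 init: str = "he", init_std: float | None = None):
        fan_in = cin * k * k
        if init == "zero":
            w = np.zeros((cout, cin, k, k))
        elif init == "normal":
            w = rng.normal(0.0, init_std if init_std is not None else 0.01,
                           size=(cout, cin, k, k))
        else:  # He normal, suited to the ReLU nonlinearity used throughout
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout))
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, din: int, dout: int, *, rng: np.random.Generator,
                 init: str = "he", init_std: float | None = None):
        if init == "zero":
            w = np.zeros((dout, din))
        elif init == "normal":
            w = rng.normal(0.0, init_std if init_std is not None else 0.01,
                           size=(dout, din))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / din), size=(dout, din))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(dout))

    def __call__(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)
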