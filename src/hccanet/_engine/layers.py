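"""Parameterised layers built on the autodiff tensor.

Initialisation is seed-controlled uniform fan-in scaling with rectifier
gain: U(-sqrt(6/fan_in), +sqrt(6/fan_in)) (variance 2/fan_in, which keeps
activation magnitudes stable through deep ReLU stacks), biases zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .tensor import Tensor, conv2d, matmul, maxpool2x2

__all__ = ["Parameter", "Module", "Conv2D", "Dense", "MaxPool2", "uniform_fan_in"]


def uniform_fan_in(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, trainable: bool = True):
        super().__init__(data, requires_grad=trainable)


class Module:
    """Minimal container: recursively collects parameters from attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def trainable_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters() if p.requires_grad]

    def n_parameters(self, trainable_only: bool = False) -> int:
        params = self.trainable_parameters() if trainable_only else self.parameters()
        return int(sum(p.data.size for p in params))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=np.float64)


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)
    elif dataclasses.is_dataclass(value) and not isinstance(value, type):
        for f in dataclasses.fields(value):
            yield from _collect(getattr(value, f.name))


class Conv2D(Module):
    """Stride-1 'same' convolution, NHWC."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True, trainable: bool = True, name: str = ""):
        if k % 2 == 0 or k < 1:
            raise ValueError(f"kernel size must be odd and >= 1, got {k}")
        fan_in = k * k * cin
        self.name = name
        self.w = Parameter(uniform_fan_in(rng, (k, k, cin, cout), fan_in), trainable)
        self.b = Parameter(np.zeros(cout), trainable) if bias else None

    @property
    def trainable(self) -> bool:
        return self.w.requires_grad

    def set_trainable(self, flag: bool) -> None:
        self.w.requires_grad = flag
        if self.b is not None:
            self.b.requires_grad = flag

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 trainable: bool = True, name: str = ""):
        self.name = name
        self.w = Parameter(uniform_fan_in(rng, (cin, cout), cin), trainable)
        self.b = Parameter(np.zeros(cout), trainable)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class MaxPool2(Module):
    def __init__(self, name: str = ""):
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)
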