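"""Neural-network layers and optimisation on top of the autodiff tape.

Initialisation is explicit about its RNG: every layer takes a
``numpy.random.Generator``, so a model built twice from the same seed has
bitwise-identical parameters.  Two init schemes are exposed because the
denoiser compares them: ``uniform`` (fan-in scaled, the default) and
``normal`` (zero-mean, sd 0.02).
"""
from __future__ import annotations

import numpy as np

from ._autograd import DTYPE, Tensor, conv1d, conv_transpose1d


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def _init_weight(rng: np.random.Generator, shape, fan_in: int, scheme: str) -> np.ndarray:
    if scheme == "uniform":
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)
    if scheme == "normal":
        return rng.normal(0.0, 0.02, size=shape)
    raise ValueError(f"unknown init scheme {scheme!r}")


class Module:
    """Minimal container: parameter discovery by attribute walk."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in vars(self).values():
            for m in _iter_modules(v):
                m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # flat name -> ndarray mapping, for checkpointing
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError(
                f"state has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=DTYPE).copy()


def _iter_modules(obj):
    if isinstance(obj, Module):
        yield obj
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            yield from _iter_modules(v)


class Conv1d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: tuple[int, int] = (0, 0),
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init: str = "uniform",
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = parameter(
            _init_weight(rng, (out_channels, in_channels, kernel_size), fan_in, init)
        )
        self.bias = parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, dilation=self.dilation,
        )


class ConvTranspose1d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init: str = "uniform",
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.stride, self.padding = stride, padding
        self.weight = parameter(
            _init_weight(rng, (in_channels, out_channels, kernel_size), fan_in, init)
        )
        self.bias = parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose1d(
            x, self.weight, self.bias, stride=self.stride, padding=self.padding
        )


class WNConv1d(Module):
    """Weight-normalised causal-capable convolution: w = g * v / ||v||."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: tuple[int, int] = (0, 0),
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        init: str = "uniform",
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        v = _init_weight(rng, (out_channels, in_channels, kernel_size), fan_in, init)
        self.v = parameter(v)
        norms = np.sqrt((v**2).sum(axis=(1, 2), keepdims=True))
        self.g = parameter(norms)  # so initial effective weight equals v
        self.bias = parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        norm = ((self.v**2).sum(axis=(1, 2), keepdims=True) + 1e-12).sqrt()
        w = self.v * (self.g / norm)
        return conv1d(
            x, w, self.bias,
            stride=self.stride, padding=self.padding, dilation=self.dilation,
        )


class InstanceNorm1d(Module):
    """Per-sample, per-channel normalisation over the time axis."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self.gamma = parameter(np.ones((channels, 1))) if affine else None
        self.beta = parameter(np.zeros((channels, 1))) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=2, keepdims=True)
        centred = x - mu
        var = (centred**2).mean(axis=2, keepdims=True)
        y = centred * ((var + self.eps) ** -0.5)
        if self.gamma is not None:
            y = y * self.gamma + self.beta
        return y


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        init: str = "uniform",
    ):
        rng = rng or np.random.default_rng()
        self.weight = parameter(
            _init_weight(rng, (in_features, out_features), in_features, init)
        )
        self.bias = parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)
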