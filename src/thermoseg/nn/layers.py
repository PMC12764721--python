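"""Neural-network building blocks on top of the autodiff engine.

Feature maps are laid out channels-last: (batch, height, width, channels).
All layers take an ``numpy.random.Generator`` at construction so weight
initialization is fully reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, as_tensor, conv2d, gelu

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm",
    "Dropout",
    "Mlp",
    "Conv2d",
]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def modules(self):
        def walk(value):
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    yield from walk(item)

        for value in self.__dict__.values():
            yield from walk(value)

    def parameters(self):
        seen = set()
        for mod in (self, *self.modules()):
            for value in mod.__dict__.values():
                if isinstance(value, Parameter) and id(value) not in seen:
                    seen.add(id(value))
                    yield value

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def _buffers(self):
        """Non-trainable state (e.g. batch-norm running stats), in a stable order."""
        for mod in (self, *self.modules()):
            if isinstance(mod, BatchNorm):
                yield mod, "running_mean"
                yield mod, "running_var"

    def state_dict(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        arrays.extend(getattr(mod, name).copy() for mod, name in self._buffers())
        return arrays

    def load_state_dict(self, state: list[np.ndarray]):
        params = list(self.parameters())
        buffers = list(self._buffers())
        if len(params) + len(buffers) != len(state):
            raise ValueError(
                f"expected {len(params) + len(buffers)} arrays, got {len(state)}")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = np.asarray(arr, dtype=np.float64).copy()
        for (mod, name), arr in zip(buffers, state[len(params):]):
            setattr(mod, name, np.asarray(arr, dtype=np.float64).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (in_features + out_features))
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        shape = x.shape
        flat = x.reshape(-1, shape[-1]) if x.ndim != 2 else x
        out = flat @ self.weight
        if self.bias is not None:
            out = out + self.bias
        if x.ndim != 2:
            out = out.reshape(*shape[:-1], self.weight.shape[1])
        return out


class LayerNorm(Module):
    """Normalization over the last (channel) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        norm = xc / (var + self.eps).sqrt()
        return norm * self.gamma + self.beta


class BatchNorm(Module):
    """Per-channel normalization over (batch, height, width).

    Uses batch statistics while training and exponential running averages
    at evaluation time.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            norm = xc / (var + self.eps).sqrt()
        else:
            norm = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return norm * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout: active only while training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float64) / keep
        return x * Tensor(mask)


class Mlp(Module):
    """Two affine maps with a GELU in between; dropout on the hidden layer."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(gelu(self.fc1(x))))


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = kernel * kernel * in_ch
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, (kernel, kernel, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(as_tensor(x), self.weight, stride=self.stride, padding=self.padding)
        if self.bias is not None:
            out = out + self.bias
        return out
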