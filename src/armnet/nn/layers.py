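"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "Module", "Parameter", "Conv2d", "Linear", "BatchNorm2d", "ReLU",
    "MaxPool2d", "Sequential", "ModuleList", "Identity",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: children and parameters discovered from attributes."""

    def __init__(self):
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name.startswith("_") or name == "training":
                continue
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization --------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, p in self.named_parameters(prefix):
            state[name] = p.data
        for m_name, m in self._named_modules(prefix):
            for b_name, buf in m._buffers.items():
                state[f"{m_name}{b_name}"] = buf
        return state

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, value in vars(self).items():
            if isinstance(value, Module) and not name.startswith("_"):
                yield from value._named_modules(f"{prefix}{name}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = {f"{m_name}{b_name}": (m, b_name)
                   for m_name, m in self._named_modules()
                   for b_name in m._buffers}
        missing = (set(own) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state_dict missing keys: {sorted(missing)[:5]}...")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, (m, b_name) in buffers.items():
            m._buffers[b_name][...] = state[name]

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        shape = (out_channels, in_channels, kernel_size, kernel_size)
        if zero_init:
            w = np.zeros(shape)
        else:
            rng = rng if rng is not None else np.random.default_rng()
            w = _he_normal(rng, shape, in_channels * kernel_size * kernel_size)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.weight = Parameter(_he_normal(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        return T.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self._buffers["running_mean"] = np.zeros(num_features, dtype=np.float32)
        self._buffers["running_var"] = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        return T.batchnorm2d(x, self.weight, self.bias,
                             self._buffers["running_mean"],
                             self._buffers["running_var"],
                             training=self.training, momentum=self.momentum,
                             eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class MaxPool2d(Module):
    """2x2, stride-2 max pooling (the only variant the backbones use)."""

    def forward(self, x):
        return T.maxpool2x2(x)


class Identity(Module):
    def forward(self, x):
        return x


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, str(i), m)

    def __iter__(self):
        i = 0
        while hasattr(self, str(i)):
            yield getattr(self, str(i))
            i += 1

    def __getitem__(self, i):
        return getattr(self, str(i))

    def __len__(self):
        return sum(1 for _ in self)

    def append(self, m: Module):
        setattr(self, str(len(self)), m)

    def forward(self, *a, **k):  # pragma: no cover
        raise NotImplementedError("ModuleList is a container")


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x
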