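"""Layer abstractions over the autodiff tensor: parameter containers,
convolution/linear/normalization layers and Kaiming initialization."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import DTYPE, Tensor, conv3d


class Parameter(Tensor):
    """Learnable weight; always stored at the network dtype (float32)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Minimal parameter-tree container with state_dict support."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(DTYPE).copy()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv3d(Module):
    """Stride-1 'same' 3-D convolution layer (kernel 1 or 3)."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        fan_in = cin * kernel ** 3
        w = np.zeros((cout, cin, kernel, kernel, kernel), dtype=DTYPE) if zero_init \
            else kaiming_normal(rng, (cout, cin, kernel, kernel, kernel), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        w = np.zeros((cin, cout), dtype=DTYPE) if zero_init else kaiming_normal(rng, (cin, cout), cin)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GroupNorm(Module):
    """Group normalization over (channels-in-group, spatial); batch-size-1 safe."""

    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % num_groups:
            raise ValueError(f"channels {channels} not divisible by groups {num_groups}")
        self.groups = num_groups
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=DTYPE))
        self.bias = Parameter(np.zeros(channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w, d = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * h * w * d)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        xn = xn.reshape(n, c, h, w, d)
        gamma = self.weight.reshape(1, c, 1, 1, 1)
        beta = self.bias.reshape(1, c, 1, 1, 1)
        return xn * gamma + beta


def default_groups(channels: int, target: int = 8) -> int:
    """Largest divisor of `channels` that is <= target."""
    for g in range(min(target, channels), 0, -1):
        if channels % g == 0:
            return g
    return 1
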