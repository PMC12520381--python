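"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, conv_transpose2x2, maxpool2x2, pad2d

__all__ = ["Module", "Linear", "Conv2d", "ConvTranspose2x2", "GroupNorm",
           "MaxPool2d", "Activation", "Sequential", "MLP"]

_ACTS = {
    "silu": lambda t: t.silu(),
    "gelu": lambda t: t.gelu(),
    "sin": lambda t: t.sin(),
    "tanh": lambda t: t.tanh(),
    "relu": lambda t: t.relu(),
    "identity": lambda t: t,
}


class Module:
    """Base class: tracks parameters through attribute discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)
        visit(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, padding: int | None = None):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.padding = (k // 2) if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, padding=self.padding)


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transposed convolution (doubles H and W)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 4))
        self.w = Tensor(rng.normal(0.0, scale, (c_in, c_out, 2, 2)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.w, self.b)


class GroupNorm(Module):
    def __init__(self, n_groups: int, n_channels: int, eps: float = 1e-5):
        if n_channels % n_groups:
            raise ValueError("channels must divide evenly into groups")
        self.n_groups = n_groups
        self.eps = eps
        self.gamma = Tensor(np.ones((1, n_channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_channels, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.n_groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn.reshape(n, c, h, w) * self.gamma + self.beta


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class Activation(Module):
    def __init__(self, name: str):
        if name not in _ACTS:
            raise ValueError(f"unknown activation {name!r}")
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        return _ACTS[self.name](x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class MLP(Module):
    """Fully connected stack with a common hidden activation."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 activation: str = "silu", final_activation: str = "identity"):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes, sizes[1:])]
        self.act = Activation(activation)
        self.final = Activation(final_activation)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = self.act(layer(x))
        return self.final(self.layers[-1](x))
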