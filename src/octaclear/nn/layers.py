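"""Network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, instance_norm, leaky_relu, relu


class Module:
    """Base class; parameters are discovered recursively from attributes."""

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """3x3 (or kxk) convolution with He-initialized weights."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            std = np.sqrt(2.0 / (cin * k * k))
            w = rng.normal(0.0, std, size=(cout, cin, k, k))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class InstanceNorm2d(Module):
    def __init__(self, ch: int):
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)

    def forward(self, x):
        return instance_norm(x, self.gamma, self.beta)


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        return leaky_relu(x, self.alpha)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
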