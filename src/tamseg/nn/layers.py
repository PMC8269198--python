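"""Neural-network layers built on the autodiff engine.

Modules own named parameters and buffers (running statistics), support
train/eval mode, and serialize to flat ``name -> array`` dictionaries.
Initialisation is deterministic: every layer takes the ``numpy`` Generator it
draws its weights from.
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, concat, conv2d, maxpool2x2, upsample_nearest)

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "Sequential",
           "MaxPool2d", "Upsample", "Identity"]


class Module:
    """Base class: parameter registry, mode flag, state-dict I/O."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        return value

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, child in self._children.items():
            out.update(child.named_state(prefix + name + "."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, t in self._params.items():
            src = state[prefix + k]
            if src.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {prefix + k}")
            t.data = src.astype(t.data.dtype)
        for k in self._buffers:
            self._buffers[k] = state[prefix + k].astype(self._buffers[k].dtype)
            setattr(self, k, self._buffers[k])
        for name, child in self._children.items():
            child.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None,
                 dilation: int = 1, groups: int = 1, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = dilation * (k - 1) // 2  # 'same' for stride 1
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups
        fan_in = cin // groups * k * k
        w = rng.standard_normal((cout, cin // groups, k, k)) * np.sqrt(2.0 / fan_in)
        self.weight = self.register_param("weight", w.astype(np.float32))
        self.bias = self.register_param("bias", np.zeros(cout, np.float32)) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation,
                      groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.register_param("gamma", np.ones(channels, np.float32))
        self.beta = self.register_param("beta", np.zeros(channels, np.float32))
        self.running_mean = self.register_buffer(
            "running_mean", np.zeros(channels, np.float32))
        self.running_var = self.register_buffer(
            "running_var", np.ones(channels, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            v = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            xhat = xc * ((v + self.eps) ** -0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class Upsample(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest(x, self.factor)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
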