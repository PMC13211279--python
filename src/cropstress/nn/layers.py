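"""Layers: convolution, batch normalization, and Conv-Norm-Activation blocks."""

from __future__ import annotations

import numpy as np

from cropstress.nn.tensor import Tensor
from cropstress.nn import ops


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for prefix, mod in self._named_modules():
            for name, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    yield f"{prefix}{name}", v

    def _named_modules(self, prefix=""):
        yield prefix, self
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self):
        for prefix, mod in self._named_modules():
            for name, v in mod.__dict__.items():
                if isinstance(v, np.ndarray):
                    yield f"{prefix}{name}", v

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            else:
                prefix, attr = name.rsplit(".", 1) if "." in name else ("", name)
                for p, mod in self._named_modules():
                    if p == (prefix + "." if prefix else ""):
                        setattr(mod, attr, np.asarray(value).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if pad is None:
            pad = kernel // 2
        self.stride, self.pad = stride, pad
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones((1, num_features, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1)))
        self.running_mean = np.zeros((1, num_features, 1, 1))
        self.running_var = np.ones((1, num_features, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class ConvBlock(Module):
    """Two Conv-Norm-ReLU units, the basic building block of the backbone."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()
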