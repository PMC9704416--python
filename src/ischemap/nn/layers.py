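"""Module/layer abstractions over the autograd core."""

from __future__ import annotations

import numpy as np

from ischemap.nn import functional as F
from ischemap.nn.autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter discovery, train/eval mode, rng."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def set_rng(self, rng: np.random.Generator):
        if hasattr(self, "rng"):
            self.rng = rng
        for _, child in self._children():
            child.set_rng(rng)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- flat state (buffers included) for serialization ------------------
    def named_buffers(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield prefix + name, v
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict:
        d = {f"p:{k}": p.data for k, p in self.named_parameters()}
        d.update({f"b:{k}": v for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict) -> None:
        params = dict(self.named_parameters())
        for key, val in d.items():
            kind, name = key.split(":", 1)
            if kind == "p":
                params[name].data[...] = val
            else:
                obj = self
                *path, leaf = name.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                getattr(obj, leaf)[...] = val


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _init_conv(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, std, size=shape)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_init_conv(rng, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 2,
                 padding: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_init_conv(rng, (c_in, c_out, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias,
                                  self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    With batch size 1 this behaves like instance normalization during
    training; inference uses frozen running statistics.  ``affine=False``
    contributes no trainable parameters.
    """

    def __init__(self, c: int, affine: bool = True, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(c))
            self.beta = Parameter(np.zeros(c))
        from ischemap.nn.autograd import get_default_dtype

        self.running_mean = np.zeros(c, dtype=get_default_dtype())
        self.running_var = np.ones(c, dtype=get_default_dtype())

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
            xh = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xh = (x - Tensor(mu)) * Tensor(1.0 / sd)
        if self.affine:
            xh = xh * self.gamma.reshape(1, -1, 1, 1) \
                + self.beta.reshape(1, -1, 1, 1)
        return xh


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p
        self.rng: np.random.Generator = np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return F.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Tanh(Module):
    def forward(self, x):
        return F.tanh(x)


class UpsampleNearest(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        return F.upsample_nearest(x, self.factor)
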