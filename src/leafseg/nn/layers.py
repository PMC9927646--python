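"""Neural-network layer primitives built on the autodiff tensor."""

from __future__ import annotations

import math

import numpy as np

from .tensor import (
    Tensor,
    bilinear_resize,
    conv2d,
    depthwise_conv2d,
)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter traversal, train/eval, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal --------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item
            elif isinstance(value, dict):
                for key, item in value.items():
                    if isinstance(item, Module):
                        yield f"{name}.{key}", item

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and not name.startswith("_"):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # -- mode -------------------------------------------------------------
    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def requires_grad_(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    # -- state ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own_params = dict(self.named_parameters())
        own_bufs = dict(self.named_buffers())
        missing = (set(own_params) | set(own_bufs)) - set(state)
        unexpected = set(state) - (set(own_params) | set(own_bufs))
        if strict and (missing or unexpected):
            raise KeyError(
                f"state mismatch: missing={sorted(missing)} unexpected={sorted(unexpected)}"
            )
        for name, p in own_params.items():
            if name in state:
                if p.data.shape != state[name].shape:
                    raise ValueError(
                        f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                    )
                p.data = state[name].astype(np.float64).copy()
        for name in own_bufs:
            if name in state:
                self._set_buffer(name, state[name])

    def _set_buffer(self, dotted: str, value: np.ndarray):
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            if isinstance(obj, (list, tuple)):
                obj = obj[int(part)]
            elif isinstance(obj, dict):
                obj = obj[part]
            else:
                obj = getattr(obj, part)
        setattr(obj, parts[-1], value.astype(np.float64).copy())

    def param_count(self) -> int:
        return sum(p.size for p in self.parameters())


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, k, stride=1, padding=0, dilation=1,
                 bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, ch, k, stride=1, padding=0, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_he_init(rng, (ch, k, k), k * k))
        self.bias = Parameter(np.zeros(ch)) if bias else None

    def forward(self, x):
        return depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class SeparableConv2d(Module):
    """Depthwise 3x3 followed by pointwise 1x1 (Xception-style)."""

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depthwise = DepthwiseConv2d(in_ch, 3, stride=stride, padding=1,
                                         bias=False, rng=rng)
        self.pointwise = Conv2d(in_ch, out_ch, 1, bias=True, rng=rng)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, ch, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean[None, :, None, None])
            var = Tensor(self.running_var[None, :, None, None])
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalise over the channel axis of an NCHW tensor, per position."""

    def __init__(self, ch, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Identity(Module):
    def forward(self, x):
        return x


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Upsample(Module):
    """Bilinear upsampling by an integer factor."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        return bilinear_resize(x, (h * self.factor, w * self.factor))
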