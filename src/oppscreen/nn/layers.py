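"""Layer/module abstractions on top of the functional ops."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "Linear",
           "ReLU", "Sequential"]


class Module:
    """Base class: parameter registry, train/eval mode, recursion."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # state (de)serialisation -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self._params.items():
            out[name] = p.data
        for mname, m in self._modules.items():
            for k, v in m.state_arrays().items():
                out[f"{mname}.{k}"] = v
        if isinstance(self, BatchNorm2d):
            out["running_mean"] = self.running_mean
            out["running_var"] = self.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, p in self._params.items():
            p.data = np.asarray(state[prefix + name], dtype=np.float32).copy()
        if isinstance(self, BatchNorm2d):
            self.running_mean = np.asarray(state[prefix + "running_mean"],
                                           dtype=np.float32).copy()
            self.running_var = np.asarray(state[prefix + "running_var"],
                                          dtype=np.float32).copy()
        for mname, m in self._modules.items():
            m.load_state_arrays(state, prefix=f"{prefix}{mname}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    sd = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, sd, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        self.register_parameter(
            "weight", _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Upsampling transposed convolution, kernel == stride."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 2,
                 bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        fan_in = in_ch  # each output pixel sees one input pixel per channel
        self.register_parameter(
            "weight", _he_init(rng, (in_ch, out_ch, stride, stride), fan_in))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.register_parameter("gamma", np.ones(num_ch, dtype=np.float32))
        self.register_parameter("beta", np.zeros(num_ch, dtype=np.float32))
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = F.batch_norm2d(x, self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
            return out
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma.data * ivar).astype(np.float32)
        shift = (self.beta.data - self.running_mean * scale).astype(np.float32)
        data = x.data * scale[None, :, None, None] + shift[None, :, None, None]

        def backward(g):
            if x.requires_grad:
                x.accumulate_grad(g * scale[None, :, None, None])

        return Tensor.make(data, (x,), backward)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        super().__init__()
        self.register_parameter("weight", _he_init(rng, (in_f, out_f), in_f))
        self.register_parameter("bias", np.zeros(out_f, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x
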