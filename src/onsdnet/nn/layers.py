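"""Neural-network layers built on the :mod:`onsdnet.nn.tensor` engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, batchnorm2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "ConvBNReLU"]


def _children(val, name):
    """Yield (name, Tensor | Module) from attributes, descending arbitrarily
    nested lists/tuples (e.g. a backbone's list of stages of blocks)."""
    if isinstance(val, (Tensor, Module)):
        yield name, val
    elif isinstance(val, (list, tuple)):
        for i, v in enumerate(val):
            yield from _children(v, f"{name}.{i}")


class Module:
    """Base class: recursive parameter/buffer collection and train/eval mode."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for attr, val in vars(self).items():
            for name, child in _children(val, f"{prefix}{attr}"):
                if isinstance(child, Tensor):
                    if child.requires_grad:
                        out.append((name, child))
                else:
                    out.extend(child.named_parameters(name + "."))
        return out

    def named_buffers(self, prefix: str = ""):
        out = []
        for attr, val in vars(self).items():
            full = f"{prefix}{attr}"
            if isinstance(val, np.ndarray) and attr.startswith("running_"):
                out.append((full, val))
                continue
            for name, child in _children(val, full):
                if isinstance(child, Module):
                    out.extend(child.named_buffers(name + "."))
        return out

    def modules(self):
        yield self
        for attr, val in vars(self).items():
            for _, child in _children(val, attr):
                if isinstance(child, Module):
                    yield from child.modules()

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            if hasattr(m, "training"):
                m.training = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: t.data.copy() for name, t in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for name, t in self.named_parameters():
            t.data[...] = d[name]
        for name, b in self.named_buffers():
            b[...] = d[name]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm2d(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        # eval: affine transform with frozen statistics, fused to scale/shift
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        a = (self.gamma.data * ivar).reshape(1, -1, 1, 1)
        b = (self.beta.data - self.gamma.data * ivar * self.running_mean
             ).reshape(1, -1, 1, 1)
        return x * Tensor(a) + Tensor(b)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None,
                 bias_init: float = 0.0):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, std, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.full(out_f, bias_init, dtype=float), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvBNReLU(Module):
    """conv(kernel) -> batchnorm -> ReLU, the workhorse block of the backbone."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()
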