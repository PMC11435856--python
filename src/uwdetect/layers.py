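"""Trainable layer abstractions built on the autodiff core.

``Module`` provides parameter registration and train/eval switching.
``Conv2d`` additionally records the multiply-accumulate count of its most
recent forward pass, which is what the architecture auditor sums to report
FLOPs (2 x MACs, convolutions only -- normalization, activations, pooling
and resampling are treated as zero-cost, the usual profiler convention for
comparing detector complexity).
"""
from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor
from . import ops


class Module:
    def __init__(self):
        self.training = True

    def parameters(self):
        seen = set()
        for p in self._walk_params():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def _walk_params(self):
        def walk(v):
            if isinstance(v, Parameter):
                yield v
            elif isinstance(v, Module):
                yield from v._walk_params()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    yield from walk(item)
        for v in self.__dict__.values():
            yield from walk(v)

    def modules(self):
        def walk(v):
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    yield from walk(item)
        yield self
        for v in self.__dict__.values():
            yield from walk(v)

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Grouped 2-D convolution with He-uniform initialisation."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 dilation: int = 1, groups: int = 1, bias: bool = True,
                 padding: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_in % groups or c_out % groups:
            raise ValueError(f"groups={groups} must divide c_in={c_in} and c_out={c_out}")
        if k % 2 == 0:
            raise ValueError("even kernel sizes are not supported (same-padding)")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.dilation, self.groups = stride, dilation, groups
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = (c_in // groups) * k * k
        bound = float(np.sqrt(1.0 / fan_in))
        self.weight = Parameter(rng.uniform(-bound, bound, (c_out, c_in // groups, k, k)))
        self.bias = Parameter(rng.uniform(-bound, bound, c_out)) if bias else None
        self.last_macs = 0

    def forward(self, x: Tensor) -> Tensor:
        y = ops.conv2d(x, self.weight, self.bias, stride=self.stride,
                       dilation=self.dilation, groups=self.groups,
                       padding=self.padding)
        n_out = y.shape[2] * y.shape[3]
        self.last_macs = self.c_out * (self.c_in // self.groups) * self.k * self.k * n_out
        return y


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.data.shape
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        y = self.gamma.data.reshape(1, c, 1, 1) * xhat + self.beta.data.reshape(1, c, 1, 1)
        out = Tensor(y)
        parents = (x, self.gamma, self.beta)
        from .autograd import _grad_enabled
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            training = self.training

            def backward(g):
                if self.beta.requires_grad:
                    self.beta._accum(g.sum(axis=(0, 2, 3)))
                if self.gamma.requires_grad:
                    self.gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    gz = g * self.gamma.data.reshape(1, c, 1, 1)
                    if training:
                        n = b * h * w
                        s1 = gz.sum(axis=(0, 2, 3), keepdims=True)
                        s2 = (gz * xhat).sum(axis=(0, 2, 3), keepdims=True)
                        gx = (gz - s1 / n - xhat * s2 / n) * inv.reshape(1, c, 1, 1)
                    else:
                        gx = gz * inv.reshape(1, c, 1, 1)
                    x._accum(gx)
            out._backward = backward
        return out


class Identity(Module):
    def forward(self, x):
        return x


class SGD:
    """Stochastic gradient descent with classical momentum and decoupled
    weight decay applied only to convolution weights (not norm affines or
    biases), following the usual detector-training recipe."""

    def __init__(self, params_decay, params_nodecay, lr: float = 1e-3,
                 momentum: float = 0.937, weight_decay: float = 5e-4):
        self.groups = [(list(params_decay), weight_decay),
                       (list(params_nodecay), 0.0)]
        self.lr, self.momentum = lr, momentum
        self.v = {}

    def step(self):
        for params, wd in self.groups:
            for p in params:
                if p.grad is None:
                    continue
                g = p.grad + wd * p.data
                buf = self.v.get(id(p))
                if buf is None:
                    buf = np.zeros_like(p.data)
                    self.v[id(p)] = buf
                buf *= self.momentum
                buf += g
                p.data -= self.lr * buf

    def zero_grad(self):
        for params, _ in self.groups:
            for p in params:
                p.grad = None
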