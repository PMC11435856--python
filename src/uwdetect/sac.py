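"""Switchable atrous convolution and the C2f block built from it.

A SAConv observes its input twice, through a rate-1 and a rate-r dilated
3x3 convolution that share a base kernel ``w``; the dilated branch adds a
trainable increment ``dw``.  A learned spatial switch

    S(x) = sigmoid(conv1x1(avgpool_5x5(x)))

mixes the two branches convexly:

    y = S * conv(x, w, rate 1) + (1 - S) * conv(x, w + dw, rate r)

so every output lies between the two branch responses.  ``dw`` starts at
zero, making the initial state a pure shared-kernel convolution.
"""
from __future__ import annotations

import numpy as np

from . import ops
from .autograd import Parameter
from .blocks import CBS, C2f
from .layers import BatchNorm2d, Conv2d, Module


class SAConv(Module):
    """Dual-rate switchable 3x3 convolution (no norm/activation)."""

    def __init__(self, c_in, c_out, k=3, rate=3, rng=None):
        super().__init__()
        self.c_in, self.c_out, self.k, self.rate = c_in, c_out, k, rate
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        bound = float(np.sqrt(1.0 / fan_in))
        self.w = Parameter(rng.uniform(-bound, bound, (c_out, c_in, k, k)))
        self.dw = Parameter(np.zeros((c_out, c_in, k, k), dtype=np.float32))
        self.switch_conv = Conv2d(c_in, 1, 1, bias=True, rng=rng)
        self.last_macs = 0

    def switch(self, x):
        """S(x): one mixing weight per spatial position, in (0, 1)."""
        return self.switch_conv(ops.avg_pool2d(x, 5)).sigmoid()

    def forward(self, x):
        s = self.switch(x)
        b1 = ops.conv2d(x, self.w, dilation=1)
        b2 = ops.conv2d(x, self.w + self.dw, dilation=self.rate)
        n_out = b1.shape[2] * b1.shape[3]
        self.last_macs = 2 * self.c_out * self.c_in * self.k * self.k * n_out
        return s * b1 + (1.0 - s) * b2


class SACBottleneck(Module):
    """Bottleneck with the first conv replaced by a SAConv.

    SAConv -> BN/SiLU -> 3x3 CBS -> 1x1 conv (+BN) restoring the channel
    count, plus the usual shortcut when shapes allow it.
    """

    def __init__(self, c, shortcut=True, hidden_ratio=(1, 1), rng=None):
        super().__init__()
        num, den = hidden_ratio
        h = max(1, (c * num) // den)
        self.sac = SAConv(c, h, rng=rng)
        self.bn = BatchNorm2d(h)
        self.cbs = CBS(h, h, 3, rng=rng)
        self.restore = Conv2d(h, c, 1, bias=False, rng=rng)
        self.restore_bn = BatchNorm2d(c)
        self.add = shortcut

    def forward(self, x):
        y = self.bn(self.sac(x)).silu()
        y = self.cbs(y)
        y = self.restore_bn(self.restore(y))
        return x + y if self.add else y


def c2f_saconv(c_in, c_out, n=1, shortcut=False, hidden_ratio=(1, 1), rng=None):
    """A C2f whose bottlenecks are SACBottlenecks (identical topology)."""
    return C2f(c_in, c_out, n, shortcut, rng=rng,
               bottleneck_factory=lambda c, sc, r: SACBottleneck(
                   c, sc, hidden_ratio=hidden_ratio, rng=r))
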