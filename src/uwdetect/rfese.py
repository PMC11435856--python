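"""Receptive-field attention convolution with ESE channel attention.

The module replaces a standard k x k convolution by a pipeline that
weights both channels and receptive-field positions before aggregating:

1. global context injection  x <- x + broadcast(conv1x1(GAP(x)))
2. ESE channel attention     x <- x * sigmoid(conv1x1(GAP(x)))
3. receptive-field features  F_rf = ReLU(BN(grouped k x k conv)), one
   k^2-vector per channel per output position
4. receptive-field attention A_rf = softmax over the k^2 positions of
   conv1x1(pooled x), where pooling averages a k x k avg-pool and a
   k x k max-pool (long-range context on both smooth and peak statistics)
5. the weighted features A_rf * F_rf are rearranged into a (kH' x kW')
   map and fused by a k x k stride-k convolution to c_out channels.

The aggregation conv's group count is a placement-level design knob: the
audited variants use grouped aggregation at the FLOP-dominant placements
and dense aggregation at the deepest ones.  An optional grouped 3x3
"interaction" conv on the attention branch widens channel mixing of the
attention logits at a configured placement.
"""
from __future__ import annotations

import numpy as np

from . import ops
from .blocks import CBS
from .layers import BatchNorm2d, Conv2d, Module


class RFESEConv(Module):
    def __init__(self, c_in, c_out, k=3, stride=1, agg_groups=1,
                 interaction_groups=0, rng=None):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("receptive-field kernel must be odd")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        kk = k * k
        self.gc_conv = Conv2d(c_in, c_in, 1, bias=True, rng=rng)
        self.ese_conv = Conv2d(c_in, c_in, 1, bias=True, rng=rng)
        self.extract = Conv2d(c_in, kk * c_in, k, stride=stride, groups=c_in,
                              bias=False, rng=rng)
        self.extract_bn = BatchNorm2d(kk * c_in)
        self.attn_conv = Conv2d(c_in, kk * c_in, 1, groups=c_in, bias=True, rng=rng)
        if interaction_groups:
            self.interaction = Conv2d(kk * c_in, kk * c_in, 3,
                                      groups=interaction_groups, bias=False, rng=rng)
            self.interaction_bn = BatchNorm2d(kk * c_in)
        else:
            self.interaction = None
        self.agg = Conv2d(c_in, c_out, k, stride=k, groups=agg_groups,
                          bias=False, padding=0, rng=rng)
        self.agg_bn = BatchNorm2d(c_out)

    # exposed sub-operations (each is individually testable) --------------
    def global_context_inject(self, x):
        return x + self.gc_conv(ops.global_avg_pool(x))

    def ese_attention(self, x):
        """One (0,1) weight per channel: sigmoid of a linear map of GAP."""
        return self.ese_conv(ops.global_avg_pool(x)).sigmoid()

    def rf_features(self, x):
        """Non-negative receptive-field features, (B, C, k^2, H', W')."""
        f = self.extract_bn(self.extract(x)).relu()
        b, _, h, w = f.shape
        return f.reshape(b, self.c_in, self.k * self.k, h, w)

    def rf_attention(self, x):
        """Softmax attention over each receptive field, sums to 1 per group."""
        p = (ops.avg_pool2d(x, self.k, self.stride)
             + ops.max_pool2d(x, self.k, self.stride)) * 0.5
        a = self.attn_conv(p)
        if self.interaction is not None:
            a = self.interaction_bn(self.interaction(a))
        b, _, h, w = a.shape
        a = a.reshape(b, self.c_in, self.k * self.k, h, w)
        return a.softmax(axis=2)

    def forward(self, x):
        x = self.global_context_inject(x)
        x = x * self.ese_attention(x)
        f = self.rf_features(x)
        a = self.rf_attention(x)
        y = f * a
        b, c, _, h, w = y.shape
        k = self.k
        # place the k^2 weighted positions on a (kH', kW') grid
        y = y.reshape(b, c, k, k, h, w).transpose(0, 1, 4, 2, 5, 3)
        y = y.reshape(b, c, k * h, k * w)
        return self.agg_bn(self.agg(y)).silu()
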