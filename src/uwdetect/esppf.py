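"""ESPPF: a widened, shallower pooling pyramid replacing SPPF.

Instead of SPPF's three cascaded 5x5 max pools, the 1x1-reduced feature
map is split channel-wise into two halves pooled in parallel: one half
through two 5x5 pools (effectively 5 then 9 receptive field), the other
through a 13x13 then a 9x9 pool (receptive field 13 then 21).  The cv1
output plus all four pooled maps (3 * hidden channels in total, versus
SPPF's 4 * hidden) are fused by a 1x1 CBS.  The narrower concatenation is
where the block's parameter saving comes from; pooling itself is free.
"""
from __future__ import annotations

from . import ops
from .autograd import cat
from .blocks import CBS
from .layers import Module


class ESPPF(Module):
    def __init__(self, c_in, c_out, hidden=32, rng=None):
        super().__init__()
        if hidden % 2:
            raise ValueError("ESPPF hidden width must be even (channel split)")
        self.hidden = hidden
        self.cv1 = CBS(c_in, hidden, 1, rng=rng)
        self.cv2 = CBS(3 * hidden, c_out, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        h = self.hidden // 2
        ya, yb = y[:, :h], y[:, h:]
        a1 = ops.max_pool2d(ya, 5)
        a2 = ops.max_pool2d(a1, 5)
        b1 = ops.max_pool2d(yb, 13)
        b2 = ops.max_pool2d(b1, 9)
        return self.cv2(cat([y, a1, a2, b1, b2], axis=1))


def esppf_param_count(c_in: int, c_out: int, hidden: int = 32) -> int:
    """Exact trainable-parameter total of an ESPPF block (pools are free)."""
    cv1 = c_in * hidden + 2 * hidden
    cv2 = 3 * hidden * c_out + 2 * c_out
    return cv1 + cv2
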