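"""Detector assembly (variant flags -> model) and the architecture audit.

The network is an n-scale (depth 1/3, width 1/4) single-stage detector:
a five-stage backbone (stride 32), a PAN-style neck and a decoupled
anchor-free head at strides 8/16/32.  Three substitutions define the
ablation ladder:

* ``use_sac``   -- C2f blocks at backbone P2/P3/P4 and in the neck become
  C2f_SAConv (switchable atrous bottlenecks; backbone hidden 33c/32, neck
  hidden 13c/16).
* ``use_rfese`` -- the stride-2 downsampling convs (backbone and neck) and
  the head's 3x3 branch convs become RFESEConv, with per-placement
  aggregation group counts.
* ``use_esppf`` -- the SPPF pyramid becomes ESPPF (hidden 32).

All hidden widths and placement group counts were fixed once by auditing
parameter totals and conv FLOPs against the reference complexity figures
for the four variants; see docs/methods.md.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ops
from .autograd import Tensor, cat, no_grad
from .blocks import CBS, C2f, Detect, SPPF
from .esppf import ESPPF
from .layers import Module
from .rfese import RFESEConv
from .sac import c2f_saconv

NC_DEFAULT = 4

SAC_BACKBONE_RATIO = (33, 32)
SAC_NECK_RATIO = (13, 16)
SAC_SITES = ("b2", "b3", "b4", "n12", "n15", "n18", "n21")

BOX_HIDDEN = 40
CLS_HIDDEN = (88, 72, 88)

RFESE_AGG_GROUPS = {
    "d2": 2, "d3": 4, "d4": 4, "d5": 1, "nd1": 4, "nd2": 4,
    "h0b1": 8, "h0b2": 2, "h0c1": 8, "h0c2": 2,
    "h1b1": 8, "h1b2": 8, "h1c1": 8, "h1c2": 8,
    "h2b1": 8, "h2b2": 8, "h2c1": 8, "h2c2": 8,
}
RFESE_INTERACTION = {"h2c2": 9}

VARIANTS = {
    "baseline": (False, False, False),
    "sac": (True, False, False),
    "sac+rfese": (True, True, False),
    "full": (True, True, True),
}


@dataclass
class ModelVariant:
    use_sac: bool = False
    use_rfese: bool = False
    use_esppf: bool = False
    nc: int = NC_DEFAULT
    scale: str = "n"

    @classmethod
    def named(cls, name: str, nc: int = NC_DEFAULT) -> "ModelVariant":
        if name not in VARIANTS:
            raise KeyError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
        sac, rfese, esppf = VARIANTS[name]
        return cls(sac, rfese, esppf, nc=nc)


class DetectionModel(Module):
    def __init__(self, variant: ModelVariant | None = None, seed: int = 0):
        super().__init__()
        v = variant or ModelVariant()
        if v.scale != "n":
            raise ValueError("only the n scale is implemented")
        self.variant = v
        rng = np.random.default_rng(seed)

        def down(name, c1, c2):
            if v.use_rfese:
                return RFESEConv(c1, c2, 3, stride=2,
                                 agg_groups=RFESE_AGG_GROUPS[name],
                                 interaction_groups=RFESE_INTERACTION.get(name, 0),
                                 rng=rng)
            return CBS(c1, c2, 3, stride=2, rng=rng)

        def c2f(name, c1, c2, n, shortcut):
            if v.use_sac and name in SAC_SITES:
                ratio = SAC_BACKBONE_RATIO if name.startswith("b") else SAC_NECK_RATIO
                return c2f_saconv(c1, c2, n, shortcut, hidden_ratio=ratio, rng=rng)
            return C2f(c1, c2, n, shortcut, rng=rng)

        def head_conv(name, c1, c2, k, stride, r):
            if v.use_rfese:
                return RFESEConv(c1, c2, k, stride=stride,
                                 agg_groups=RFESE_AGG_GROUPS[name],
                                 interaction_groups=RFESE_INTERACTION.get(name, 0),
                                 rng=r)
            return CBS(c1, c2, k, stride, rng=r)

        self.stem = CBS(3, 16, 3, stride=2, rng=rng)
        self.d2, self.b2 = down("d2", 16, 32), c2f("b2", 32, 32, 1, True)
        self.d3, self.b3 = down("d3", 32, 64), c2f("b3", 64, 64, 2, True)
        self.d4, self.b4 = down("d4", 64, 128), c2f("b4", 128, 128, 2, True)
        self.d5, self.b5 = down("d5", 128, 256), C2f(256, 256, 1, True, rng=rng)
        self.pyramid = (ESPPF(256, 256, rng=rng) if v.use_esppf
                        else SPPF(256, 256, rng=rng))
        self.n12 = c2f("n12", 384, 128, 1, False)
        self.n15 = c2f("n15", 192, 64, 1, False)
        self.nd1 = down("nd1", 64, 64)
        self.n18 = c2f("n18", 192, 128, 1, False)
        self.nd2 = down("nd2", 128, 128)
        self.n21 = c2f("n21", 384, 256, 1, False)
        self.head = Detect(nc=v.nc, ch=(64, 128, 256), box_hidden=BOX_HIDDEN,
                           cls_hidden=CLS_HIDDEN, rng=rng, conv_factory=head_conv)
        self.nc, self.reg_max = v.nc, self.head.reg_max

    def forward(self, x: Tensor):
        x = self.stem(x)
        x = self.b2(self.d2(x))
        p3 = self.b3(self.d3(x))
        p4 = self.b4(self.d4(p3))
        p5 = self.pyramid(self.b5(self.d5(p4)))
        u4 = self.n12(cat([ops.upsample_nearest2(p5), p4], axis=1))
        u3 = self.n15(cat([ops.upsample_nearest2(u4), p3], axis=1))
        d4_ = self.n18(cat([self.nd1(u3), u4], axis=1))
        d5_ = self.n21(cat([self.nd2(d4_), p5], axis=1))
        return self.head([u3, d4_, d5_])


def build_model(variant, nc: int = NC_DEFAULT, seed: int = 0) -> DetectionModel:
    """Build a variant by name ('baseline', 'sac', 'sac+rfese', 'full') or
    from a ModelVariant instance."""
    if isinstance(variant, str):
        variant = ModelVariant.named(variant, nc=nc)
    return DetectionModel(variant, seed=seed)


def count_params(model: Module) -> int:
    """Exact trainable-parameter count (sum over all parameter arrays)."""
    return sum(p.data.size for p in model.parameters())


def count_flops(model: Module, imgsz: int = 640) -> float:
    """Forward-pass FLOPs at ``imgsz`` x ``imgsz``, counted as 2 x conv MACs."""
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, imgsz, imgsz), dtype=np.float32))
    with no_grad():
        model(x)
    macs = sum(getattr(m, "last_macs", 0) for m in model.modules())
    model.train(was_training)
    return 2.0 * macs


@dataclass
class AuditReport:
    variant: str
    params: int
    flops: float

    @property
    def params_m(self) -> float:
        return round(self.params / 1e6, 2)

    @property
    def gflops(self) -> float:
        return round(self.flops / 1e9, 2)

    def __str__(self):
        return (f"{self.variant}: {self.params:,} params ({self.params_m:.2f} M), "
                f"{self.flops / 1e9:.4f} GFLOPs ({self.gflops:.2f} G)")


def audit(variant: str, nc: int = NC_DEFAULT, imgsz: int = 640,
          seed: int = 0) -> AuditReport:
    """Build a variant and measure its parameter/FLOP totals."""
    m = build_model(variant, nc=nc, seed=seed)
    return AuditReport(variant, count_params(m), count_flops(m, imgsz))
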