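"""Baseline single-stage detector building blocks.

The vocabulary follows the YOLOv8 family: CBS (conv + batch norm + SiLU),
Bottleneck, the cross-stage C2f block, the SPPF pooling pyramid and an
anchor-free decoupled head whose box branch regresses a discrete
distribution over ``reg_max`` bins per box side (decoded by expectation).
"""
from __future__ import annotations

import numpy as np

from . import ops
from .autograd import Tensor, cat, no_grad
from .layers import BatchNorm2d, Conv2d, Module


class CBS(Module):
    """Conv2d (no bias) + BatchNorm + SiLU, the basic composite unit."""

    def __init__(self, c_in, c_out, k=1, stride=1, dilation=1, groups=1, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride, dilation, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class Bottleneck(Module):
    """Two 3x3 CBS with an optional identity shortcut."""

    def __init__(self, c_in, c_out, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = CBS(c_in, c_out, 3, rng=rng)
        self.cv2 = CBS(c_out, c_out, 3, rng=rng)
        self.add = shortcut and c_in == c_out

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage block: split, stack bottlenecks, concatenate every
    intermediate branch, fuse with a 1x1 CBS."""

    def __init__(self, c_in, c_out, n=1, shortcut=False, rng=None,
                 bottleneck_factory=None):
        super().__init__()
        if n < 1:
            raise ValueError("C2f needs at least one bottleneck")
        self.c = c_out // 2
        self.cv1 = CBS(c_in, 2 * self.c, 1, rng=rng)
        self.cv2 = CBS((2 + n) * self.c, c_out, 1, rng=rng)
        factory = bottleneck_factory or (lambda c, sc, r: Bottleneck(c, c, sc, rng=r))
        self.m = [factory(self.c, shortcut, rng) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        outs = [a, b]
        for m in self.m:
            outs.append(m(outs[-1]))
        return self.cv2(cat(outs, axis=1))


class SPPF(Module):
    """Pooling pyramid: three cascaded 5x5 stride-1 max pools."""

    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        h = c_in // 2
        self.cv1 = CBS(c_in, h, 1, rng=rng)
        self.cv2 = CBS(4 * h, c_out, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        p1 = ops.max_pool2d(y, 5)
        p2 = ops.max_pool2d(p1, 5)
        p3 = ops.max_pool2d(p2, 5)
        return self.cv2(cat([y, p1, p2, p3], axis=1))


class Detect(Module):
    """Anchor-free decoupled head over three scales (strides 8/16/32).

    Each position emits ``nc`` class logits and ``4*reg_max`` distribution
    logits.  Branch convs are created through ``conv_factory`` so model
    assembly can substitute attention convolutions at audited placements.
    """

    STRIDES = (8, 16, 32)

    def __init__(self, nc=4, ch=(64, 128, 256), box_hidden=40,
                 cls_hidden=(88, 72, 88), reg_max=16, rng=None,
                 conv_factory=None):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        fac = conv_factory or (lambda name, ci, co, k, s, r: CBS(ci, co, k, s, rng=r))
        self.box_branches, self.cls_branches = [], []
        for i, c in enumerate(ch):
            b = box_hidden
            self.box_branches.append([
                fac(f"h{i}b1", c, b, 3, 1, rng),
                fac(f"h{i}b2", b, b, 3, 1, rng),
                Conv2d(b, 4 * reg_max, 1, bias=True, rng=rng),
            ])
            cci = cls_hidden[i]
            self.cls_branches.append([
                fac(f"h{i}c1", c, cci, 3, 1, rng),
                fac(f"h{i}c2", cci, cci, 3, 1, rng),
                Conv2d(cci, nc, 1, bias=True, rng=rng),
            ])
        # detection-prior bias init: boxes start near small extents, class
        # logits near the expected object rate per cell
        for i, s in enumerate(self.STRIDES):
            self.box_branches[i][-1].bias.data[:] = 1.0
            self.cls_branches[i][-1].bias.data[:] = float(
                np.log(5.0 / nc / (640.0 / s) ** 2))
        # fixed projection for decoding the box distribution; not trainable
        self.dfl_proj = np.arange(reg_max, dtype=np.float32)

    def forward(self, feats):
        outs = []
        for i, x in enumerate(feats):
            b = x
            for m in self.box_branches[i]:
                b = m(b)
            c = x
            for m in self.cls_branches[i]:
                c = m(c)
            outs.append(cat([b, c], axis=1))
        return outs


def head_grid(h, w, stride):
    """Anchor-point centres (in pixels) for one head scale."""
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return (np.stack([xs, ys], axis=-1).reshape(-1, 2) + 0.5) * stride


def decode_boxes(head_outs, nc, reg_max=16, img_size=640, conf_thres=0.0):
    """Decode raw head maps to (boxes xyxy, class ids, confidences).

    Box side distances are the expectation of the softmaxed ``reg_max``-bin
    distribution, scaled by the stride; confidences are sigmoid class
    scores.  Boxes are clipped to the image bounds.
    """
    proj = np.arange(reg_max, dtype=np.float32)
    boxes, classes, confs = [], [], []
    with no_grad():
        for out, stride in zip(head_outs, Detect.STRIDES):
            a = out.data if isinstance(out, Tensor) else out
            bsz, ch, h, w = a.shape
            assert bsz == 1, "decode operates on single images"
            a = a.reshape(ch, h * w).T
            dist = a[:, : 4 * reg_max].reshape(-1, 4, reg_max)
            dist = dist - dist.max(axis=-1, keepdims=True)
            e = np.exp(dist)
            d = (e / e.sum(axis=-1, keepdims=True)) @ proj  # (n,4) l,t,r,b in stride units
            centers = head_grid(h, w, stride)
            xy1 = centers - d[:, :2] * stride
            xy2 = centers + d[:, 2:] * stride
            cls_logit = a[:, 4 * reg_max:]
            cid = cls_logit.argmax(axis=1)
            conf = 1.0 / (1.0 + np.exp(-cls_logit[np.arange(len(cid)), cid]))
            keep = conf >= conf_thres
            bx = np.clip(np.concatenate([xy1, xy2], axis=1), 0, img_size)
            boxes.append(bx[keep])
            classes.append(cid[keep])
            confs.append(conf[keep])
    return (np.concatenate(boxes), np.concatenate(classes), np.concatenate(confs))


def nms(boxes, classes, confs, iou_thres=0.45, max_det=300):
    """Greedy per-class non-maximum suppression."""
    order = np.argsort(-confs)
    keep = []
    while order.size and len(keep) < max_det:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        xx1 = np.maximum(boxes[i, 0], boxes[rest, 0])
        yy1 = np.maximum(boxes[i, 1], boxes[rest, 1])
        xx2 = np.minimum(boxes[i, 2], boxes[rest, 2])
        yy2 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.clip(xx2 - xx1, 0, None) * np.clip(yy2 - yy1, 0, None)
        area_i = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        area_r = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        iou = inter / np.maximum(area_i + area_r - inter, 1e-9)
        same = classes[rest] == classes[i]
        order = rest[~((iou > iou_thres) & same)]
    keep = np.array(keep, dtype=int)
    return boxes[keep], classes[keep], confs[keep]
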