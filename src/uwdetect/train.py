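"""Training and evaluation harness.

Assignment follows the task-aligned strategy: anchor points whose centre
falls inside a ground-truth box are candidates; each ground truth keeps
its top-10 candidates ranked by the alignment score

    align = classification^0.5 * IoU^6

and an anchor claimed by several ground truths goes to the best-aligned
one.  The loss decomposes into the usual three detector components: CIoU
for boxes, binary cross-entropy for classification and the distribution
focal loss over the ``reg_max`` regression bins; component weights follow
the common single-stage defaults (7.5 / 0.5 / 1.5).

Optimisation defaults: SGD with learning rate 1e-3, momentum 0.937 and
weight decay 5e-4, batch size 4.
"""
from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, cat, no_grad
from .blocks import Detect, decode_boxes, head_grid, nms
from .data import DatasetManifest, load_sample
from .layers import SGD
from .metrics import iou_matrix, map_metrics
from .model import DetectionModel

ALIGN_ALPHA, ALIGN_BETA, ALIGN_TOPK = 0.5, 6.0, 10
LOSS_W_BOX, LOSS_W_CLS, LOSS_W_DFL = 7.5, 0.5, 1.5


def _flatten_head(outs, nc, reg_max):
    """Concatenate per-scale maps into (B, A, 4*reg_max) and (B, A, nc)."""
    dists, clss, centers, strides = [], [], [], []
    for out, stride in zip(outs, Detect.STRIDES):
        b, ch, h, w = out.shape
        flat = out.reshape(b, ch, h * w).transpose(0, 2, 1)
        dists.append(flat[:, :, : 4 * reg_max])
        clss.append(flat[:, :, 4 * reg_max:])
        centers.append(head_grid(h, w, stride))
        strides.append(np.full(h * w, stride, dtype=np.float32))
    return (cat(dists, axis=1), cat(clss, axis=1),
            np.concatenate(centers), np.concatenate(strides))


def _assign(pred_boxes, pred_scores, centers, gt_boxes, gt_cls):
    """Task-aligned assignment for one image (pure numpy, no gradients).

    Returns (anchor_idx, gt_idx, target_scores) where target_scores is the
    normalised alignment metric used to weight box loss and as the
    classification target.
    """
    m = len(gt_boxes)
    if m == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, np.float32))
    inside = ((centers[:, 0][:, None] > gt_boxes[None, :, 0])
              & (centers[:, 0][:, None] < gt_boxes[None, :, 2])
              & (centers[:, 1][:, None] > gt_boxes[None, :, 1])
              & (centers[:, 1][:, None] < gt_boxes[None, :, 3]))  # (A, M)
    ious = iou_matrix(pred_boxes, gt_boxes)                        # (A, M)
    cls_p = pred_scores[:, gt_cls]                                 # (A, M)
    align = (cls_p ** ALIGN_ALPHA) * (ious ** ALIGN_BETA)
    align = np.where(inside, align, 0.0)
    # top-k per gt
    keep = np.zeros_like(align, dtype=bool)
    k = min(ALIGN_TOPK, align.shape[0])
    top = np.argpartition(-align, k - 1, axis=0)[:k]
    keep[top, np.arange(m)] = True
    keep &= align > 0
    # an anchor serves at most one gt: the best-aligned
    align = np.where(keep, align, 0.0)
    best_gt = align.argmax(axis=1)
    anchor_mask = align[np.arange(len(best_gt)), best_gt] > 0
    a_idx = np.nonzero(anchor_mask)[0]
    g_idx = best_gt[a_idx]
    t = align[a_idx, g_idx]
    # normalise: per gt, scale so the best anchor's target equals its IoU
    t_norm = np.zeros_like(t)
    for j in np.unique(g_idx):
        sel = g_idx == j
        amax = t[sel].max()
        imax = ious[a_idx[sel], j].max()
        t_norm[sel] = t[sel] / (amax + 1e-9) * imax
    return a_idx, g_idx, t_norm.astype(np.float32)


def _bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    p = logits.sigmoid().clip(1e-7, 1.0 - 1e-7)
    t = targets
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log())


def _ciou_loss(pb: Tensor, gt: np.ndarray) -> Tensor:
    """1 - CIoU between predicted boxes (tensor, (n,4) xyxy) and targets."""
    eps = 1e-7
    gx1, gy1, gx2, gy2 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    px1, px2 = pb[:, 0], pb[:, 2]
    py1, py2 = pb[:, 1], pb[:, 3]
    pw, ph = (px2 - px1).clip(eps, 1e9), (py2 - py1).clip(eps, 1e9)
    gw, gh = gx2 - gx1, gy2 - gy1
    ix = px2.minimum(gx2) - px1.maximum(gx1)
    iy = py2.minimum(gy2) - py1.maximum(gy1)
    inter = ix.clip(0, 1e9) * iy.clip(0, 1e9)
    union = pw * ph + gw * gh - inter + eps
    i_o_u = inter / union
    # enclosing box diagonal and centre distance
    cw = px2.maximum(gx2) - px1.minimum(gx1)
    chh = py2.maximum(gy2) - py1.minimum(gy1)
    c2 = cw * cw + chh * chh + eps
    rho2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) * 0.25
    v = (4.0 / math.pi ** 2) * ((Tensor(np.arctan(gw / (gh + eps)))
                                 - (pw / ph).atan()) ** 2)
    with no_grad():
        alpha = v.data / (1.0 - i_o_u.data + v.data + eps)
    return 1.0 - i_o_u + rho2 / c2 + v * alpha


def detection_loss(outs, targets, nc: int, reg_max: int):
    """Composite loss for a batch.

    ``targets``: per image ``(gt_boxes_xyxy_px, gt_classes)``.  Returns
    (total, box_loss, cls_loss, dfl_loss) as Tensors.
    """
    pd, pc, centers, strides = _flatten_head(outs, nc, reg_max)
    bsz, na = pc.shape[0], pc.shape[1]
    proj = np.arange(reg_max, dtype=np.float32)
    dist = pd.reshape(bsz, na, 4, reg_max)
    dexp = dist.softmax(axis=-1) @ Tensor(proj.reshape(reg_max, 1))
    dexp = dexp.reshape(bsz, na, 4)  # l,t,r,b in stride units
    su = strides[None, :, None]
    cxy = centers[None, :, :]
    x1y1 = Tensor(cxy) - dexp[:, :, :2] * su
    x2y2 = Tensor(cxy) + dexp[:, :, 2:] * su
    cls_targets = np.zeros((bsz, na, nc), dtype=np.float32)
    sel_b, sel_a, sel_tgt_box, sel_w = [], [], [], []
    for b, (gtb, gtc) in enumerate(targets):
        gtb = np.asarray(gtb, dtype=np.float32).reshape(-1, 4)
        gtc = np.asarray(gtc, dtype=np.int64)
        with no_grad():
            pb = np.concatenate([x1y1.data[b], x2y2.data[b]], axis=1)
            ps = 1.0 / (1.0 + np.exp(-pc.data[b]))
        a_idx, g_idx, t = _assign(pb, ps, centers, gtb, gtc)
        cls_targets[b, a_idx, gtc[g_idx]] = t
        sel_b.append(np.full(len(a_idx), b))
        sel_a.append(a_idx)
        sel_tgt_box.append(gtb[g_idx])
        sel_w.append(t)
    sel_b = np.concatenate(sel_b).astype(int)
    sel_a = np.concatenate(sel_a).astype(int)
    sel_tgt_box = np.concatenate(sel_tgt_box).reshape(-1, 4)
    sel_w = np.concatenate(sel_w).astype(np.float32)
    score_sum = max(float(sel_w.sum()), 1.0)

    cls_loss = _bce(pc, cls_targets).sum() / score_sum

    if len(sel_a):
        pb_sel = cat([x1y1[sel_b, sel_a], x2y2[sel_b, sel_a]], axis=1)
        w = sel_w / score_sum
        box_loss = (_ciou_loss(pb_sel, sel_tgt_box) * w).sum()
        # distribution focal loss on the two bins bracketing the target
        st = strides[sel_a][:, None]
        cxys = centers[sel_a]
        tdist = np.concatenate([cxys - sel_tgt_box[:, :2],
                                sel_tgt_box[:, 2:] - cxys], axis=1) / st
        tdist = np.clip(tdist, 0, reg_max - 1 - 0.01)
        lo = np.floor(tdist).astype(int)
        hi = lo + 1
        wl, wr = (hi - tdist).astype(np.float32), (tdist - lo).astype(np.float32)
        logits = dist[sel_b, sel_a]  # (n, 4, reg_max)
        z = logits - logits.data.max(axis=-1, keepdims=True)
        lse = z.exp().sum(axis=-1, keepdims=True).log()
        logp = z - lse
        n_idx = np.arange(len(sel_a))[:, None].repeat(4, axis=1)
        s_idx = np.arange(4)[None, :].repeat(len(sel_a), axis=0)
        dfl = -(logp[n_idx, s_idx, lo] * wl + logp[n_idx, s_idx, hi] * wr)
        dfl_loss = (dfl.mean(axis=1) * w).sum()
    else:
        box_loss = Tensor(np.zeros(()))
        dfl_loss = Tensor(np.zeros(()))

    total = LOSS_W_BOX * box_loss + LOSS_W_CLS * cls_loss + LOSS_W_DFL * dfl_loss
    return total, box_loss, cls_loss, dfl_loss


class TrainConfig:
    def __init__(self, epochs=30, batch_size=4, imgsz=160, lr=1e-3,
                 momentum=0.937, weight_decay=5e-4, seed=0):
        self.epochs, self.batch_size, self.imgsz = epochs, batch_size, imgsz
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.seed = seed


def _load_split(manifest: DatasetManifest, split: str):
    paths = manifest.splits[split]
    images, targets = [], []
    for p in paths:
        img, boxes, classes = load_sample(manifest, p)
        images.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        targets.append((boxes, classes))
    return np.stack(images), targets


def _optimizer(model, cfg):
    decay, nodecay = [], []
    for m in model.modules():
        for name in ("weight", "w", "dw"):
            p = getattr(m, name, None)
            if p is not None and hasattr(p, "data") and p.data.ndim == 4:
                decay.append(p)
    ids = {id(p) for p in decay}
    nodecay = [p for p in model.parameters() if id(p) not in ids]
    return SGD(decay, nodecay, lr=cfg.lr, momentum=cfg.momentum,
               weight_decay=cfg.weight_decay)


def smoke_train(model: DetectionModel, manifest: DatasetManifest,
                cfg: TrainConfig | None = None, split: str = "train",
                verbose: bool = False):
    """Short deterministic training run; returns per-epoch loss history."""
    cfg = cfg or TrainConfig()
    images, targets = _load_split(manifest, split)
    if len(images) == 0:
        raise ValueError(f"no images in split {split!r}")
    rng = np.random.default_rng(cfg.seed)
    opt = _optimizer(model, cfg)
    model.train()
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(images))
        sums = np.zeros(4)
        nb = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = Tensor(images[idx])
            outs = model(x)
            total, lb, lc, ld = detection_loss(
                outs, [targets[i] for i in idx], model.nc, model.reg_max)
            opt.zero_grad()
            total.backward()
            opt.step()
            sums += (total.item(), lb.item(), lc.item(), ld.item())
            nb += 1
        rec = {"epoch": epoch + 1, "total": sums[0] / nb, "box": sums[1] / nb,
               "cls": sums[2] / nb, "dfl": sums[3] / nb}
        history.append(rec)
        if verbose:
            print(f"epoch {rec['epoch']:3d}  total {rec['total']:.4f}  "
                  f"box {rec['box']:.4f}  cls {rec['cls']:.4f}  dfl {rec['dfl']:.4f}")
    return history


def evaluate(model: DetectionModel, manifest: DatasetManifest,
             split: str = "val", conf_thres: float = 0.25,
             iou_nms: float = 0.45):
    """Run inference over a split and report mAP@0.5 and mAP@0.5:0.95."""
    images, targets = _load_split(manifest, split)
    model.eval()
    dets = []
    imgsz = images.shape[-1]
    for i in range(len(images)):
        with no_grad():
            outs = model(Tensor(images[i: i + 1]))
        b, c, s = decode_boxes(outs, model.nc, model.reg_max, img_size=imgsz,
                               conf_thres=conf_thres)
        dets.append(nms(b, c, s, iou_thres=iou_nms))
    m50, m5095 = map_metrics(dets, targets, model.nc)
    return {"map50": m50, "map50_95": m5095}
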