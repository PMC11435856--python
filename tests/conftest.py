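"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (nested loops, direct formulas) so
they stay independent of the implementation paths they check.
"""
from __future__ import annotations

import numpy as np
import pytest


def naive_max_pool(x: np.ndarray, k: int) -> np.ndarray:
    """Direct sliding-window k x k stride-1 max pool with -inf padding.

    ``x`` is (C, H, W); same-padding.
    """
    pad = (k - 1) // 2
    c, h, w = x.shape
    xp = np.full((c, h + 2 * pad, w + 2 * pad), -np.inf, dtype=x.dtype)
    xp[:, pad:pad + h, pad:pad + w] = x
    out = np.empty_like(x)
    for i in range(h):
        for j in range(w):
            out[:, i, j] = xp[:, i:i + k, j:j + k].max(axis=(1, 2))
    return out


def naive_unfold(x: np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """im2col by nested loops: (C, H, W) -> (C, k*k, H', W'), zero padding."""
    pad = (k - 1) // 2
    c, h, w = x.shape
    xp = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    xp[:, pad:pad + h, pad:pad + w] = x
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    out = np.empty((c, k * k, oh, ow), dtype=x.dtype)
    for i in range(oh):
        for j in range(ow):
            patch = xp[:, i * stride:i * stride + k, j * stride:j * stride + k]
            out[:, :, i, j] = patch.reshape(c, k * k)
    return out


def naive_average_precision(conf, tp_flags, n_gt: int) -> float:
    """Brute-force AP: 101-point interpolation computed straight from the
    definition, sweeping every confidence threshold."""
    conf = np.asarray(conf, dtype=float)
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if n_gt == 0:
        return float("nan")
    order = np.argsort(-conf)
    tp = tp_flags[order]
    precisions, recalls = [], []
    for i in range(1, len(tp) + 1):
        t = tp[:i].sum()
        precisions.append(t / i)
        recalls.append(t / n_gt)
    total = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for p, rr in zip(precisions, recalls):
            if rr >= r - 1e-12 and p > best:
                best = p
        total += best
    return total / 101


def naive_iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Ten 96-px scenes split 7/2/1 for loader and evaluation tests."""
    from uwdetect.data import default_specs, write_dataset

    root = tmp_path_factory.mktemp("scenes")
    specs = default_specs(10, size=96, seed=11, n_objects=3)
    return write_dataset(root, specs)
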