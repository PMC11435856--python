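"""Switchable atrous convolution: switch behaviour, boundary equivalences,
convexity and weight-sharing semantics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uwdetect import ops
from uwdetect.autograd import Tensor
from uwdetect.blocks import Bottleneck
from uwdetect.model import count_params
from uwdetect.sac import SACBottleneck, SAConv, c2f_saconv


@pytest.fixture
def sac():
    return SAConv(4, 4, rng=np.random.default_rng(0))


def _branches(sac, x):
    b1 = ops.conv2d(x, sac.w, dilation=1).data
    b2 = ops.conv2d(x, sac.w + sac.dw, dilation=sac.rate).data
    return b1, b2


def test_switch_zero_conv_gives_half(sac, rng):
    sac.switch_conv.weight.data[:] = 0.0
    sac.switch_conv.bias.data[:] = 0.0
    s = sac.switch(Tensor(rng.standard_normal((1, 4, 6, 6)))).data
    assert s.shape == (1, 1, 6, 6)
    assert np.allclose(s, 0.5)


def test_switch_constant_input_constant_output(sac):
    x = Tensor(np.full((1, 4, 8, 8), 2.0, dtype=np.float32))
    s = sac.switch(x).data
    assert np.allclose(s, s[0, 0, 4, 4])


def test_switch_strictly_inside_unit_interval(sac, rng):
    s = sac.switch(Tensor(rng.standard_normal((1, 4, 8, 8)) * 50)).data
    assert np.all(s > 0) and np.all(s < 1)


@pytest.mark.parametrize("bias,branch", [(1e3, 0), (-1e3, 1)])
def test_boundary_equivalences(sac, rng, bias, branch):
    """S -> 1 selects the rate-1 branch; S -> 0 the dilated w+dw branch."""
    sac.dw.data[:] = rng.standard_normal(sac.dw.shape) * 0.1
    sac.switch_conv.bias.data[:] = bias
    x = Tensor(rng.standard_normal((1, 4, 8, 8)))
    out = sac(x).data
    assert np.allclose(out, _branches(sac, x)[branch], atol=1e-5)


def test_dilated_branch_receptive_field_impulse(sac):
    """A far-corner impulse at offset (3,3) reaches the centre output of the
    rate-3 branch but not the rate-1 branch."""
    x = np.zeros((1, 4, 9, 9), dtype=np.float32)
    x[0, 0, 4 + 3, 4 + 3] = 1.0
    b1, b2 = _branches(sac, Tensor(x))
    assert np.allclose(b1[0, :, 4, 4], 0.0)
    assert not np.allclose(b2[0, :, 4, 4], 0.0)


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_convexity_output_between_branches(seed):
    rng = np.random.default_rng(seed)
    sac = SAConv(3, 3, rng=rng)
    sac.dw.data[:] = rng.standard_normal(sac.dw.shape) * 0.3
    sac.switch_conv.bias.data[:] = rng.standard_normal(1)
    x = Tensor(rng.standard_normal((1, 3, 7, 7)).astype(np.float32))
    out = sac(x).data
    b1, b2 = _branches(sac, x)
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    assert np.all(out >= lo - 1e-5) and np.all(out <= hi + 1e-5)


def test_weight_sharing_w_moves_both_branches_dw_only_dilated(sac, rng):
    x = Tensor(rng.standard_normal((1, 4, 8, 8)))
    b1a, b2a = _branches(sac, x)
    sac.dw.data[0, 0, 1, 1] += 0.5
    b1b, b2b = _branches(sac, x)
    assert np.array_equal(b1a, b1b)          # dw does not touch rate-1
    assert not np.allclose(b2a, b2b)
    sac.w.data[0, 0, 1, 1] += 0.5
    b1c, b2c = _branches(sac, x)
    assert not np.allclose(b1b, b1c) and not np.allclose(b2b, b2c)


def test_sac_bottleneck_zero_weights_is_identity(rng):
    sb = SACBottleneck(6, shortcut=True, rng=np.random.default_rng(1))
    sb.eval()
    for m in (sb.sac.w, sb.sac.dw):
        m.data[:] = 0.0
    sb.cbs.conv.weight.data[:] = 0.0
    sb.restore.weight.data[:] = 0.0
    x = rng.standard_normal((1, 6, 8, 8)).astype(np.float32)
    assert np.allclose(sb(Tensor(x)).data, x, atol=1e-6)


def test_sac_bottleneck_shape_and_param_excess(rng):
    sb = SACBottleneck(8, rng=np.random.default_rng(2))
    y = sb(Tensor(rng.standard_normal((2, 8, 10, 10))))
    assert y.shape == (2, 8, 10, 10)
    # layerwise enumeration: excess over a plain bottleneck equals
    # |dw| + switch conv + the extra 1x1-restore stage params
    plain = count_params(Bottleneck(8, 8, rng=np.random.default_rng(3)))
    c = h = 8
    excess = (c * h * 9          # dw
              + (c + 1)          # switch conv
              + (h * c + 2 * c)) # 1x1 restore conv + its norm
    assert count_params(sb) == plain + excess


def test_c2f_saconv_matches_c2f_shape_contract(rng):
    blk = c2f_saconv(64, 64, n=1, shortcut=True, rng=np.random.default_rng(4))
    blk.eval()
    x = Tensor(rng.standard_normal((1, 64, 12, 12)))
    y1, y2 = blk(x).data, blk(x).data
    assert y1.shape == (1, 64, 12, 12)
    assert np.array_equal(y1, y2)  # deterministic across repeated runs


def test_c2f_saconv_rate1_only_equals_shared_kernel_network(rng):
    """With dw = 0 and the switch saturated at S = 1 the block is exactly a
    rate-1-only network: the dilated branch becomes irrelevant."""
    blk = c2f_saconv(16, 16, n=1, shortcut=True, rng=np.random.default_rng(5))
    blk.eval()
    x = Tensor(rng.standard_normal((1, 16, 10, 10)))
    for bneck in blk.m:
        bneck.sac.dw.data[:] = 0.0
        bneck.sac.switch_conv.bias.data[:] = 1e3
        bneck.sac.switch_conv.weight.data[:] = 0.0
    ref = blk(x).data
    # perturbing only what the dilated branch adds must not change anything
    for bneck in blk.m:
        bneck.sac.rate = 5
    assert np.allclose(blk(x).data, ref, atol=1e-6)
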