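"""RFESEConv: context injection, ESE weights, receptive-field features and
softmax attention, checked against scalar and sliding-window oracles."""
import numpy as np
import pytest
from conftest import naive_unfold

from uwdetect.autograd import Tensor
from uwdetect.rfese import RFESEConv


@pytest.fixture
def module(rng):
    m = RFESEConv(4, 8, stride=1, rng=np.random.default_rng(3))
    m.eval()
    return m


def test_context_inject_zero_conv_is_identity(module, rng):
    module.gc_conv.weight.data[:] = 0.0
    module.gc_conv.bias.data[:] = 0.0
    x = Tensor(rng.standard_normal((1, 4, 6, 6)))
    assert np.allclose(module.global_context_inject(x).data, x.data)


def test_context_inject_constant_input_stays_constant(module):
    x = Tensor(np.broadcast_to(np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1),
                               (1, 4, 6, 6)).copy())
    y = module.global_context_inject(x).data
    assert np.allclose(y, y[:, :, :1, :1])  # spatially constant per channel


def test_context_inject_matches_hand_computation():
    m = RFESEConv(2, 2, rng=np.random.default_rng(0))
    w = np.array([[0.5, -1.0], [2.0, 0.25]], dtype=np.float32)
    m.gc_conv.weight.data[:] = w.reshape(2, 2, 1, 1)
    m.gc_conv.bias.data[:] = [0.1, -0.2]
    x = np.array([[[1.0, 2.0], [3.0, 4.0]],
                  [[-1.0, 0.0], [1.0, 2.0]]], dtype=np.float32)[None]
    gap = x.mean(axis=(2, 3))[0]                      # (2.5, 0.5)
    ctx = w @ gap + np.array([0.1, -0.2])
    y = m.global_context_inject(Tensor(x)).data
    assert np.allclose(y, x + ctx.reshape(1, 2, 1, 1), atol=1e-6)


def test_ese_zero_transform_gives_half_weights(module):
    module.ese_conv.weight.data[:] = 0.0
    module.ese_conv.bias.data[:] = 0.0
    w = module.ese_attention(Tensor(np.random.default_rng(0)
                                    .standard_normal((1, 4, 5, 5)))).data
    assert np.allclose(w, 0.5)


def test_ese_identity_transform_is_sigmoid_of_channel_mean(rng):
    m = RFESEConv(3, 3, rng=np.random.default_rng(1))
    m.ese_conv.weight.data[:] = np.eye(3).reshape(3, 3, 1, 1)
    m.ese_conv.bias.data[:] = 0.0
    x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
    w = m.ese_attention(Tensor(x)).data[0, :, 0, 0]
    expected = 1.0 / (1.0 + np.exp(-x.mean(axis=(2, 3))[0]))
    assert np.allclose(w, expected, atol=1e-6)


def test_ese_weights_strictly_inside_unit_interval(module, rng):
    w = module.ese_attention(Tensor(rng.standard_normal((2, 4, 7, 7)) * 10)).data
    assert np.all(w > 0) and np.all(w < 1)


def test_rf_features_channel_count_and_nonnegativity(module, rng):
    f = module.rf_features(Tensor(rng.standard_normal((1, 4, 6, 6))))
    assert f.shape == (1, 4, 9, 6, 6)  # C*k^2 = 36 channels grouped as (C, 9)
    assert np.all(f.data >= 0)


def test_rf_features_one_hot_selectors_equal_unfold(rng):
    """With one-hot spatial selector kernels and identity norm the grouped
    extraction reproduces im2col of the input."""
    m = RFESEConv(3, 3, rng=np.random.default_rng(2))
    m.eval()
    w = np.zeros((27, 1, 3, 3), dtype=np.float32)
    for c in range(3):
        for p in range(9):
            w[c * 9 + p, 0, p // 3, p % 3] = 1.0
    m.extract.weight.data[:] = w
    m.extract_bn.running_mean[:] = 0.0
    m.extract_bn.running_var[:] = 1.0 - m.extract_bn.eps
    x = np.abs(rng.standard_normal((3, 6, 6))).astype(np.float32)  # ReLU-safe
    f = m.rf_features(Tensor(x[None])).data[0]
    oracle = naive_unfold(x, 3)
    assert np.allclose(f, oracle, atol=1e-5)


def test_rf_attention_groups_sum_to_one(module, rng):
    a = module.rf_attention(Tensor(rng.standard_normal((2, 4, 8, 8)) * 3)).data
    assert np.allclose(a.sum(axis=2), 1.0, atol=1e-6)
    assert np.all(a > 0) and np.all(a < 1)


def test_rf_attention_zero_logits_uniform(module, rng):
    module.attn_conv.weight.data[:] = 0.0
    module.attn_conv.bias.data[:] = 0.0
    a = module.rf_attention(Tensor(rng.standard_normal((1, 4, 6, 6)))).data
    assert np.allclose(a, 1.0 / 9.0, atol=1e-7)


def test_rf_attention_matches_scalar_softmax():
    m = RFESEConv(1, 1, rng=np.random.default_rng(4))
    m.eval()
    # identity pooling contribution is deterministic; pick weights so logits
    # equal pooled value times a fixed per-position gain
    gains = np.arange(1, 10, dtype=np.float32)
    m.attn_conv.weight.data[:] = gains.reshape(9, 1, 1, 1)
    m.attn_conv.bias.data[:] = 0.0
    x = np.full((1, 1, 3, 3), 0.7, dtype=np.float32)
    a = m.rf_attention(Tensor(x)).data[0, 0, :, 1, 1]
    pooled = 0.5 * (0.7 + 0.7)  # avg- and max-pool of a constant
    logits = gains * pooled
    e = np.exp(logits - logits.max())
    assert np.allclose(a, e / e.sum(), atol=1e-6)


def test_forward_shape_contract_stride2(rng):
    m = RFESEConv(32, 64, stride=2, agg_groups=4, rng=np.random.default_rng(5))
    m.eval()
    y = m(Tensor(rng.standard_normal((1, 32, 40, 40))))
    assert y.shape == (1, 64, 20, 20)


def test_forward_reduces_to_aggregation_path_when_attention_neutral(rng):
    """Uniform attention + saturated ESE + zero context: the module equals
    aggregating the (unfolded / 9) features directly."""
    m = RFESEConv(3, 6, stride=1, rng=np.random.default_rng(6))
    m.eval()
    m.gc_conv.weight.data[:] = 0.0
    m.gc_conv.bias.data[:] = 0.0
    m.ese_conv.weight.data[:] = 0.0
    m.ese_conv.bias.data[:] = 1e4          # ESE weight -> 1
    m.attn_conv.weight.data[:] = 0.0
    m.attn_conv.bias.data[:] = 0.0         # uniform attention 1/9
    x = np.abs(rng.standard_normal((1, 3, 6, 6))).astype(np.float32)
    y = m(Tensor(x)).data
    # oracle: unfold -> identical BN/ReLU -> /9 -> rearrange -> agg conv
    f = m.rf_features(Tensor(x)).data / 9.0
    b, c, _, h, w = f.shape
    re = f.reshape(b, c, 3, 3, h, w).transpose(0, 1, 4, 2, 5, 3).reshape(b, c, 3 * h, 3 * w)
    ref = m.agg_bn(m.agg(Tensor(re))).silu().data
    assert np.allclose(y, ref, atol=1e-5)


def test_forward_determinism(rng):
    m = RFESEConv(8, 8, stride=1, rng=np.random.default_rng(7))
    m.eval()
    x = Tensor(rng.standard_normal((1, 8, 10, 10)))
    assert np.array_equal(m(x).data, m(x).data)


def test_even_kernel_rejected():
    with pytest.raises(ValueError):
        RFESEConv(4, 4, k=4)
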