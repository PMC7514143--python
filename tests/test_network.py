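"""Network forward computation: context causality, convolution geometry,
pooling, and the probabilistic output contract."""

import numpy as np
import pytest

from ddinet import NetworkConfig, context_encode, init_params
from ddinet.autodiff import Tensor
from ddinet.network import (
    batch_arrays, dilated_conv, forward_batch, fuse_semantic, max_pool,
    typical_conv,
)


def _random_embeddings(rng, B=2, L=9, n_w=8):
    return Tensor(rng.normal(size=(B, L, n_w)))


def _ctx_params(cfg, rng):
    p = init_params(cfg, vocab_size=10, seed=7)
    return p


@pytest.fixture
def ctx_cfg():
    return NetworkConfig(word_dim=8, hidden=3, fused_dim=6, pos_dim=2,
                         n_filters=4, max_len=12, dropout=0.0,
                         filter_sizes=(2,), dilated_filter_sizes=(2,))


# ---------------------------------------------------------------------------
# recurrent context

def test_context_dimensions_are_twice_hidden(ctx_cfg):
    rng = np.random.default_rng(0)
    params = _ctx_params(ctx_cfg, rng)
    ew = _random_embeddings(rng)
    el, er = context_encode(ew, params, ctx_cfg)
    assert el.shape == (2, 9, 2 * ctx_cfg.hidden)
    assert er.shape == (2, 9, 2 * ctx_cfg.hidden)


def test_default_dimensions_match_reference_geometry():
    cfg = NetworkConfig()
    assert cfg.hidden == 100 and cfg.context_dim == 200
    assert cfg.concat_dim == 600           # n_l + n_w + n_r
    assert cfg.embed_dim == 200 + 2 * 15   # fused semantic + two position parts


@pytest.mark.parametrize("cell", ["lstm", "simple"])
def test_left_context_is_causal(ctx_cfg, cell):
    """Permuting tokens at positions > i leaves left_context(i) unchanged."""
    cfg = NetworkConfig(**{**ctx_cfg.to_dict(), "cell": cell})
    rng = np.random.default_rng(1)
    params = _ctx_params(cfg, rng)
    ew = rng.normal(size=(1, 8, cfg.word_dim))
    el, er = context_encode(Tensor(ew), params, cfg)
    i = 4
    shuffled = ew.copy()
    shuffled[0, i + 1:] = shuffled[0, i + 1:][::-1]
    shuffled[0, i + 1:] += rng.normal(size=shuffled[0, i + 1:].shape)
    el2, _ = context_encode(Tensor(shuffled), params, cfg)
    np.testing.assert_allclose(el2.data[0, :i + 1], el.data[0, :i + 1])


def test_right_context_is_anticausal(ctx_cfg):
    rng = np.random.default_rng(2)
    params = _ctx_params(ctx_cfg, rng)
    ew = rng.normal(size=(1, 8, ctx_cfg.word_dim))
    _, er = context_encode(Tensor(ew), params, ctx_cfg)
    i = 4
    shuffled = ew.copy()
    shuffled[0, :i] += rng.normal(size=shuffled[0, :i].shape)
    _, er2 = context_encode(Tensor(shuffled), params, ctx_cfg)
    np.testing.assert_allclose(er2.data[0, i:], er.data[0, i:])


def test_length_one_sequence_gets_boundary_context(ctx_cfg):
    """With no neighbours both contexts equal the zero boundary state."""
    rng = np.random.default_rng(3)
    params = _ctx_params(ctx_cfg, rng)
    ew = _random_embeddings(rng, B=2, L=1)
    el, er = context_encode(ew, params, ctx_cfg)
    np.testing.assert_allclose(el.data, 0.0)
    np.testing.assert_allclose(er.data, 0.0)


def test_context_empty_sequence_raises(ctx_cfg):
    params = _ctx_params(ctx_cfg, np.random.default_rng(0))
    with pytest.raises(ValueError):
        context_encode(Tensor(np.zeros((1, 0, 8))), params, ctx_cfg)


def test_bilstm_mode_runs_and_differs(ctx_cfg):
    cfg = NetworkConfig(**{**ctx_cfg.to_dict(), "context_mode": "bilstm"})
    rng = np.random.default_rng(4)
    params = _ctx_params(cfg, rng)
    ew = _random_embeddings(rng)
    el, er = context_encode(ew, params, cfg)
    assert el.shape[-1] == 2 * cfg.hidden
    # full-sequence reading: left context is NOT causal in this mode
    shuffled = ew.data.copy()
    shuffled[0, -1] += 1.0
    el2, _ = context_encode(Tensor(shuffled), params, cfg)
    assert not np.allclose(el2.data[0, 2], el.data[0, 2])


# ---------------------------------------------------------------------------
# fusion

def test_fusion_zero_weights_zero_output():
    word = Tensor(np.random.default_rng(0).normal(size=(2, 5, 4)))
    left = Tensor(np.random.default_rng(1).normal(size=(2, 5, 3)))
    right = Tensor(np.random.default_rng(2).normal(size=(2, 5, 3)))
    W = Tensor(np.zeros((10, 6)))
    out = fuse_semantic(word, left, right, W, Tensor(np.zeros(6)))
    np.testing.assert_allclose(out.data, 0.0)


def test_fusion_identity_block_reproduces_word_slice():
    rng = np.random.default_rng(5)
    word = Tensor(rng.normal(size=(1, 4, 4)))
    left = Tensor(rng.normal(size=(1, 4, 3)))
    right = Tensor(rng.normal(size=(1, 4, 3)))
    W = np.zeros((10, 4))
    W[3:7, :] = np.eye(4)          # select the word part of [left; word; right]
    out = fuse_semantic(word, left, right, Tensor(W), Tensor(np.zeros(4)))
    np.testing.assert_allclose(out.data, word.data)


def test_fusion_dimension_mismatch_raises():
    with pytest.raises(ValueError, match="dim"):
        fuse_semantic(Tensor(np.zeros((1, 2, 4))), Tensor(np.zeros((1, 2, 3))),
                      Tensor(np.zeros((1, 2, 3))), Tensor(np.zeros((9, 5))),
                      Tensor(np.zeros(5)))


# ---------------------------------------------------------------------------
# convolutions: independent brute-force oracle

def _brute_conv(E, W, b, dilation):
    """Window-enumeration oracle for the convolution output."""
    B, L, C = E.shape
    k = W.shape[0]
    span = (k - 1) * dilation + 1
    out = []
    for i in range(L - span + 1):
        taps = sum(E[:, i + j * dilation, :] @ W[j] for j in range(k))
        out.append(np.maximum(taps + b, 0.0))
    return np.stack(out, axis=1)


@pytest.mark.parametrize("L,k,d", [(10, 3, 1), (10, 3, 2), (12, 5, 2),
                                   (7, 2, 3), (150, 3, 2), (150, 3, 1)])
def test_conv_output_lengths_and_values(L, k, d):
    rng = np.random.default_rng(k * 100 + d)
    E = rng.normal(size=(2, L, 4))
    W = rng.normal(size=(k, 4, 3))
    b = rng.normal(size=3)
    out = dilated_conv(Tensor(E), Tensor(W), Tensor(b), dilation=d)
    assert out.shape[1] == L - (k - 1) * d          # valid-window count
    np.testing.assert_allclose(out.data, _brute_conv(E, W, b, d), atol=1e-12)
    if d == 1:
        typ = typical_conv(Tensor(E), Tensor(W), Tensor(b))
        assert typ.shape[1] == L - k + 1
        np.testing.assert_allclose(typ.data, out.data)


def test_dilated_taps_are_spaced():
    """A D_k=3, d=2 filter spans 5 positions with taps at offsets 0, 2, 4."""
    L, C = 9, 1
    W = np.ones((3, C, 1))
    E = np.zeros((1, L, C))
    E[0, 4, 0] = 1.0                  # impulse
    out = dilated_conv(Tensor(E), Tensor(W), Tensor(np.zeros(1)), dilation=2)
    # positions whose taps {i, i+2, i+4} include 4 respond
    np.testing.assert_allclose(out.data[0, :, 0], [1, 0, 1, 0, 1])


def test_conv_coordinate_selector():
    rng = np.random.default_rng(9)
    E = rng.normal(size=(1, 6, 3))
    W = np.zeros((1, 3, 1))
    W[0, 1, 0] = 1.0                  # k=1 filter selecting coordinate 1
    out = typical_conv(Tensor(E), Tensor(W), Tensor(np.zeros(1)))
    np.testing.assert_allclose(out.data[0, :, 0], np.maximum(E[0, :, 1], 0.0))


def test_conv_zero_input_zero_bias_is_zero():
    out = typical_conv(Tensor(np.zeros((1, 5, 2))),
                       Tensor(np.random.default_rng(0).normal(size=(3, 2, 4))),
                       Tensor(np.zeros(4)))
    np.testing.assert_allclose(out.data, 0.0)


def test_conv_sequence_too_short_raises():
    with pytest.raises(ValueError, match="span"):
        dilated_conv(Tensor(np.zeros((1, 4, 2))),
                     Tensor(np.zeros((3, 2, 1))), Tensor(np.zeros(1)),
                     dilation=2)


# ---------------------------------------------------------------------------
# pooling

def test_max_pool_example():
    F = Tensor(np.array([1.0, 3.0, 2.0, 5.0]).reshape(1, 4, 1))
    out = max_pool(F, window=2)
    np.testing.assert_allclose(out.data[0, :, 0], [3.0, 5.0])


def test_max_pool_constant_and_global():
    F = Tensor(np.full((1, 6, 2), 4.2))
    np.testing.assert_allclose(max_pool(F, 3).data, 4.2)
    assert max_pool(F, 6).shape == (1, 1, 2)


def test_max_pool_window_too_large_raises():
    with pytest.raises(ValueError, match="window"):
        max_pool(Tensor(np.zeros((1, 3, 1))), window=4)


# ---------------------------------------------------------------------------
# full forward

def test_forward_outputs_probability_distribution(tiny_net):
    params = init_params(tiny_net, vocab_size=15, seed=0)
    rng = np.random.default_rng(0)
    ids = rng.integers(0, 15, size=(3, tiny_net.max_len))
    d1 = rng.integers(1, 2 * tiny_net.max_len, size=(3, tiny_net.max_len))
    d2 = rng.integers(1, 2 * tiny_net.max_len, size=(3, tiny_net.max_len))
    probs = np.exp(forward_batch(params, tiny_net, ids, d1, d2).data)
    assert probs.shape == (3, 5)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(probs > 0) and np.all(probs < 1)
    # eval-mode forward is deterministic
    again = np.exp(forward_batch(params, tiny_net, ids, d1, d2).data)
    np.testing.assert_array_equal(probs, again)


def test_ablation_flags_change_embedding_dim(tiny_net):
    base = tiny_net.embed_dim
    no_pos = NetworkConfig(**{**tiny_net.to_dict(), "use_position": False})
    no_ctx = NetworkConfig(**{**tiny_net.to_dict(), "use_context": False})
    no_fuse = NetworkConfig(**{**tiny_net.to_dict(), "use_fusion": False})
    assert no_pos.embed_dim == base - 2 * tiny_net.pos_dim
    assert no_ctx.semantic_dim == tiny_net.word_dim
    assert no_fuse.semantic_dim == tiny_net.word_dim + 4 * tiny_net.hidden
    for cfg in (no_pos, no_ctx, no_fuse):
        params = init_params(cfg, vocab_size=10, seed=0)
        ids = np.zeros((1, cfg.max_len), dtype=int)
        d = np.ones((1, cfg.max_len), dtype=int)
        probs = np.exp(forward_batch(params, cfg, ids, d, d).data)
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-12)
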