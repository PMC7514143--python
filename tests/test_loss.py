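"""Class weighting, the improved focal loss, and training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddinet import (
    DDIExtractor, LossConfig, NetworkConfig, TrainConfig,
    compute_class_weights, cross_entropy, improved_focal_loss,
)
from ddinet.autodiff import Tensor
from ddinet.loss import batch_loss
from ddinet.synthetic import GeneratorConfig, generate


def _random_probs(rng, C=5):
    p = rng.random(C) + 1e-3
    return p / p.sum()


# ---------------------------------------------------------------------------
# class weights

def test_class_weights_benchmark_training_counts():
    alpha = compute_class_weights([822, 1669, 1319, 188, 19012])
    np.testing.assert_allclose(np.round(alpha, 2),
                               [0.15, 0.08, 0.10, 0.67, 0.01])


def test_class_weights_symmetry_cases():
    np.testing.assert_allclose(compute_class_weights([7] * 5), [0.2] * 5)
    np.testing.assert_allclose(compute_class_weights([1, 1]), [0.5, 0.5])


def test_class_weights_zero_count_errors():
    with pytest.raises(ValueError, match="positive count"):
        compute_class_weights([10, 0, 5, 3, 2])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(1, 10 ** 6), min_size=2, max_size=8))
def test_class_weights_sum_and_ordering(counts):
    alpha = compute_class_weights(counts)
    assert np.isclose(alpha.sum(), 1.0)
    order = np.argsort(counts)
    assert np.all(np.diff(alpha[order]) <= 1e-15)   # bigger count, smaller weight


# ---------------------------------------------------------------------------
# losses

def test_cross_entropy_closed_forms():
    probs = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
    probs[2] = 1.0
    assert cross_entropy(probs, 2) == pytest.approx(0.0)
    probs[2] = np.exp(-1.0)
    assert cross_entropy(probs, 2) == pytest.approx(1.0)
    probs[2] = 0.5
    assert cross_entropy(probs, 2) == pytest.approx(np.log(2))


def test_focal_reduces_to_cross_entropy_when_e_zero():
    rng = np.random.default_rng(0)
    cfg = LossConfig(gamma=2.0, e_weight=0.0, alpha=np.full(5, 0.2))
    for _ in range(1000):
        p = _random_probs(rng)
        y = rng.integers(5)
        assert improved_focal_loss(p, y, cfg) == cross_entropy(p, y)


def test_focal_gamma_zero_e_one_is_alpha_weighted_ce():
    rng = np.random.default_rng(1)
    alpha = compute_class_weights(rng.integers(1, 100, size=5))
    cfg = LossConfig(gamma=0.0, e_weight=1.0, alpha=alpha)
    for _ in range(200):
        p = _random_probs(rng)
        y = rng.integers(5)
        assert improved_focal_loss(p, y, cfg) == pytest.approx(
            alpha[y] * cross_entropy(p, y), rel=1e-12)


def test_focal_modulating_factor_100x_at_p09():
    """At gamma=2 and p_t=0.9, the focal factor scales the loss by 1/100."""
    probs = np.array([0.9, 0.025, 0.025, 0.025, 0.025])
    focal_only = LossConfig(gamma=2.0, e_weight=1.0, alpha=np.ones(5))
    ratio = improved_focal_loss(probs, 0, focal_only) / cross_entropy(probs, 0)
    assert ratio == pytest.approx(0.01, rel=1e-12)


def test_focal_vanishes_as_pt_approaches_one():
    cfg = LossConfig(gamma=2.0, e_weight=0.9, alpha=np.full(5, 0.2))
    probs = np.array([1.0 - 1e-12] + [2.5e-13] * 4)
    assert improved_focal_loss(probs, 0, cfg) < 1e-10


def test_focal_nonnegative_and_decreasing_in_pt():
    cfg = LossConfig(gamma=2.0, e_weight=0.9, alpha=np.full(5, 0.2))
    pts = np.linspace(0.01, 0.99, 50)
    losses = []
    for pt in pts:
        probs = np.full(5, (1 - pt) / 4)
        probs[1] = pt
        losses.append(improved_focal_loss(probs, 1, cfg))
    losses = np.asarray(losses)
    assert np.all(losses >= 0)
    assert np.all(np.diff(losses) < 0)


def test_batch_loss_matches_per_instance_mean():
    """The differentiable batched loss equals the mean of the reference form."""
    rng = np.random.default_rng(2)
    cfg = LossConfig(gamma=2.0, e_weight=0.9,
                     alpha=compute_class_weights([5, 9, 4, 2, 40]))
    probs = np.stack([_random_probs(rng) for _ in range(32)])
    y = rng.integers(0, 5, size=32)
    expected = np.mean([improved_focal_loss(probs[i], y[i], cfg)
                        for i in range(32)])
    got = batch_loss(Tensor(np.log(probs)), y, cfg).item()
    assert got == pytest.approx(expected, rel=1e-12)


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(gamma=-1.0).validate()
    with pytest.raises(ValueError):
        LossConfig(e_weight=1.5).validate()


# ---------------------------------------------------------------------------
# training

def _tiny_model(n_sentences=120, seed=5, **net_kwargs):
    docs = generate(GeneratorConfig(
        n_sentences=n_sentences, seed=seed, distractor_rate=0.0,
        class_proportions=(0.2, 0.2, 0.2, 0.2, 0.2)))
    net = NetworkConfig(word_dim=12, hidden=4, fused_dim=12, pos_dim=3,
                        n_filters=4, max_len=24, dropout=0.0, **net_kwargs)
    return DDIExtractor.from_corpus(docs, network=net)


def test_training_loss_decreases_on_easy_data():
    model = _tiny_model()
    res = model.fit(TrainConfig(max_epochs=2, seed=0))
    assert res.history[1]["train_loss"] < res.history[0]["train_loss"]


def test_training_is_deterministic_given_seed():
    losses = []
    for _ in range(2):
        res = _tiny_model().fit(TrainConfig(max_epochs=1, seed=42))
        losses.append(res.history[0]["train_loss"])
    assert losses[0] == losses[1]


def test_training_requires_every_class():
    docs = generate(GeneratorConfig(
        n_sentences=40, seed=3, distractor_rate=0.0,
        class_proportions=(0.5, 0.5, 0.0, 0.0, 0.0)))
    net = NetworkConfig(word_dim=8, hidden=3, fused_dim=8, pos_dim=2,
                        n_filters=2, max_len=24)
    model = DDIExtractor.from_corpus(docs, network=net)
    with pytest.raises(ValueError, match="missing"):
        model.fit(TrainConfig(max_epochs=1))


def test_alpha_computed_from_training_counts():
    model = _tiny_model()
    res = model.fit(TrainConfig(max_epochs=1, seed=0))
    counts = [model.class_counts()[lab] for lab in
              ("Advice", "Effect", "Mechanism", "Int", "Negative")]
    np.testing.assert_allclose(res.loss.alpha, compute_class_weights(counts))
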