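"""Class weighting, the improved focal loss, and the Adam training loop.

The DDI corpus is heavily imbalanced (the Negative class dominates), so plain
cross-entropy lets easy negatives dominate the gradient. The training
objective here blends the class-weighted focal loss with plain cross-entropy:

    L = −e · α_t · (1 − p_t)^γ · log p_t − (1 − e) · log p_t

where p_t is the predicted probability of the true class, γ down-weights
easily classified instances, e ∈ [0, 1] balances the two terms, and the
per-class weight α_i is the normalized inverse class frequency

    α_i = (T / Count_i) / Σ_j (T / Count_j),   T = Σ_i Count_i.

Setting e = 0 recovers plain cross-entropy exactly (the ablation switch).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .corpus import LABELS, POSITIVE_LABELS
from .network import NetworkConfig, batch_arrays, forward_batch, init_params, predict
from .preprocess import EncodedInstance

__all__ = [
    "LossConfig", "TrainConfig", "TrainResult", "compute_class_weights",
    "cross_entropy", "improved_focal_loss", "batch_loss", "train",
]

_P_FLOOR = 1e-7  # numerical floor applied before the log


@dataclass
class LossConfig:
    """Hyperparameters of the improved focal loss objective."""

    gamma: float = 2.0
    e_weight: float = 0.9
    alpha: np.ndarray | None = None   # per-class weights; computed from counts if None

    def validate(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.e_weight <= 1.0:
            raise ValueError("e_weight must lie in [0, 1]")
        if self.alpha is not None and len(self.alpha) != len(LABELS):
            raise ValueError("alpha must have one entry per class")


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 5          # early stopping on dev micro-F
    seed: int = 0
    verbose: bool = False

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# class weights

def compute_class_weights(counts) -> np.ndarray:
    """Normalized inverse-frequency weights α (one per class, summing to 1)."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError(
            "class weights undefined: every class needs a positive count "
            f"(got {counts.tolist()})")
    inv = counts.sum() / counts
    return inv / inv.sum()


# ---------------------------------------------------------------------------
# per-instance losses (reference, pure-number form)

def cross_entropy(probabilities, true_class: int) -> float:
    """Plain cross-entropy −log p_t with a numerical floor on p_t."""
    p_t = max(float(np.asarray(probabilities)[true_class]), _P_FLOOR)
    return -float(np.log(p_t))


def improved_focal_loss(probabilities, true_class: int,
                        cfg: LossConfig) -> float:
    """The blended focal + cross-entropy loss for one instance."""
    cfg.validate()
    if cfg.alpha is None:
        raise ValueError("LossConfig.alpha must be set for the focal term")
    p_t = max(float(np.asarray(probabilities)[true_class]), _P_FLOOR)
    log_pt = float(np.log(p_t))
    focal = (1.0 - p_t) ** cfg.gamma if cfg.gamma != 0 else 1.0
    alpha_t = float(cfg.alpha[true_class])
    return -cfg.e_weight * alpha_t * focal * log_pt - (1.0 - cfg.e_weight) * log_pt


# ---------------------------------------------------------------------------
# batched, differentiable loss

def batch_loss(log_probs: Tensor, y: np.ndarray, cfg: LossConfig) -> Tensor:
    """Mean improved focal loss over a batch, built from autodiff ops.

    ``log_probs`` is the (B, C) log-softmax output; ``y`` the true class ids.
    """
    if cfg.alpha is None:
        raise ValueError("LossConfig.alpha must be set before training")
    B = log_probs.shape[0]
    lp_t = ad.clip_min(log_probs[np.arange(B), y], np.log(_P_FLOOR))
    p_t = ad.exp(lp_t)
    alpha_t = Tensor(np.asarray(cfg.alpha)[y])
    if cfg.gamma != 0:
        focal = (Tensor(np.ones(B)) - p_t) ** cfg.gamma
    else:
        focal = Tensor(np.ones(B))
    loss = (alpha_t * focal * lp_t) * (-cfg.e_weight) + lp_t * (cfg.e_weight - 1.0)
    return loss.mean()


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# training loop

@dataclass
class TrainResult:
    params: dict[str, Tensor]
    history: list[dict]
    best_epoch: int
    best_dev_f: float
    net_cfg: NetworkConfig
    loss_cfg: LossConfig
    train_cfg: TrainConfig


def _dev_micro_f(params, cfg, dev_set, y_dev) -> float:
    """Micro-F over the four positive classes on the dev split."""
    import warnings

    from .evaluation import confusion, micro_prf

    pred = predict(params, cfg, dev_set)
    with warnings.catch_warnings():
        # early epochs may predict no positives at all; that is simply F=0
        warnings.simplefilter("ignore")
        return micro_prf(confusion(y_dev, pred)).micro_f


def train(train_set: list[EncodedInstance],
          dev_set: list[EncodedInstance],
          vocab_size: int,
          net_cfg: NetworkConfig,
          loss_cfg: LossConfig | None = None,
          train_cfg: TrainConfig | None = None,
          params: dict[str, Tensor] | None = None,
          pretrained=None, vocab=None) -> TrainResult:
    """Mini-batch Adam optimization of the mean improved focal loss.

    α is computed once from the training-set class counts (after any
    filtering the caller applied). Training stops early when the dev micro-F
    over the positive classes has not improved for ``patience`` epochs; the
    best-dev parameter set is returned. Fully deterministic given the seed.
    """
    loss_cfg = copy.deepcopy(loss_cfg) if loss_cfg is not None else LossConfig()
    train_cfg = train_cfg or TrainConfig()
    loss_cfg.validate()
    train_cfg.validate()
    if not train_set:
        raise ValueError("empty training set")

    counts = np.bincount([e.label_id for e in train_set], minlength=len(LABELS))
    if np.any(counts == 0):
        missing = [LABELS[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"classes missing from the training set: {missing}; the "
            "inverse-frequency weights are undefined")
    if loss_cfg.alpha is None:
        loss_cfg.alpha = compute_class_weights(counts)

    rng = np.random.default_rng(train_cfg.seed)
    if params is None:
        params = init_params(net_cfg, vocab_size, seed=train_cfg.seed,
                             pretrained=pretrained, vocab=vocab)
    opt = Adam(params, lr=train_cfg.learning_rate)

    ids, d1, d2, y = batch_arrays(train_set)
    y_dev = np.asarray([e.label_id for e in dev_set]) if dev_set else None

    history: list[dict] = []
    best_f, best_epoch, best_state, bad = -1.0, 0, None, 0
    n = len(train_set)
    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, train_cfg.batch_size):
            sel = order[i:i + train_cfg.batch_size]
            opt.zero_grad()
            lp = forward_batch(params, net_cfg, ids[sel], d1[sel], d2[sel],
                               train=True, rng=rng)
            loss = batch_loss(lp, y[sel], loss_cfg)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if dev_set:
            f = _dev_micro_f(params, net_cfg, dev_set, y_dev)
            row["dev_micro_f"] = f
            if f > best_f:
                best_f, best_epoch, bad = f, epoch, 0
                best_state = {k: p.data.copy() for k, p in params.items()}
            else:
                bad += 1
        history.append(row)
        if train_cfg.verbose:
            print("  " + "  ".join(f"{k}={v:.4f}" if isinstance(v, float)
                                   else f"{k}={v}" for k, v in row.items()))
        if dev_set and bad >= train_cfg.patience:
            break
    if best_state is not None:
        for k, p in params.items():
            p.data = best_state[k]
    else:
        best_epoch, best_f = len(history), float("nan")
    return TrainResult(params=params, history=history, best_epoch=best_epoch,
                       best_dev_f=best_f, net_cfg=net_cfg,
                       loss_cfg=loss_cfg, train_cfg=train_cfg)
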