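"""The recurrent hybrid convolutional network forward computation.

Architecture, per candidate instance:

1. every token gets a word embedding plus left/right *context embeddings*
   produced by recurrent chains (LSTM by default);
2. word + contexts are fused by a fully connected layer into a compact
   semantic embedding, so position information is not dimensionally
   overwhelmed;
3. two learned position embeddings (relative distance to DRUG1 and DRUG2)
   are concatenated to the semantic embedding;
4. two convolutional branches encode the sequence: *typical* convolutions
   over consecutive windows (local context) and *dilated* convolutions whose
   taps are spaced ``d`` positions apart (dependencies between separated
   words); each branch stacks ``conv_layers`` blocks with max pooling;
5. global max pooling per branch, concatenation, dropout, and a softmax
   output layer over the five DDI classes.

Everything is expressed through :mod:`ddinet.autodiff` tensors so the whole
computation is differentiable for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .preprocess import EncodedInstance

__all__ = [
    "NetworkConfig", "init_params", "context_encode", "fuse_semantic",
    "embed_sequence", "typical_conv", "dilated_conv", "max_pool",
    "forward_batch", "forward", "predict_proba", "predict", "batch_arrays",
]


@dataclass
class NetworkConfig:
    """All architecture dimensions and structural choices.

    Defaults follow the reference configuration for the DDI task: 200-d word
    embeddings, 100 recurrent units per direction (so 200-d left and right
    context embeddings), a 200-d fused semantic embedding, 15-d position
    embeddings per entity, filter sizes 3 and 5 in both branches, dilation 2,
    two conv blocks, pooling window 2, dropout 0.5, 150-token sequences and
    5 output classes.
    """

    word_dim: int = 200
    hidden: int = 100
    fused_dim: int = 200
    pos_dim: int = 15
    filter_sizes: tuple[int, ...] = (3, 5)
    dilated_filter_sizes: tuple[int, ...] = (3, 5)
    dilation: int = 2
    n_filters: int = 100
    pool_window: int = 2
    conv_layers: int = 2
    dropout: float = 0.5
    max_len: int = 150
    n_classes: int = 5
    cell: str = "lstm"              # "lstm" | "simple"
    context_mode: str = "causal"    # "causal" | "bilstm"
    use_context: bool = True        # ablation: drop context embeddings
    use_position: bool = True       # ablation: drop position embeddings
    use_fusion: bool = True         # ablation: concat instead of fused layer

    # ---- derived dimensions -------------------------------------------
    @property
    def context_dim(self) -> int:
        """Dimension of each of the left/right context embeddings (2·hidden)."""
        return 2 * self.hidden

    @property
    def semantic_dim(self) -> int:
        if not self.use_context:
            return self.word_dim
        if self.use_fusion:
            return self.fused_dim
        return self.word_dim + 2 * self.context_dim

    @property
    def concat_dim(self) -> int:
        """Input size of the fusion layer: n_l + n_w + n_r."""
        return self.word_dim + 2 * self.context_dim

    @property
    def embed_dim(self) -> int:
        """Per-token embedding size N_E = semantic + two position embeddings."""
        return self.semantic_dim + (2 * self.pos_dim if self.use_position else 0)

    @property
    def sentence_dim(self) -> int:
        """Size of the pooled sentence vector s fed to the output layer."""
        return self.n_filters * (len(self.filter_sizes)
                                 + len(self.dilated_filter_sizes))

    def validate(self) -> None:
        if min(self.word_dim, self.hidden, self.fused_dim, self.pos_dim,
               self.n_filters, self.max_len, self.n_classes) < 1:
            raise ValueError("all dimensions must be positive")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.cell not in ("lstm", "simple"):
            raise ValueError(f"unknown cell {self.cell!r}")
        if self.context_mode not in ("causal", "bilstm"):
            raise ValueError(f"unknown context_mode {self.context_mode!r}")
        spans = [k - 1 for k in self.filter_sizes]
        spans += [(k - 1) * self.dilation for k in self.dilated_filter_sizes]
        if self.max_len - max(spans) < self.pool_window:
            raise ValueError("max_len too short for the filter/pooling geometry")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# parameter initialization

def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def _chain_names(cfg: NetworkConfig) -> list[str]:
    if not cfg.use_context:
        return []
    if cfg.context_mode == "bilstm":
        return ["fwd", "bwd"]
    return ["left_a", "left_b", "right_a", "right_b"]


def init_params(cfg: NetworkConfig, vocab_size: int, seed: int = 0,
                pretrained: dict[str, np.ndarray] | None = None,
                vocab=None) -> dict[str, Tensor]:
    """Build the trainable parameter set θ.

    Word embeddings are uniform in [−0.05, 0.05] (the out-of-vocabulary
    initialization); rows for tokens present in ``pretrained`` are overwritten
    when a vocabulary is given.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    p: dict[str, Tensor] = {}

    word = rng.uniform(-0.05, 0.05, size=(vocab_size, cfg.word_dim))
    if pretrained and vocab is not None:
        for i, tok in enumerate(vocab.tokens):
            vec = pretrained.get(tok)
            if vec is not None and len(vec) == cfg.word_dim:
                word[i] = vec
    p["word_emb"] = Tensor(word, requires_grad=True)

    if cfg.use_position:
        for name in ("pos1_emb", "pos2_emb"):
            p[name] = Tensor(rng.uniform(-0.05, 0.05,
                                         size=(2 * cfg.max_len, cfg.pos_dim)),
                             requires_grad=True)

    gates = 4 if cfg.cell == "lstm" else 1
    H = cfg.hidden
    for name in _chain_names(cfg):
        p[f"ctx_{name}_Wx"] = Tensor(
            _glorot(rng, (cfg.word_dim, gates * H), cfg.word_dim, H),
            requires_grad=True)
        p[f"ctx_{name}_Wh"] = Tensor(
            _glorot(rng, (H, gates * H), H, H), requires_grad=True)
        p[f"ctx_{name}_b"] = Tensor(np.zeros(gates * H), requires_grad=True)

    if cfg.use_context and cfg.use_fusion:
        p["fuse_W"] = Tensor(_glorot(rng, (cfg.concat_dim, cfg.fused_dim),
                                     cfg.concat_dim, cfg.fused_dim),
                             requires_grad=True)
        p["fuse_b"] = Tensor(np.zeros(cfg.fused_dim), requires_grad=True)

    for branch, sizes in (("typ", cfg.filter_sizes),
                          ("dil", cfg.dilated_filter_sizes)):
        for k in sizes:
            c_in = cfg.embed_dim
            for layer in range(1, cfg.conv_layers + 1):
                p[f"{branch}{layer}_k{k}_W"] = Tensor(
                    _glorot(rng, (k, c_in, cfg.n_filters),
                            k * c_in, cfg.n_filters), requires_grad=True)
                p[f"{branch}{layer}_k{k}_b"] = Tensor(
                    np.zeros(cfg.n_filters), requires_grad=True)
                c_in = cfg.n_filters

    p["out_W"] = Tensor(_glorot(rng, (cfg.sentence_dim, cfg.n_classes),
                                cfg.sentence_dim, cfg.n_classes),
                        requires_grad=True)
    p["out_b"] = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
    return p


# ---------------------------------------------------------------------------
# recurrent context encoding

def _step(cfg: NetworkConfig, x: Tensor, state, Wx, Wh, b):
    """One recurrent step; state is (h, c) for LSTM, (h,) for simple cells."""
    H = cfg.hidden
    if cfg.cell == "simple":
        (h,) = state
        h2 = ad.tanh(x @ Wx + h @ Wh + b)
        return h2, (h2,)
    h, c = state
    z = x @ Wx + h @ Wh + b
    i = ad.sigmoid(z[:, 0:H])
    f = ad.sigmoid(z[:, H:2 * H])
    o = ad.sigmoid(z[:, 2 * H:3 * H])
    g = ad.tanh(z[:, 3 * H:4 * H])
    c2 = f * c + i * g
    h2 = o * ad.tanh(c2)
    return h2, (h2, c2)


def _run_chain(cfg, params, name, inputs, order):
    """Run one recurrent chain over ``inputs`` in the given time order.

    Boundary states are zero vectors. Returns hidden states indexed by time.
    """
    B = inputs[0].shape[0]
    H = cfg.hidden
    zero = Tensor(np.zeros((B, H)))
    state = (zero,) if cfg.cell == "simple" else (zero, zero)
    Wx, Wh, b = (params[f"ctx_{name}_Wx"], params[f"ctx_{name}_Wh"],
                 params[f"ctx_{name}_b"])
    hs: list[Tensor | None] = [None] * len(inputs)
    for t in order:
        h, state = _step(cfg, inputs[t], state, Wx, Wh, b)
        hs[t] = h
    return hs


def context_encode(ew: Tensor, params: dict[str, Tensor],
                   cfg: NetworkConfig) -> tuple[Tensor, Tensor]:
    """Left and right context embeddings for every position of ``ew`` (B,L,n_w).

    In the default ``causal`` mode the left context of position i reads only
    embeddings at positions < i (two independently parameterized chains over
    the right-shifted inputs, concatenated) and symmetrically for the right
    context. In ``bilstm`` mode a conventional full-sequence BiLSTM is run and
    each position's contexts are its neighbours' hidden states (not causal).
    """
    B, L, n_w = ew.shape
    if L < 1:
        raise ValueError("empty sequence")
    zero_in = Tensor(np.zeros((B, n_w)))
    if cfg.context_mode == "causal":
        left_in = [zero_in] + [ew[:, t - 1, :] for t in range(1, L)]
        right_in = [ew[:, t + 1, :] for t in range(L - 1)] + [zero_in]
        fwd, bwd = list(range(L)), list(range(L - 1, -1, -1))
        la = _run_chain(cfg, params, "left_a", left_in, fwd)
        lb = _run_chain(cfg, params, "left_b", left_in, fwd)
        ra = _run_chain(cfg, params, "right_a", right_in, bwd)
        rb = _run_chain(cfg, params, "right_b", right_in, bwd)
        el = ad.stack([ad.concat([la[t], lb[t]], axis=1) for t in range(L)], axis=1)
        er = ad.stack([ad.concat([ra[t], rb[t]], axis=1) for t in range(L)], axis=1)
        return el, er
    # bilstm: shared full-sequence chains, neighbour states as context
    xs = [ew[:, t, :] for t in range(L)]
    hf = _run_chain(cfg, params, "fwd", xs, list(range(L)))
    hb = _run_chain(cfg, params, "bwd", xs, list(range(L - 1, -1, -1)))
    zero_h = Tensor(np.zeros((B, cfg.hidden)))
    el_t = [ad.concat([hf[t - 1] if t > 0 else zero_h,
                       hb[t - 1] if t > 0 else zero_h], axis=1)
            for t in range(L)]
    er_t = [ad.concat([hf[t + 1] if t < L - 1 else zero_h,
                       hb[t + 1] if t < L - 1 else zero_h], axis=1)
            for t in range(L)]
    return ad.stack(el_t, axis=1), ad.stack(er_t, axis=1)


def fuse_semantic(word: Tensor, left: Tensor, right: Tensor,
                  W: Tensor, b: Tensor) -> Tensor:
    """Fuse [left; word; right] into a compact semantic embedding (affine map)."""
    se = ad.concat([left, word, right], axis=-1)
    if se.shape[-1] != W.shape[0]:
        raise ValueError(
            f"fusion input dim {se.shape[-1]} != weight rows {W.shape[0]}")
    return se @ W + b


def embed_sequence(params: dict[str, Tensor], cfg: NetworkConfig,
                   token_ids: np.ndarray, dist1: np.ndarray,
                   dist2: np.ndarray) -> Tensor:
    """Per-token embedding matrix E (B, L, N_E): semantic + position parts."""
    if cfg.use_position:
        if dist1.max() >= 2 * cfg.max_len or dist2.max() >= 2 * cfg.max_len:
            raise ValueError("position index outside embedding table")
    ew = ad.embedding(params["word_emb"], token_ids)
    if cfg.use_context:
        el, er = context_encode(ew, params, cfg)
        if cfg.use_fusion:
            es = fuse_semantic(ew, el, er, params["fuse_W"], params["fuse_b"])
        else:
            es = ad.concat([el, ew, er], axis=-1)
    else:
        es = ew
    if not cfg.use_position:
        return es
    p1 = ad.embedding(params["pos1_emb"], dist1)
    p2 = ad.embedding(params["pos2_emb"], dist2)
    return ad.concat([es, p1, p2], axis=-1)


# ---------------------------------------------------------------------------
# convolutions and pooling

def _conv1d(E: Tensor, W: Tensor, b: Tensor, dilation: int,
            padding: str) -> Tensor:
    k = W.shape[0]
    span = (k - 1) * dilation + 1
    if padding == "same":
        total = span - 1
        E = ad.pad_time(E, total // 2, total - total // 2)
    L = E.shape[1]
    if L < span:
        raise ValueError(f"sequence length {L} < receptive span {span}")
    out_len = L - span + 1
    acc = None
    for j in range(k):
        piece = E[:, j * dilation:j * dilation + out_len, :] @ W[j]
        acc = piece if acc is None else acc + piece
    return ad.relu(acc + b)


def typical_conv(E: Tensor, W: Tensor, b: Tensor,
                 padding: str = "valid") -> Tensor:
    """Convolution over consecutive k-word windows + ReLU; output length n−k+1."""
    return _conv1d(E, W, b, dilation=1, padding=padding)


def dilated_conv(E: Tensor, W: Tensor, b: Tensor, dilation: int,
                 padding: str = "valid") -> Tensor:
    """Convolution with taps spaced ``dilation`` apart + ReLU.

    Receptive span is (k−1)·d+1 consecutive positions; valid output length is
    n − (k−1)·d. With d=1 this is exactly the typical convolution.
    """
    return _conv1d(E, W, b, dilation=dilation, padding=padding)


def max_pool(F: Tensor, window: int, stride: int | None = None) -> Tensor:
    """Sliding maximum over the feature sequence (stride defaults to window)."""
    return ad.maxpool1d(F, window, stride)


# ---------------------------------------------------------------------------
# full forward

def _branch(params, cfg, E, branch: str, sizes, dilation: int) -> list[Tensor]:
    outs = []
    for k in sizes:
        h = E
        for layer in range(1, cfg.conv_layers + 1):
            W = params[f"{branch}{layer}_k{k}_W"]
            b = params[f"{branch}{layer}_k{k}_b"]
            # layer 1 uses valid windows (the stated output-length formulas);
            # deeper layers use same-padding so short sequences survive.
            pad = "valid" if layer == 1 else "same"
            h = _conv1d(E=h, W=W, b=b, dilation=dilation, padding=pad)
            if layer < cfg.conv_layers:
                h = max_pool(h, cfg.pool_window)
        outs.append(ad.max_axis(h, axis=1))   # global max over time
    return outs


def forward_batch(params: dict[str, Tensor], cfg: NetworkConfig,
                  token_ids: np.ndarray, dist1: np.ndarray,
                  dist2: np.ndarray, train: bool = False,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Log class probabilities (B, C) for a batch of encoded instances."""
    E = embed_sequence(params, cfg, token_ids, dist1, dist2)
    feats = _branch(params, cfg, E, "typ", cfg.filter_sizes, 1)
    feats += _branch(params, cfg, E, "dil", cfg.dilated_filter_sizes,
                     cfg.dilation)
    s = ad.concat(feats, axis=1)
    if train and cfg.dropout > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = 1.0 - cfg.dropout
        mask = (rng.random(s.shape) < keep) / keep
        s = s * mask
    logits = s @ params["out_W"] + params["out_b"]
    return ad.log_softmax(logits)


def forward(enc: EncodedInstance, params: dict[str, Tensor],
            cfg: NetworkConfig) -> np.ndarray:
    """Probability vector over the C classes for a single instance (eval mode)."""
    lp = forward_batch(params, cfg, enc.token_ids[None, :],
                       enc.dist1[None, :], enc.dist2[None, :])
    return np.exp(lp.data[0])


def batch_arrays(encoded: list[EncodedInstance]):
    """Stack encoded instances into (ids, dist1, dist2, labels) arrays."""
    ids = np.stack([e.token_ids for e in encoded])
    d1 = np.stack([e.dist1 for e in encoded])
    d2 = np.stack([e.dist2 for e in encoded])
    y = np.asarray([e.label_id for e in encoded])
    return ids, d1, d2, y


def predict_proba(params, cfg, encoded: list[EncodedInstance],
                  batch_size: int = 64) -> np.ndarray:
    """(N, C) class probabilities, eval mode (no dropout)."""
    out = []
    for i in range(0, len(encoded), batch_size):
        ids, d1, d2, _ = batch_arrays(encoded[i:i + batch_size])
        out.append(np.exp(forward_batch(params, cfg, ids, d1, d2).data))
    return np.concatenate(out) if out else np.zeros((0, cfg.n_classes))


def predict(params, cfg, encoded: list[EncodedInstance],
            batch_size: int = 64) -> np.ndarray:
    """Predicted label ids (argmax of the class probabilities)."""
    return predict_proba(params, cfg, encoded, batch_size).argmax(axis=1)
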