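"""High-level model interface: build from a corpus, fit, inspect results.

``DDIExtractor`` bundles the preprocessing pipeline (blinding, optional
negative-instance filtering, vocabulary building, encoding) with the network
and training configuration; ``fit()`` returns a ``DDIResults`` object that
carries the trained parameters, the per-epoch history and evaluation /
prediction / persistence methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .corpus import LABELS, Document
from .evaluation import MetricsReport, as_percent, confusion, micro_prf
from .loss import LossConfig, TrainConfig, TrainResult, train
from .network import NetworkConfig, init_params, predict, predict_proba
from .preprocess import (
    CandidateInstance, EncodedInstance, FilterRecord, Vocabulary, encode,
    filter_negatives, make_candidates,
)

__all__ = ["DDIExtractor", "DDIResults", "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1


class DDIExtractor:
    """A DDI relation classifier specified by data + configuration.

    Parameters
    ----------
    train_instances, dev_instances
        Blinded candidate instances (see :func:`ddinet.preprocess.make_candidates`).
    network, loss, pretrained_embeddings
        Architecture / objective configuration and an optional token->vector
        map (word2vec text format) used to warm-start the embedding table.
    """

    def __init__(self, train_instances: list[CandidateInstance],
                 dev_instances: list[CandidateInstance] | None = None,
                 vocab: Vocabulary | None = None,
                 network: NetworkConfig | None = None,
                 loss: LossConfig | None = None,
                 pretrained_embeddings: dict | None = None):
        self.network = network or NetworkConfig()
        self.network.validate()
        self.loss = loss or LossConfig()
        self.train_instances = train_instances
        self.dev_instances = dev_instances or []
        self.vocab = vocab or Vocabulary.from_instances(train_instances)
        self.pretrained = pretrained_embeddings
        self.filter_log: list[FilterRecord] = []

    @classmethod
    def from_corpus(cls, train_docs: list[Document],
                    dev_docs: list[Document] | None = None,
                    filtering: bool = True,
                    filter_rules: tuple[str, ...] = ("R1", "R2", "R3"),
                    **kwargs) -> "DDIExtractor":
        """Build from corpus documents, applying the preprocessing pipeline.

        Negative-instance filtering is applied to the training split only;
        evaluation keeps every candidate so test-time metrics are not skewed
        by the filter.
        """
        train_inst = make_candidates(train_docs)
        removed: list[FilterRecord] = []
        if filtering:
            train_inst, removed = filter_negatives(train_inst, filter_rules)
        dev_inst = make_candidates(dev_docs) if dev_docs else []
        model = cls(train_inst, dev_inst, **kwargs)
        model.filter_log = removed
        return model

    def _encode(self, instances) -> list[EncodedInstance]:
        return [encode(i, self.vocab, self.network.max_len) for i in instances]

    def class_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for inst in self.train_instances:
            counts[inst.label] += 1
        return counts

    def fit(self, train_config: TrainConfig | None = None) -> "DDIResults":
        result = train(
            self._encode(self.train_instances),
            self._encode(self.dev_instances),
            vocab_size=len(self.vocab),
            net_cfg=self.network,
            loss_cfg=self.loss,
            train_cfg=train_config or TrainConfig(),
            pretrained=self.pretrained,
            vocab=self.vocab,
        )
        return DDIResults(result.params, self.vocab, result.net_cfg,
                          result.loss_cfg, result.train_cfg,
                          history=result.history,
                          best_epoch=result.best_epoch,
                          best_dev_f=result.best_dev_f)


@dataclass
class DDIResults:
    """A fitted classifier: parameters, history and evaluation helpers."""

    params: dict[str, Tensor]
    vocab: Vocabulary
    network: NetworkConfig
    loss: LossConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_dev_f: float = float("nan")

    # ---- inference -----------------------------------------------------
    def _encode(self, instances) -> list[EncodedInstance]:
        return [encode(i, self.vocab, self.network.max_len) for i in instances]

    def predict(self, instances: list[CandidateInstance]) -> list[str]:
        ids = predict(self.params, self.network, self._encode(instances))
        return [LABELS[i] for i in ids]

    def predict_proba(self, instances: list[CandidateInstance]) -> np.ndarray:
        return predict_proba(self.params, self.network, self._encode(instances))

    def evaluate(self, instances: list[CandidateInstance]) -> MetricsReport:
        gold = [i.label for i in instances]
        return micro_prf(confusion(gold, self.predict(instances)))

    # ---- reporting -----------------------------------------------------
    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def summary(self) -> str:
        n_params = sum(p.data.size for p in self.params.values())
        lines = [
            "DDI relation classifier — fit summary",
            "=" * 45,
            f"classes:            {', '.join(LABELS)}",
            f"vocabulary size:    {len(self.vocab)}",
            f"trainable params:   {n_params}",
            f"embedding dim N_E:  {self.network.embed_dim}",
            f"context cell/mode:  {self.network.cell}/{self.network.context_mode}",
            f"loss:               gamma={self.loss.gamma}, "
            f"e={self.loss.e_weight}",
            f"alpha:              "
            + ", ".join(f"{lab}={w:.2f}" for lab, w in
                        zip(LABELS, self.loss.alpha)),
            f"epochs run:         {len(self.history)}",
            f"best epoch:         {self.best_epoch}",
        ]
        if np.isfinite(self.best_dev_f):
            lines.append(f"best dev micro-F:   {as_percent(self.best_dev_f):.2f}%")
        return "\n".join(lines)

    # ---- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters + configs + vocabulary."""
        meta = {
            "version": CHECKPOINT_VERSION,
            "network": self.network.to_dict(),
            "loss": {"gamma": self.loss.gamma, "e_weight": self.loss.e_weight,
                     "alpha": None if self.loss.alpha is None
                     else list(map(float, self.loss.alpha))},
            "train": {"batch_size": self.train_config.batch_size,
                      "learning_rate": self.train_config.learning_rate,
                      "max_epochs": self.train_config.max_epochs,
                      "patience": self.train_config.patience,
                      "seed": self.train_config.seed},
            "vocab": self.vocab.tokens,
            "history": self.history,
            "best_epoch": self.best_epoch,
            "best_dev_f": self.best_dev_f,
        }
        arrays = {f"param_{k}": p.data for k, p in self.params.items()}
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DDIResults":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version "
                                 f"{meta.get('version')}")
            params = {k[len("param_"):]: Tensor(data[k], requires_grad=True)
                      for k in data.files if k.startswith("param_")}
        net = NetworkConfig(**{**meta["network"],
                               "filter_sizes": tuple(meta["network"]["filter_sizes"]),
                               "dilated_filter_sizes":
                                   tuple(meta["network"]["dilated_filter_sizes"])})
        lc = meta["loss"]
        loss = LossConfig(gamma=lc["gamma"], e_weight=lc["e_weight"],
                          alpha=None if lc["alpha"] is None
                          else np.asarray(lc["alpha"]))
        tc = TrainConfig(**meta["train"])
        vocab = Vocabulary()
        for tok in meta["vocab"]:
            vocab.add(tok)
        return cls(params=params, vocab=vocab, network=net, loss=loss,
                   train_config=tc, history=meta["history"],
                   best_epoch=meta["best_epoch"],
                   best_dev_f=meta["best_dev_f"])
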