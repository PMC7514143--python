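import numpy as np
import pytest

from ddinet import (
    ConfusionMatrix, Document, EntityMention, NetworkConfig, PairAnnotation,
    SentenceRecord,
)

TABLE_SENTENCE = ("DIAMOX modifies phenytoin metabolism with increased serum "
                  "levels of phenytoin.")


def _span(text: str, surface: str, from_: int = 0) -> tuple[int, int]:
    s = text.index(surface, from_)
    return (s, s + len(surface) - 1)


@pytest.fixture
def worked_sentence() -> SentenceRecord:
    """Sentence with three drug mentions (one name appearing twice)."""
    text = TABLE_SENTENCE
    s1 = _span(text, "DIAMOX")
    s2 = _span(text, "phenytoin")
    s3 = _span(text, "phenytoin", s2[1] + 1)
    sent = SentenceRecord(
        id="w.s0", text=text,
        mentions=[
            EntityMention(id="w.s0.e0", char_spans=[s1], text="DIAMOX"),
            EntityMention(id="w.s0.e1", char_spans=[s2], text="phenytoin"),
            EntityMention(id="w.s0.e2", char_spans=[s3], text="phenytoin"),
        ],
        pairs=[
            PairAnnotation(id="w.s0.p0", e1_id="w.s0.e0", e2_id="w.s0.e1",
                           label="Mechanism"),
            PairAnnotation(id="w.s0.p1", e1_id="w.s0.e0", e2_id="w.s0.e2",
                           label="Mechanism"),
            PairAnnotation(id="w.s0.p2", e1_id="w.s0.e1", e2_id="w.s0.e2",
                           label="Negative"),
        ])
    sent.validate()
    return sent


@pytest.fixture
def benchmark_confusion() -> ConfusionMatrix:
    """Published benchmark prediction table for the DDIExtraction 2013 test
    set (classifier predictions merged with filter-rule assignments)."""
    return ConfusionMatrix(np.array([
        [178,   5,   3,  2,   33],
        [  2, 269,   9,  0,   80],
        [  7,   4, 232,  0,   59],
        [  0,  36,   2, 43,   15],
        [ 34,  58,  45,  5, 4595],
    ]))


@pytest.fixture
def tiny_net() -> NetworkConfig:
    """A desk-scale architecture: same structure, small dimensions."""
    return NetworkConfig(word_dim=8, hidden=3, fused_dim=6, pos_dim=2,
                         filter_sizes=(2, 3), dilated_filter_sizes=(2, 3),
                         dilation=2, n_filters=4, pool_window=2,
                         conv_layers=2, dropout=0.0, max_len=12)


def make_simple_doc(n_mentions: int, positive_pairs=()) -> Document:
    """A one-sentence document with n generic drug mentions."""
    names = [f"drug{chr(ord('a') + i)}" for i in range(n_mentions)]
    text = "study of " + " with ".join(names) + " ."
    sent = SentenceRecord(id="d0.s0", text=text)
    cursor = 0
    for i, name in enumerate(names):
        start = text.index(name, cursor)
        sent.mentions.append(EntityMention(
            id=f"d0.s0.e{i}", char_spans=[(start, start + len(name) - 1)],
            text=name))
        cursor = start + len(name)
    for j, (a, b, lab) in enumerate(positive_pairs):
        sent.pairs.append(PairAnnotation(
            id=f"d0.s0.p{j}", e1_id=f"d0.s0.e{a}", e2_id=f"d0.s0.e{b}",
            label=lab))
    sent.validate()
    return Document(id="d0", sentences=[sent])
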