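"""Drug blinding, negative-instance filtering, tokenization and encoding.

A sentence with m drug mentions yields C(m,2) candidate pair instances. For
each candidate the two target mentions are *blinded* to the symbols DRUG1 and
DRUG2 and every other drug mention to DRUG0, so the classifier generalizes
across drug names. Rule-based filtering then removes negative candidates that
trivially cannot interact (same name / abbreviation, coordinate structures,
specializations), which mitigates the heavy class imbalance of the task.

Instances are finally encoded as fixed-length integer sequences plus two
relative-distance position features (distance of each token to DRUG1 and to
DRUG2, shifted to be non-negative so a single embedding table serves both).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import (
    LABELS, LABEL_TO_ID, NEGATIVE_LABEL, CorpusError, Document,
    EntityMention, SentenceRecord,
)

__all__ = [
    "CandidateInstance", "EncodedInstance", "Vocabulary", "FilterRecord",
    "blind", "tokenize", "filter_negatives", "encode", "decode",
    "make_candidates", "load_word2vec_text",
]

DRUG1, DRUG2, DRUG0 = "DRUG1", "DRUG2", "DRUG0"

_TOKEN_RE = re.compile(r"DRUG[012]|[A-Za-z]+|[0-9]+|[^\sA-Za-z0-9]")


def tokenize(text: str) -> list[str]:
    """Deterministic tokenizer: whitespace + punctuation splitting.

    DRUG0/DRUG1/DRUG2 survive as single tokens, everything else is
    lowercased, and runs of digits are normalized to zeros ("44" -> "00").
    """
    toks = []
    for m in _TOKEN_RE.finditer(text):
        t = m.group()
        if t in (DRUG0, DRUG1, DRUG2):
            toks.append(t)
        elif t.isdigit():
            toks.append("0" * len(t))
        else:
            toks.append(t.lower())
    return toks


# ---------------------------------------------------------------------------
# blinding

def blind(sentence: SentenceRecord,
          pair: tuple[EntityMention, EntityMention]) -> str:
    """Replace the candidate pair with DRUG1/DRUG2 and all other mentions with DRUG0.

    Replacement is offset-based and applied right-to-left so earlier offsets
    stay valid. For discontinuous mentions only the first span is replaced by
    the symbol; the remaining spans are deleted.
    """
    e1, e2 = pair
    text = sentence.text
    regions: list[tuple[int, int, str]] = []  # (start, end incl, replacement)
    for m in sentence.mentions:
        symbol = DRUG1 if m.id == e1.id else DRUG2 if m.id == e2.id else DRUG0
        first, *rest = m.char_spans
        regions.append((first[0], first[1], symbol))
        regions.extend((s, e, "") for s, e in rest)
    regions.sort()
    for (_, end_a, _), (start_b, _, _) in zip(regions, regions[1:]):
        if start_b <= end_a:
            raise CorpusError(
                f"sentence {sentence.id}: overlapping mention spans")
    if regions and regions[-1][1] >= len(text):
        raise CorpusError(f"sentence {sentence.id}: span out of range")
    for s, e, rep in reversed(regions):
        text = text[:s] + rep + text[e + 1:]
    return text


# ---------------------------------------------------------------------------
# candidate instances

@dataclass
class CandidateInstance:
    """One blinded drug-pair classification instance."""

    instance_id: str
    tokens: list[str]
    e1_index: int
    e2_index: int
    label: str
    # provenance needed by the filtering rules
    sentence_id: str = ""
    sentence_text: str = ""
    e1_text: str = ""
    e2_text: str = ""
    e1_span: tuple[int, int] = (0, 0)
    e2_span: tuple[int, int] = (0, 0)

    def validate(self) -> None:
        if self.tokens.count(DRUG1) != 1 or self.tokens.count(DRUG2) != 1:
            raise ValueError(
                f"instance {self.instance_id}: expected exactly one DRUG1 and "
                f"one DRUG2 token")
        if self.e1_index == self.e2_index:
            raise ValueError(f"instance {self.instance_id}: e1_index == e2_index")
        if self.tokens[self.e1_index] != DRUG1 or self.tokens[self.e2_index] != DRUG2:
            raise ValueError(f"instance {self.instance_id}: index/token mismatch")
        if self.label not in LABELS:
            raise ValueError(f"instance {self.instance_id}: bad label {self.label!r}")


def make_candidates(docs: list[Document], *,
                    use_gold_pairs: bool = True) -> list[CandidateInstance]:
    """Blind and tokenize every candidate pair of every sentence.

    With ``use_gold_pairs`` (annotated corpora) the pairs listed in the XML
    are trusted as the candidate set; otherwise all C(m,2) pairs are
    enumerated, with unannotated pairs labeled Negative.
    """
    from .corpus import enumerate_candidates

    out: list[CandidateInstance] = []
    for doc in docs:
        for sent in doc.sentences:
            if use_gold_pairs and sent.pairs:
                cands = []
                for p in sent.pairs:
                    m1, m2 = sent.mention(p.e1_id), sent.mention(p.e2_id)
                    if m1.start > m2.start:   # e1 precedes e2 in text
                        m1, m2 = m2, m1
                    cands.append((m1, m2, p.label, p.id))
            else:
                cands = [(m1, m2, lab, f"{sent.id}.p{i}")
                         for i, (m1, m2, lab) in
                         enumerate(enumerate_candidates(sent))]
            for m1, m2, lab, pid in cands:
                toks = tokenize(blind(sent, (m1, m2)))
                inst = CandidateInstance(
                    instance_id=pid, tokens=toks,
                    e1_index=toks.index(DRUG1), e2_index=toks.index(DRUG2),
                    label=lab, sentence_id=sent.id, sentence_text=sent.text,
                    e1_text=m1.text, e2_text=m2.text,
                    e1_span=m1.char_spans[0], e2_span=m2.char_spans[0])
                inst.validate()
                out.append(inst)
    return out


# ---------------------------------------------------------------------------
# negative-instance filtering

@dataclass
class FilterRecord:
    instance: CandidateInstance
    rule: str

    def as_row(self) -> str:
        return "\t".join((self.instance.instance_id, self.rule,
                          self.instance.e1_text, self.instance.e2_text))


_COORDINATORS = {",", ";", "and", "or", "/"}
_LINK_PHRASES = (("such", "as"), ("including",), ("e", ".", "g", "."))


def _rule_same_or_abbrev(inst: CandidateInstance) -> bool:
    """R1: identical names, or one is a parenthesized abbreviation of the other."""
    if inst.e1_text.casefold() == inst.e2_text.casefold():
        return True
    text = inst.sentence_text
    gap = text[inst.e1_span[1] + 1:inst.e2_span[0]]
    after = text[inst.e2_span[1] + 1:inst.e2_span[1] + 2]
    return gap.strip() == "(" and after == ")"


def _rule_coordinate(inst: CandidateInstance) -> bool:
    """R2: all tokens strictly between the pair are coordinators or DRUG0."""
    lo, hi = sorted((inst.e1_index, inst.e2_index))
    between = inst.tokens[lo + 1:hi]
    if not between:
        return False
    allowed = _COORDINATORS | {DRUG0}
    return (all(t in allowed for t in between)
            and any(t in _COORDINATORS for t in between))


def _rule_specialization(inst: CandidateInstance) -> bool:
    """R3: strict substring names, or a "such as"/"including"/"e.g." link."""
    a, b = inst.e1_text.casefold(), inst.e2_text.casefold()
    if a != b and (a in b or b in a):
        return True
    lo, hi = sorted((inst.e1_index, inst.e2_index))
    cleaned = tuple(t for t in inst.tokens[lo + 1:hi]
                    if t not in {",", ";", DRUG0})
    return cleaned in _LINK_PHRASES


_RULES = (("R1", _rule_same_or_abbrev),
          ("R2", _rule_coordinate),
          ("R3", _rule_specialization))


def filter_negatives(
    instances: list[CandidateInstance],
    rules: tuple[str, ...] = ("R1", "R2", "R3"),
) -> tuple[list[CandidateInstance], list[FilterRecord]]:
    """Apply the negative-instance filtering rules.

    Only Negative-labeled instances are ever removed; positive instances are
    always retained. Returns the retained instances and a removal log (one
    record per removed instance with the rule that fired first).
    """
    retained, removed = [], []
    for inst in instances:
        rule_hit = None
        if inst.label == NEGATIVE_LABEL:
            for rid, pred in _RULES:
                if rid in rules and pred(inst):
                    rule_hit = rid
                    break
        if rule_hit is None:
            retained.append(inst)
        else:
            removed.append(FilterRecord(inst, rule_hit))
    return retained, removed


def write_filter_log(removed: list[FilterRecord], path: str | Path) -> None:
    rows = ["instance_id\trule\te1_text\te2_text"]
    rows += [r.as_row() for r in removed]
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# vocabulary

class Vocabulary:
    """Token -> integer id map. Id 0 is padding, id 1 is unknown."""

    PAD, UNK = 0, 1

    def __init__(self, tokens: list[str] | None = None):
        self._id_to_token = ["<pad>", "<unk>", DRUG0, DRUG1, DRUG2]
        self._token_to_id = {t: i for i, t in enumerate(self._id_to_token)}
        for t in tokens or []:
            self.add(t)

    def add(self, token: str) -> int:
        if token not in self._token_to_id:
            self._token_to_id[token] = len(self._id_to_token)
            self._id_to_token.append(token)
        return self._token_to_id[token]

    @classmethod
    def from_instances(cls, instances: list[CandidateInstance],
                       min_count: int = 1) -> "Vocabulary":
        counts: dict[str, int] = {}
        order: list[str] = []
        for inst in instances:
            for t in inst.tokens:
                if t not in counts:
                    order.append(t)
                counts[t] = counts.get(t, 0) + 1
        return cls([t for t in order if counts[t] >= min_count])

    def get(self, token: str) -> int:
        return self._token_to_id.get(token, self.UNK)

    def token(self, idx: int) -> str:
        return self._id_to_token[idx]

    def __len__(self) -> int:
        return len(self._id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self._token_to_id

    @property
    def tokens(self) -> list[str]:
        return list(self._id_to_token)

    def save(self, path: str | Path) -> None:
        lines = [f"{t}\t{i}" for i, t in enumerate(self._id_to_token)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        vocab = cls()
        for line in Path(path).read_text().splitlines():
            tok, idx = line.split("\t")
            if int(idx) >= len(vocab._id_to_token):
                vocab.add(tok)
        return vocab


# ---------------------------------------------------------------------------
# fixed-length encoding with position features

@dataclass
class EncodedInstance:
    """Integer-encoded candidate: token ids + two position-feature sequences.

    ``dist1[i]`` / ``dist2[i]`` hold the relative distance of token i to the
    DRUG1 / DRUG2 token, clipped to ±(max_len−1) and shifted by +max_len so
    values lie in [1, 2·max_len−1]; 0 is reserved for padding positions.
    """

    instance_id: str
    token_ids: np.ndarray
    dist1: np.ndarray
    dist2: np.ndarray
    length: int
    label_id: int
    flagged: bool = False

    @property
    def label(self) -> str:
        return LABELS[self.label_id]


def encode(inst: CandidateInstance, vocab: Vocabulary,
           max_len: int) -> EncodedInstance:
    """Pad/truncate to ``max_len`` and attach the two distance features.

    When truncation would drop DRUG1 or DRUG2 the window is shifted so both
    entity tokens survive whenever their span fits in ``max_len``; otherwise
    the instance is flagged (its label cannot be grounded in the window).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    toks = inst.tokens
    k, t = inst.e1_index, inst.e2_index
    start, flagged = 0, False
    if len(toks) > max_len:
        lo, hi = min(k, t), max(k, t)
        if hi - lo + 1 <= max_len:
            start = max(0, hi - max_len + 1)
        else:
            start, flagged = lo, True
    window = toks[start:start + max_len]
    n = len(window)
    ids = np.zeros(max_len, dtype=np.int64)
    d1 = np.zeros(max_len, dtype=np.int64)
    d2 = np.zeros(max_len, dtype=np.int64)
    ids[:n] = [vocab.get(tok) for tok in window]
    kk, tt = k - start, t - start
    pos = np.arange(n)
    d1[:n] = np.clip(pos - kk, -(max_len - 1), max_len - 1) + max_len
    d2[:n] = np.clip(pos - tt, -(max_len - 1), max_len - 1) + max_len
    return EncodedInstance(
        instance_id=inst.instance_id, token_ids=ids, dist1=d1, dist2=d2,
        length=n, label_id=LABEL_TO_ID[inst.label], flagged=flagged)


def decode(enc: EncodedInstance, vocab: Vocabulary) -> list[str]:
    """Recover the (unpadded) token sequence from an encoded instance."""
    return [vocab.token(i) for i in enc.token_ids[:enc.length]]


# ---------------------------------------------------------------------------
# pretrained embeddings (word2vec text format)

def load_word2vec_text(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Read a word2vec text file: header "vocab_size dim", then token + floats.

    Returns the token -> vector map and the embedding dimension. Tokens absent
    from the file fall back to the network's OOV initialization.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: missing word2vec header line")
        _, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                continue
            vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float64)
    return vectors, dim
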