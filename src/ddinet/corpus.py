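"""Reading, writing and validating the DDIExtraction-2013 XML corpus dialect.

The corpus is a set of documents; each document holds sentences; each sentence
carries drug-entity mentions with character offsets and pair annotations that
label a drug pair with one of the five DDI classes (Mechanism, Effect, Advice,
Int) or Negative (the pair is co-mentioned but no interaction is asserted).

Character offsets follow the public corpus convention: 0-based with an
*inclusive* end ("0-5" covers six characters). Discontinuous mentions are
encoded as semicolon-separated spans ("a-b;c-d").
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

__all__ = [
    "LABELS", "POSITIVE_LABELS", "NEGATIVE_LABEL",
    "EntityMention", "PairAnnotation", "SentenceRecord", "Document",
    "CorpusError", "read_corpus", "write_corpus", "enumerate_candidates",
]

#: Canonical class order used everywhere (confusion matrices, α weights, ...).
LABELS: tuple[str, ...] = ("Advice", "Effect", "Mechanism", "Int", "Negative")
POSITIVE_LABELS: tuple[str, ...] = LABELS[:4]
NEGATIVE_LABEL = "Negative"
LABEL_TO_ID = {lab: i for i, lab in enumerate(LABELS)}

_TYPE_CANON = {lab.lower(): lab for lab in POSITIVE_LABELS}


class CorpusError(ValueError):
    """Malformed corpus content (bad XML, dangling references, bad offsets)."""


@dataclass
class EntityMention:
    """A drug-entity mention with one or more character spans."""

    id: str
    char_spans: list[tuple[int, int]]
    text: str
    entity_type: str = "drug"

    def validate(self, sentence_text: str | None = None) -> None:
        if not self.char_spans:
            raise CorpusError(f"entity {self.id}: no character spans")
        spans = sorted(self.char_spans)
        if spans != self.char_spans:
            raise CorpusError(f"entity {self.id}: spans out of order")
        for (s, e) in spans:
            if s < 0 or e < s:
                raise CorpusError(f"entity {self.id}: bad span {(s, e)}")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise CorpusError(f"entity {self.id}: overlapping spans")
        if sentence_text is not None:
            if self.char_spans[-1][1] >= len(sentence_text):
                raise CorpusError(f"entity {self.id}: span beyond sentence end")
            surface = " ".join(sentence_text[s:e + 1] for s, e in self.char_spans)
            # tolerate single-space joining differences for discontinuous spans
            if len(self.char_spans) == 1 and surface != self.text:
                raise CorpusError(
                    f"entity {self.id}: surface {surface!r} != text {self.text!r}")

    @property
    def start(self) -> int:
        return self.char_spans[0][0]


@dataclass
class PairAnnotation:
    """A labeled candidate drug pair within one sentence."""

    id: str
    e1_id: str
    e2_id: str
    label: str

    def validate(self) -> None:
        if self.e1_id == self.e2_id:
            raise CorpusError(f"pair {self.id}: e1 == e2")
        if self.label not in LABELS:
            raise CorpusError(f"pair {self.id}: unknown label {self.label!r}")


@dataclass
class SentenceRecord:
    """One corpus sentence with its entity mentions and gold pair annotations."""

    id: str
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    pairs: list[PairAnnotation] = field(default_factory=list)

    def validate(self) -> None:
        ids = set()
        for m in self.mentions:
            m.validate(self.text)
            if m.id in ids:
                raise CorpusError(f"sentence {self.id}: duplicate entity id {m.id}")
            ids.add(m.id)
        n = len(self.mentions)
        if len(self.pairs) > n * (n - 1) // 2:
            raise CorpusError(f"sentence {self.id}: more pairs than C(m,2)")
        for p in self.pairs:
            p.validate()
            if p.e1_id not in ids or p.e2_id not in ids:
                raise CorpusError(
                    f"sentence {self.id}: pair {p.id} references unknown entity")

    def mention(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.id == mention_id:
                return m
        raise CorpusError(f"sentence {self.id}: no entity {mention_id}")


@dataclass
class Document:
    id: str
    sentences: list[SentenceRecord] = field(default_factory=list)

    def validate(self) -> None:
        seen = set()
        for s in self.sentences:
            if s.id in seen:
                raise CorpusError(f"document {self.id}: duplicate sentence id {s.id}")
            seen.add(s.id)
            s.validate()


# ---------------------------------------------------------------------------
# offsets

def parse_char_offset(value: str) -> list[tuple[int, int]]:
    """Parse "a-b" or discontinuous "a-b;c-d" into inclusive-end span tuples."""
    spans = []
    for part in value.split(";"):
        try:
            a, b = part.split("-")
            spans.append((int(a), int(b)))
        except ValueError as exc:
            raise CorpusError(f"bad charOffset {value!r}") from exc
    return spans


def format_char_offset(spans: list[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in spans)


# ---------------------------------------------------------------------------
# reading

def _parse_sentence(elem, filename: str) -> SentenceRecord:
    sent = SentenceRecord(id=elem.get("id", ""), text=elem.get("text", ""))
    for ent in elem.findall("entity"):
        sent.mentions.append(EntityMention(
            id=ent.get("id", ""),
            char_spans=parse_char_offset(ent.get("charOffset", "")),
            text=ent.get("text", ""),
            entity_type=ent.get("type", "drug"),
        ))
    for pair in elem.findall("pair"):
        ddi = pair.get("ddi", "false").lower()
        if ddi == "true":
            raw = (pair.get("type") or "").lower()
            if raw not in _TYPE_CANON:
                raise CorpusError(
                    f"{filename}:{pair.sourceline}: pair {pair.get('id')} has "
                    f"ddi='true' but unknown type {pair.get('type')!r}")
            label = _TYPE_CANON[raw]
        else:
            label = NEGATIVE_LABEL
        sent.pairs.append(PairAnnotation(
            id=pair.get("id", ""), e1_id=pair.get("e1", ""),
            e2_id=pair.get("e2", ""), label=label))
    try:
        sent.validate()
    except CorpusError as exc:
        raise CorpusError(f"{filename}:{elem.sourceline}: {exc}") from exc
    return sent


def _read_file(path: Path) -> list[Document]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"{path}: XML parse error: {exc}") from exc
    root = tree.getroot()
    doc_elems = [root] if root.tag == "document" else root.findall("document")
    docs = []
    for de in doc_elems:
        doc = Document(id=de.get("id", path.stem))
        for se in de.findall("sentence"):
            doc.sentences.append(_parse_sentence(se, str(path)))
        doc.validate()
        docs.append(doc)
    return docs


def read_corpus(path: str | os.PathLike) -> list[Document]:
    """Load all documents from an XML file or a directory of ``*.xml`` files."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    files = sorted(p.glob("*.xml")) if p.is_dir() else [p]
    docs: list[Document] = []
    for f in files:
        docs.extend(_read_file(f))
    return docs


# ---------------------------------------------------------------------------
# writing

def _sentence_to_xml(sent: SentenceRecord) -> etree._Element:
    se = etree.Element("sentence", id=sent.id, text=sent.text)
    for m in sent.mentions:
        etree.SubElement(se, "entity", id=m.id,
                         charOffset=format_char_offset(m.char_spans),
                         type=m.entity_type, text=m.text)
    for pr in sent.pairs:
        attrs = {"id": pr.id, "e1": pr.e1_id, "e2": pr.e2_id}
        if pr.label == NEGATIVE_LABEL:
            attrs["ddi"] = "false"
        else:
            attrs["ddi"] = "true"
            attrs["type"] = pr.label.lower()
        etree.SubElement(se, "pair", **attrs)
    return se


def write_corpus(docs: list[Document], path: str | os.PathLike) -> None:
    """Write documents in the same dialect accepted by :func:`read_corpus`.

    A ``*.xml`` path produces a single file (documents wrapped in a ``corpus``
    root element); any other path is treated as a directory and one file per
    document is written into it.
    """
    p = Path(path)
    for d in docs:
        d.validate()
    if p.suffix == ".xml":
        root = etree.Element("corpus")
        for d in docs:
            de = etree.SubElement(root, "document", id=d.id)
            for s in d.sentences:
                de.append(_sentence_to_xml(s))
        p.parent.mkdir(parents=True, exist_ok=True)
        etree.ElementTree(root).write(str(p), pretty_print=True,
                                      xml_declaration=True, encoding="UTF-8")
    else:
        p.mkdir(parents=True, exist_ok=True)
        for d in docs:
            de = etree.Element("document", id=d.id)
            for s in d.sentences:
                de.append(_sentence_to_xml(s))
            etree.ElementTree(de).write(str(p / f"{d.id}.xml"), pretty_print=True,
                                        xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# candidate enumeration

def enumerate_candidates(
    sentence: SentenceRecord,
) -> list[tuple[EntityMention, EntityMention, str]]:
    """All C(m,2) unordered mention pairs, in document order, with labels.

    The label comes from the matching gold pair annotation when one exists;
    unannotated pairs (synthetic/validation mode) default to Negative.
    """
    sentence.validate()
    label_of = {frozenset((p.e1_id, p.e2_id)): p.label for p in sentence.pairs}
    mentions = sorted(sentence.mentions, key=lambda m: (m.start, m.id))
    out = []
    for i in range(len(mentions)):
        for j in range(i + 1, len(mentions)):
            e1, e2 = mentions[i], mentions[j]
            out.append((e1, e2,
                        label_of.get(frozenset((e1.id, e2.id)), NEGATIVE_LABEL)))
    return out
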