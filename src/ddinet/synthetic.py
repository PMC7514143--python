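"""Synthetic DDI-style corpus generation.

Emits labeled corpora in the same XML dialect as the real benchmark so every
other module is testable without the licensed download. Each sentence
instantiates a class-specific template over sampled (invented) drug names;
the class signal is carried by trigger phrases (e.g. Advice: "should not be
coadministered with", Mechanism: "increases the plasma concentration of").
The templates are intentionally easy, so end-to-end learning tests are fast
and stable; ``hard_mode`` adds trigger-phrase overlap between Int and Effect
to mimic the Int→Effect confusion seen on real data. No attempt is made to
match real biomedical language statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    LABELS, NEGATIVE_LABEL, Document, EntityMention, PairAnnotation,
    SentenceRecord,
)
from .preprocess import CandidateInstance, make_candidates

__all__ = ["GeneratorConfig", "generate", "generate_filter_fixtures"]


_PREFIXES = ["ami", "beta", "carbo", "dexa", "erlo", "fluco", "gliben",
             "halo", "ibu", "keto", "lami", "metro", "nife", "oxa", "pheny",
             "quina", "rito", "sulfa", "theo", "vera", "zido", "cime",
             "dilti", "enala", "fosi"]
_MIDDLES = ["", "do", "ra", "ni", "lo", "me", "ti"]
_SUFFIXES = ["zole", "micin", "pril", "sartan", "dipine", "statin", "mab",
             "cillin", "profen", "azepam", "idine", "barbital", "mycin",
             "olol", "oxetine"]

# Templates: {E1}/{E2} are the labeled pair, {EX} an optional distractor.
_TEMPLATES: dict[str, list[str]] = {
    "Advice": [
        "{E1} should not be coadministered with {E2}.",
        "caution is advised when {E1} is combined with {E2}.",
        "concurrent use of {E1} with {E2} is not recommended.",
    ],
    "Effect": [
        "{E1} may potentiate the hypotensive effect of {E2}.",
        "{E1} enhances the sedative action of {E2}.",
        "administration of {E1} increased the risk of bleeding with {E2}.",
    ],
    "Mechanism": [
        "{E1} increases the plasma concentration of {E2}.",
        "{E1} inhibits the hepatic metabolism of {E2}.",
        "{E1} reduces the renal clearance of {E2} by 00 %.",
    ],
    "Int": [
        "a potential interaction of {E1} and {E2} may exist.",
        "{E1} may interact with {E2}.",
    ],
    "Negative": [
        "the pharmacokinetics of {E1} were unchanged in subjects not receiving {E2}.",
        "{E1} was studied separately from {E2} in this trial.",
        "no pharmacokinetic data are available comparing {E1} with {E2}.",
        "{E1} plasma levels were measured before {E2} was introduced.",
    ],
}

_HARD_INT = [
    "{E1} may interact with {E2}, possibly potentiating its effect.",
    "an interaction of {E1} with {E2} may enhance its action.",
]

_DISTRACTOR_SUFFIX = " in patients also receiving {EX}"


@dataclass
class GeneratorConfig:
    """Controls corpus size, the class mix and the sentence shapes.

    ``class_proportions`` follows the canonical label order
    (Advice, Effect, Mechanism, Int, Negative); the default mirrors the
    filtered benchmark training mix (~82% Negative).
    """

    n_sentences: int = 1000
    class_proportions: tuple[float, ...] = (0.04, 0.07, 0.06, 0.01, 0.82)
    lexicon_size: int = 120
    distractor_rate: float = 0.2
    sentences_per_document: int = 10
    hard_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be >= 1")
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != len(LABELS) or np.any(props < 0) or \
                abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be 5 non-negative "
                             "values summing to 1")
        if self.lexicon_size < 3:
            raise ValueError("lexicon_size must be >= 3")
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise ValueError("distractor_rate must lie in [0, 1]")


def _build_lexicon(rng: np.random.Generator, size: int) -> list[str]:
    names: list[str] = []
    seen = set()
    while len(names) < size:
        name = (rng.choice(_PREFIXES) + rng.choice(_MIDDLES)
                + rng.choice(_SUFFIXES))
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


_SLOT_RE = re.compile(r"\{(E1|E2|EX)\}")


def _fill(template: str, names: dict[str, str]):
    """Substitute slots, recording each entity's inclusive character span."""
    text, offsets, prev = "", {}, 0
    for m in _SLOT_RE.finditer(template):
        text += template[prev:m.start()]
        surface = names[m.group(1)]
        offsets[m.group(1)] = (len(text), len(text) + len(surface) - 1)
        text += surface
        prev = m.end()
    text += template[prev:]
    return text, offsets


def generate(cfg: GeneratorConfig) -> list[Document]:
    """Deterministically generate a labeled corpus from the config's seed.

    Every sentence carries at least two entity mentions with exact character
    offsets and a pair annotation labeled by its template class; distractor
    mentions add extra Negative pairs. Sentence-level template labels follow
    ``class_proportions`` multinomially.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lexicon = _build_lexicon(rng, cfg.lexicon_size)
    props = np.asarray(cfg.class_proportions, dtype=float)

    docs: list[Document] = []
    doc: Document | None = None
    for i in range(cfg.n_sentences):
        if i % cfg.sentences_per_document == 0:
            doc = Document(id=f"DDI-SYN.d{i // cfg.sentences_per_document}")
            docs.append(doc)
        label = LABELS[rng.choice(len(LABELS), p=props)]
        pool = list(_TEMPLATES[label])
        if cfg.hard_mode and label == "Int":
            pool += _HARD_INT
        template = pool[rng.integers(len(pool))]
        with_distractor = rng.random() < cfg.distractor_rate
        if with_distractor:
            template = template.rstrip(".") + _DISTRACTOR_SUFFIX + "."
        picks = rng.choice(len(lexicon), size=3, replace=False)
        names = {"E1": lexicon[picks[0]], "E2": lexicon[picks[1]],
                 "EX": lexicon[picks[2]]}
        text, offsets = _fill(template, names)

        sid = f"{doc.id}.s{len(doc.sentences)}"
        sent = SentenceRecord(id=sid, text=text)
        slots = ["E1", "E2"] + (["EX"] if with_distractor else [])
        ent_ids = {}
        for j, slot in enumerate(slots):
            eid = f"{sid}.e{j}"
            ent_ids[slot] = eid
            sent.mentions.append(EntityMention(
                id=eid, char_spans=[offsets[slot]], text=names[slot],
                entity_type="drug"))
        sent.pairs.append(PairAnnotation(
            id=f"{sid}.p0", e1_id=ent_ids["E1"], e2_id=ent_ids["E2"],
            label=label))
        if with_distractor:
            for j, slot in enumerate(("E1", "E2")):
                sent.pairs.append(PairAnnotation(
                    id=f"{sid}.p{j + 1}", e1_id=ent_ids[slot],
                    e2_id=ent_ids["EX"], label=NEGATIVE_LABEL))
        sent.validate()
        doc.sentences.append(sent)
    return docs


# ---------------------------------------------------------------------------
# filtering-rule fixtures

def _sentence(sid: str, text: str, surfaces: list[str],
              label: str) -> SentenceRecord:
    """Build a sentence whose mentions are the given surfaces, in order."""
    sent = SentenceRecord(id=sid, text=text)
    cursor = 0
    for j, surf in enumerate(surfaces):
        start = text.index(surf, cursor)
        sent.mentions.append(EntityMention(
            id=f"{sid}.e{j}", char_spans=[(start, start + len(surf) - 1)],
            text=surf, entity_type="drug"))
        cursor = start + len(surf)
    sent.pairs.append(PairAnnotation(
        id=f"{sid}.p0", e1_id=f"{sid}.e0",
        e2_id=f"{sid}.e{1 if len(surfaces) < 3 else 2}", label=label))
    sent.validate()
    return sent


def generate_filter_fixtures() -> list[tuple[CandidateInstance, str | None]]:
    """Hand-constructed instances exercising each filtering rule exactly once.

    Returns (instance, expected) pairs where ``expected`` is the rule id that
    must remove the instance, or None for matched controls that must survive
    (including a positive instance that matches a rule textually: positives
    are never filtered).
    """
    cases: list[tuple[SentenceRecord, str | None]] = [
        # R1: same name twice
        (_sentence("fx.s0", "alphacillin modifies alphacillin metabolism.",
                   ["alphacillin", "alphacillin"], "Negative"), "R1"),
        # control: different names, plain co-mention
        (_sentence("fx.s1", "alphacillin modifies betamycin metabolism.",
                   ["alphacillin", "betamycin"], "Negative"), None),
        # R1: parenthesized abbreviation
        (_sentence("fx.s2", "acetylsalicylic acid (ASA) was administered.",
                   ["acetylsalicylic acid", "ASA"], "Negative"), "R1"),
        # R2: coordinate structure
        (_sentence("fx.s3", "alphacillin , gammazole and betamycin were "
                            "coadministered with care.",
                   ["alphacillin", "gammazole", "betamycin"], "Negative"), "R2"),
        # control: a content word between the mentions
        (_sentence("fx.s4", "alphacillin strongly inhibits betamycin.",
                   ["alphacillin", "betamycin"], "Negative"), None),
        # R3: one name a strict substring of the other
        (_sentence("fx.s5", "oral betamycin solution contains betamycin.",
                   ["oral betamycin solution", "betamycin"], "Negative"), "R3"),
        # R3: specialization via "such as"
        (_sentence("fx.s6", "enzyme inducers such as gammazole were given.",
                   ["enzyme inducers", "gammazole"], "Negative"), "R3"),
        # control: positive instance matching R2 textually -> retained
        (_sentence("fx.s7", "alphacillin and betamycin interact strongly.",
                   ["alphacillin", "betamycin"], "Int"), None),
    ]
    out = []
    for sent, expected in cases:
        doc = Document(id=sent.id.split(".")[0], sentences=[sent])
        inst = make_candidates([doc])[0]
        out.append((inst, expected))
    return out
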