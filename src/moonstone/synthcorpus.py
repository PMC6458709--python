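"""Seeded generator of clinical-note-like documents with gold annotations.

Real notes for this task are protected health information, so the test
corpus is synthesized.  Each document mixes section headers, neutral
filler prose, and phenomena the extractor must handle: direct statements
("patient lives alone"), statements requiring inference ("family at
bedside"), negations carrying no affirmative label ("he receives no help
from his family"), semi-structured template fields ("HOMELESS:1"),
semantic-role reversals ("the patient helps the wife with medications"),
and ambiguous everyday-word distractors ("medical equipment at the
bedside").  Gold eHOST XML marks exactly the label-bearing spans.

Template families marked ``held_out=True`` recombine the knowledge base's
vocabulary in orderings and contexts that no grammar or word rule was
written against; they probe rule generality rather than memorized strings.
Generation is fully deterministic for a fixed config (including seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .evalbench import REFERENCE_CLASS_ORDER
from .pipeline import ANNOTATOR_ID, RefAnnotation
from .textproc import RawDocument

__all__ = ["SynthConfig", "generate_corpus", "corpus_answer_key", "write_corpus", "gold_to_xml"]

CLASSES = list(REFERENCE_CLASS_ORDER)
NONE_CLASS = "none"


@dataclass
class SynthConfig:
    n_docs: int = 200
    # distribution over the 7 classes plus "none"; uniform by default
    class_mix: dict = field(
        default_factory=lambda: {c: 1.0 / 8.0 for c in CLASSES + [NONE_CLASS]}
    )
    negation_rate: float = 0.3
    template_rate: float = 0.3
    role_reversal_rate: float = 0.2
    distractor_rate: float = 0.5
    seed: int = 1

    def validate(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix sums to {total}, expected 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class_mix probabilities must be non-negative")
        unknown = set(self.class_mix) - set(CLASSES) - {NONE_CLASS}
        if unknown:
            raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
        for name in ("negation_rate", "template_rate", "role_reversal_rate", "distractor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class _Template:
    text: str
    held_out: bool = False


# --- labeled prose templates per class ------------------------------------

_PROSE = {
    "Homeless/marginally housed": [
        _Template("Patient is homeless."),
        _Template("Veteran is currently homeless and staying in a shelter."),
        _Template("Pt is marginally housed."),
        _Template("Patient remains homeless at this time.", held_out=True),
        _Template("Veteran undomiciled, couch surfing with acquaintances.", held_out=True),
    ],
    "Lives at home/not homeless": [
        _Template("pt not homeless"),
        _Template("Patient lives at home."),
        _Template("Discharged to home."),
        _Template("He lives in his own home.", held_out=True),
        _Template("Patient currently living at home without difficulty.", held_out=True),
    ],
    "Lives in a facility": [
        _Template("Patient lives in a nursing home."),
        _Template("He resides at an assisted living facility."),
        _Template("Discharged to skilled nursing facility."),
        _Template("Patient currently residing in a group home.", held_out=True),
        _Template("Veteran stays at a long term care facility.", held_out=True),
    ],
    "Does not live alone": [
        _Template("Patient lives with his daughter."),
        _Template("She lives with her husband."),
        _Template("Grandson currently living with the patient in his apartment."),
        _Template("Patient stays with his brother.", held_out=True),
        _Template("Granddaughter living with the patient for the past year.", held_out=True),
    ],
    "Lives alone": [
        _Template("Patient lives alone."),
        _Template("He lives by himself."),
        _Template("She lives alone."),
        _Template("Veteran is living alone currently.", held_out=True),
        _Template("Pt stays by himself.", held_out=True),
    ],
    "Has social support": [
        _Template("Wife at bedside."),
        _Template("Family at bedside."),
        _Template("Daughter helps the patient with medications."),
        _Template("Patient in phone contact with adult children."),
        _Template("Accompanied to medical appointment by son."),
        _Template("Supportive family."),
        _Template("Neighbor checks on him regularly.", held_out=True),
        _Template("Brought in by daughter today.", held_out=True),
    ],
    "No social support": [
        _Template("He has no help with ADL needs."),
        _Template("No family support."),
        _Template("Patient lacks social support."),
        _Template("Social support: none.", held_out=True),
        _Template("She has no one to help her at home.", held_out=True),
    ],
}

# template-field renderings (text, needs_upper_variant) per class
_FIELDS = {
    "Homeless/marginally housed": ["HOMELESS:1", "homeless:y", "HOMELESS: yes"],
    "Lives at home/not homeless": ["HOMELESS:0", "homeless:n", "HOMELESS: no"],
    "Lives alone": ["LIVES ALONE:y", "lives alone:1", "ALONE: yes"],
    "Does not live alone": ["LIVES ALONE:n", "lives alone:0", "ALONE: no"],
    "Has social support": ["SOCIAL SUPPORT:y", "social support:1"],
    "No social support": ["SOCIAL SUPPORT:n", "social support:0"],
}

_NEGATIONS = [
    "He receives no help from his family.",
    "No family at bedside.",
    "Patient is not living with anyone.",
]

_REVERSALS = [
    "The patient helps the wife with medications.",
    "The patient helps the daughter with the chores.",
    "Pt assists the neighbor with shopping.",
]

_DISTRACTORS = [
    "Medical equipment at the bedside.",
    "Bedside commode in place.",
    "Discharge planning discussed with the team.",
    "The patient reports feeling well.",
    "Ambulating without assistance.",
]

_FILLER = [
    "Vital signs stable.",
    "Medication list reviewed and reconciled.",
    "Follow up in two weeks.",
    "No acute distress.",
    "Labs reviewed.",
    "Continue current regimen.",
]

_HEADERS = ["SOCIAL HISTORY:", "ASSESSMENT:", "HOSPITAL COURSE:", "SOCIAL WORK NOTE:"]


def _draw_class(rng: random.Random, mix: dict) -> str:
    r = rng.random()
    acc = 0.0
    for cls, p in mix.items():
        acc += p
        if r < acc:
            return cls
    return list(mix)[-1]


def generate_corpus(config: SynthConfig):
    """Generate (documents, gold) where *gold* maps doc_id to a list of
    :class:`~moonstone.pipeline.RefAnnotation`."""
    config.validate()
    rng = random.Random(config.seed)
    documents: list[RawDocument] = []
    gold: dict[str, list] = {}
    for i in range(config.n_docs):
        doc_id = f"synth-{i:04d}"
        cls = _draw_class(rng, config.class_mix)
        parts: list[str] = [rng.choice(_HEADERS), ""]
        body: list[tuple[str, Optional[str]]] = []  # (sentence, class or None)
        for _ in range(rng.randint(2, 4)):
            body.append((rng.choice(_FILLER), None))
        if cls != NONE_CLASS:
            if cls in _FIELDS and rng.random() < config.template_rate:
                sentence = rng.choice(_FIELDS[cls])
            else:
                sentence = rng.choice(_PROSE[cls]).text
            body.append((sentence, cls))
        if rng.random() < config.negation_rate:
            body.append((rng.choice(_NEGATIONS), None))
        if rng.random() < config.role_reversal_rate:
            body.append((rng.choice(_REVERSALS), None))
        if rng.random() < config.distractor_rate:
            body.append((rng.choice(_DISTRACTORS), None))
        rng.shuffle(body)

        text_parts = list(parts)
        offset = sum(len(p) + 1 for p in text_parts)
        annotations: list[RefAnnotation] = []
        for sentence, label in body:
            if label is not None:
                annotations.append(
                    RefAnnotation(doc_id, offset, offset + len(sentence), label)
                )
            text_parts.append(sentence)
            offset += len(sentence) + 1
        text = "\n".join(text_parts) + "\n"
        documents.append(RawDocument(doc_id, text))
        gold[doc_id] = annotations
    return documents, gold


def corpus_answer_key(gold: dict) -> dict:
    """Per-class gold annotation counts (order-independent)."""
    counts = {cls: 0 for cls in CLASSES}
    for anns in gold.values():
        for a in anns:
            counts[a.class_label] = counts.get(a.class_label, 0) + 1
    return counts


def gold_to_xml(doc: RawDocument, annotations) -> str:
    """Gold annotations in the same eHOST dialect the pipeline writes."""
    from lxml import etree

    root = etree.Element("annotations", textSource=doc.doc_id)
    for a in sorted(annotations, key=lambda a: (a.start, a.end)):
        el = etree.SubElement(root, "annotation")
        etree.SubElement(el, "span", start=str(a.start), end=str(a.end))
        etree.SubElement(el, "spannedText").text = doc.text[a.start : a.end]
        etree.SubElement(el, "mentionClass").text = a.class_label
        etree.SubElement(el, "annotator").text = "gold"
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def write_corpus(documents, gold, out_dir) -> None:
    """Write text files, gold XML and an answer-key TSV to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in documents:
        (out / f"{doc.doc_id}.txt").write_text(doc.text)
        (out / f"{doc.doc_id}.xml").write_text(gold_to_xml(doc, gold[doc.doc_id]))
    counts = corpus_answer_key(gold)
    lines = ["class\tgold_count"] + [f"{cls}\t{n}" for cls, n in counts.items()]
    (out / "answer_key.tsv").write_text("\n".join(lines) + "\n")
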