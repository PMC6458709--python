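"""Document pipeline: text -> annotations -> eHOST XML / TSV.

``process_document`` runs the full chain — tokenize, sectionize, sentence
split, template-field detection, word-level annotation, negation flagging,
chart parsing, scoring/selection, sentence-level inference, class mapping
and de-duplication — and is deterministic for a fixed (document, KB,
config) triple.

Sentences containing recognized template fields (``HOMELESS:1``) are
treated as structured regions: the field mapping produces the annotation
directly and the grammar is not applied to that sentence.

The XML dialect is Knowtator/eHOST-style: an ``annotations`` root whose
``annotation`` children carry ``span`` (``start``/``end`` attributes,
**0-based half-open** character offsets into the source text),
``spannedText`` and ``mentionClass``.  ``read_ehost_xml`` accepts exactly
what ``write_ehost_xml`` emits, so write -> read is the identity on
(span, class) pairs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from lxml import etree

from . import chartparser as cp
from . import textproc as tp
from . import tsl
from .grammar import KnowledgeBase

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionResult",
    "RefAnnotation",
    "process_document",
    "filter_duplicates",
    "write_ehost_xml",
    "read_ehost_xml",
    "result_to_tsv_rows",
    "TSV_COLUMNS",
    "load_config",
]

ANNOTATOR_ID = "moonstone"
TSV_COLUMNS = ["doc_id", "start", "end", "text", "class", "score", "rule_name", "inferred"]


@dataclass
class ExtractionResult:
    doc_id: str
    annotations: list  # cp.Annotation restricted to target concepts
    classes: dict = field(default_factory=dict)  # annotation uid -> class label
    kb_version: str = ""
    config_hash: str = ""
    truncated_sentences: int = 0

    def labeled(self):
        """(start, end, class_label) triples, sorted by span."""
        return [
            (a.start, a.end, self.classes[a.uid])
            for a in sorted(self.annotations, key=lambda a: (a.start, a.end))
        ]


@dataclass(frozen=True)
class RefAnnotation:
    """A minimal (document, span, class) annotation as read from XML."""

    doc_id: str
    start: int
    end: int
    class_label: str
    flagged: bool = False  # unknown class or span/text mismatch


def load_config(path=None) -> cp.ParserConfig:
    """Parser configuration from a YAML file; omitted keys keep defaults."""
    config = cp.ParserConfig()
    if path is None:
        return config
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in data.items():
        if not hasattr(config, key):
            raise ValueError(f"unknown config key {key!r}")
        setattr(config, key, type(getattr(config, key))(value))
    return config


def _config_hash(config: cp.ParserConfig) -> str:
    text = repr(sorted(vars(config).items()))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def process_document(
    doc: tp.RawDocument,
    kb: KnowledgeBase,
    config: Optional[cp.ParserConfig] = None,
) -> ExtractionResult:
    """Run the full pipeline over one document."""
    config = config or cp.ParserConfig()
    grammar_hosts = cp.build_grammar_hosts()
    inference_hosts = cp.build_inference_hosts(kb.hierarchy)
    tokens = tp.tokenize(doc.text)
    sections = tp.segment_sections(doc, tokens, kb.header_lexicon)
    out: list[cp.Annotation] = []
    classes: dict[int, str] = {}
    truncated = 0
    all_sentence_facts: set = set()

    for section in sections:
        for sentence in tp.split_sentences(section, tokens):
            fields = tp.detect_template_fields(sentence, tokens)
            if fields:
                for f in fields:
                    ann = _template_annotation(f, kb)
                    if ann is not None:
                        out.append(ann)
                        classes[ann.uid] = kb.class_of(ann.summary_constant)
                continue  # structured region: grammar does not apply
            leaves = cp.apply_word_level(sentence, tokens, kb.word_rules)
            if not leaves:
                continue
            for leaf in leaves:
                leaf.negated = cp.detect_negation(
                    sentence,
                    tokens,
                    leaf,
                    kb.negation_pre_triggers,
                    kb.negation_post_triggers,
                    config.negation_scope,
                )
            forest = cp.chart_parse(leaves, kb.grammar_rules, kb.hierarchy, grammar_hosts, config)
            if forest.truncated:
                truncated += 1
            selected = cp.select_interpretations(forest, kb, config)
            augmented = cp.apply_inference_rules(
                selected, forest.annotations, kb.inference_rules, kb.hierarchy, kb, inference_hosts
            )
            if config.cross_sentence:
                all_sentence_facts |= cp.sentence_facts(forest.annotations, kb.hierarchy)
            # keep one annotation per class within a sentence (duplicate
            # mentions of the same conclusion add nothing)
            best_by_class: dict[str, cp.Annotation] = {}
            for a in augmented:
                cls = kb.class_of(a.summary_constant)
                if cls is None:
                    continue
                prev = best_by_class.get(cls)
                if prev is None or (a.score, len(a.token_indices)) > (prev.score, len(prev.token_indices)):
                    best_by_class[cls] = a
            for cls, a in best_by_class.items():
                out.append(a)
                classes[a.uid] = cls

    if config.cross_sentence and all_sentence_facts:
        closure = tsl.forward_chain(all_sentence_facts, kb.inference_rules, inference_hosts)
        present = set(classes.values())
        for fact in sorted(
            (f for f in closure if isinstance(f, tsl.Compound) and f.relation == "concept"),
            key=tsl.to_sexpr,
        ):
            constant = fact.args[0].name
            cls = kb.class_of(constant)
            if cls and cls not in present:
                ann = cp.Annotation(
                    start=0,
                    end=len(doc.text),
                    token_indices=frozenset(range(len(tokens))) or frozenset({0}),
                    summary_constant=constant,
                    rule_name="inference:document",
                    inferred=True,
                    score=1.0,
                )
                out.append(ann)
                classes[ann.uid] = cls
                present.add(cls)

    deduped = filter_duplicates(out, classes)
    return ExtractionResult(
        doc_id=doc.doc_id,
        annotations=deduped,
        classes={a.uid: classes[a.uid] for a in deduped},
        kb_version=kb.version,
        config_hash=_config_hash(config),
        truncated_sentences=truncated,
    )


def _template_annotation(f: tp.TemplateField, kb: KnowledgeBase):
    if f.polarity not in ("affirmed", "negated"):
        return None
    label = f.label.lower()
    for tm in kb.template_mappings:
        if tm.label == label:
            constant = tm.affirmed_constant if f.polarity == "affirmed" else tm.negated_constant
            if constant is None or kb.class_of(constant) is None:
                return None
            return cp.Annotation(
                start=f.span[0],
                end=f.span[1],
                token_indices=frozenset({-f.span[0] - 1}),  # placeholder: outside token space
                summary_constant=constant,
                rule_name=f"template:{label}",
                score=1.0,
            )
    return None


def filter_duplicates(annotations: Sequence, classes: dict) -> list:
    """Collapse annotations identical in (span, class), keeping the best
    score; output sorted by span."""
    best: dict[tuple, cp.Annotation] = {}
    for a in annotations:
        key = (a.start, a.end, classes[a.uid])
        prev = best.get(key)
        if prev is None or a.score > prev.score:
            best[key] = a
    return sorted(best.values(), key=lambda a: (a.start, a.end, classes[a.uid]))


# ---------------------------------------------------------------------------
# eHOST-style XML
# ---------------------------------------------------------------------------


def write_ehost_xml(result: ExtractionResult, doc: tp.RawDocument) -> str:
    """Serialize a result to the frozen eHOST-style dialect (see module
    docstring).  Offsets are 0-based half-open and must lie inside the
    document."""
    root = etree.Element("annotations", textSource=doc.doc_id)
    for a in sorted(result.annotations, key=lambda a: (a.start, a.end)):
        if not (0 <= a.start <= a.end <= len(doc.text)):
            raise ValueError(
                f"annotation span ({a.start}, {a.end}) outside document {doc.doc_id!r}"
            )
        el = etree.SubElement(root, "annotation")
        etree.SubElement(el, "span", start=str(a.start), end=str(a.end))
        etree.SubElement(el, "spannedText").text = doc.text[a.start : a.end]
        etree.SubElement(el, "mentionClass").text = result.classes[a.uid]
        etree.SubElement(el, "annotator").text = ANNOTATOR_ID
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def read_ehost_xml(xml_text: str, doc: tp.RawDocument, known_classes: Sequence[str] = ()):
    """Read annotations back from the writer's dialect.

    Returns (annotations, warnings).  A span whose text differs from the
    recorded spannedText, or an unknown class label, is kept but flagged
    with a warning carrying both strings.
    """
    try:
        root = etree.fromstring(xml_text.encode())
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed annotation XML: {e}") from e
    known = set(known_classes)
    annotations: list[RefAnnotation] = []
    warnings: list[str] = []
    for el in root.findall("annotation"):
        span = el.find("span")
        start, end = int(span.get("start")), int(span.get("end"))
        cls = el.findtext("mentionClass") or ""
        recorded = el.findtext("spannedText") or ""
        if not (0 <= start <= end <= len(doc.text)):
            raise ValueError(f"span ({start}, {end}) outside document {doc.doc_id!r}")
        flagged = False
        actual = doc.text[start:end]
        if actual != recorded:
            warnings.append(
                f"{doc.doc_id}: span ({start}, {end}) text {actual!r} != recorded {recorded!r}"
            )
            flagged = True
        if known and cls not in known:
            warnings.append(f"{doc.doc_id}: unknown class label {cls!r}")
            flagged = True
        annotations.append(RefAnnotation(doc.doc_id, start, end, cls, flagged))
    return annotations, warnings


def result_to_tsv_rows(result: ExtractionResult, doc: tp.RawDocument) -> list:
    rows = []
    for a in result.annotations:
        rows.append(
            {
                "doc_id": result.doc_id,
                "start": a.start,
                "end": a.end,
                "text": doc.text[a.start : a.end],
                "class": result.classes[a.uid],
                "score": round(a.score, 6),
                "rule_name": a.rule_name,
                "inferred": a.inferred,
            }
        )
    return rows
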