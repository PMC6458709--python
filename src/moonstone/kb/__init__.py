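"""Bundled social-risk knowledge base and its canonical sentence suite.

The KB covers three social-risk variables — housing situation, living
alone, social support — mapped onto seven output classes.  Rule content
transcribed from the published rule examples (the spouse word rule, the
friend/family–care–patient support rule, the cohabiting-kin inference
rule) is kept together with vocabulary authored for this artifact
(facility terms, marginal-housing phrases); the mapping from internal
constants to the seven class labels is this implementation's convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .. import grammar as _grammar
from .. import tsl as _tsl

__all__ = ["load_default_kb", "load_kb_dir", "canonical_suite", "SuiteCase", "DATA_DIR"]

DATA_DIR = Path(__file__).parent / "data"


def load_kb_dir(path) -> _grammar.KnowledgeBase:
    """Load a knowledge base from a directory with the standard layout
    (hierarchy.tsl, words.tsl, grammar.tsl, inference.tsl, negation.txt,
    templates.tsl, optional headers.txt)."""
    path = Path(path)
    hierarchy = _tsl.load_type_hierarchy((path / "hierarchy.tsl").read_text())
    word_rules = _grammar.load_word_rules((path / "words.tsl").read_text())
    all_rules = _grammar.load_grammar_rules((path / "grammar.tsl").read_text(), hierarchy)
    inference_rules = _grammar.load_inference_rules((path / "inference.tsl").read_text())
    templates, targets = _grammar.load_templates_and_targets((path / "templates.tsl").read_text())
    pre, post = [], []
    for line in (path / "negation.txt").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, _, phrase = line.partition("\t")
        (pre if kind.strip().upper() == "PRE" else post).append(phrase.strip())
    headers: tuple = ()
    headers_file = path / "headers.txt"
    if headers_file.exists():
        headers = tuple(h.strip() for h in headers_file.read_text().splitlines() if h.strip())
    return _grammar.KnowledgeBase(
        hierarchy=hierarchy,
        word_rules=word_rules,
        grammar_rules=[r for r in all_rules if not r.is_abstract],
        abstract_rules=[r for r in all_rules if r.is_abstract],
        inference_rules=inference_rules,
        negation_pre_triggers=tuple(pre),
        negation_post_triggers=tuple(post),
        template_mappings=templates,
        target_concepts=targets,
        header_lexicon=headers,
        version="socialrisk-1",
    )


def load_default_kb() -> _grammar.KnowledgeBase:
    """Load and validate the bundled social-risk KB."""
    kb = load_kb_dir(DATA_DIR)
    report = _grammar.validate_kb(kb)
    if not report.ok:
        raise _grammar.KBLoadError(f"bundled KB failed validation:\n{report}")
    return kb


@dataclass(frozen=True)
class SuiteCase:
    """One regression sentence: the classes the pipeline must assign (an
    empty tuple means the sentence must yield nothing), plus summary
    constants that must not appear anywhere in the sentence's parse."""

    text: str
    expected_classes: tuple
    forbidden_constants: tuple = ()


_HOMELESS = "Homeless/marginally housed"
_AT_HOME = "Lives at home/not homeless"
_FACILITY = "Lives in a facility"
_NOT_ALONE = "Does not live alone"
_ALONE = "Lives alone"
_SUPPORT = "Has social support"
_NO_SUPPORT = "No social support"


def canonical_suite() -> list:
    """The KB's regression gate: worked sentences with expected classes."""
    return [
        SuiteCase("wife at bedside", (_SUPPORT,)),
        SuiteCase("family at bedside", (_SUPPORT,)),
        SuiteCase("spouse at bedside", (_SUPPORT,)),
        SuiteCase("he receives no help from his family", (), (":POSSIBLE_SUPPORT:",)),
        SuiteCase("the patient lives with his wife at home", (_AT_HOME, _NOT_ALONE)),
        SuiteCase("discharged: home with wife", (_AT_HOME, _NOT_ALONE)),
        SuiteCase("Grandson currently living with the patient in his apartment", (_NOT_ALONE,)),
        SuiteCase("the wife helps the patient with medications", (_SUPPORT,)),
        SuiteCase("the patient helps the wife with medications", ()),
        SuiteCase("he needs no help with ADL", ()),
        SuiteCase("he has no help with ADL needs", (_NO_SUPPORT,)),
        SuiteCase("pt not homeless", (_AT_HOME,)),
        SuiteCase("HOMELESS:1", (_HOMELESS,)),
        SuiteCase("homeless:y", (_HOMELESS,)),
        SuiteCase("medical equipment at the bedside", ()),
        SuiteCase("patient lives alone", (_ALONE,)),
        SuiteCase("patient is homeless", (_HOMELESS,)),
        SuiteCase("patient lives at home", (_AT_HOME,)),
        SuiteCase("patient lives in a nursing home", (_FACILITY,)),
        SuiteCase("discharged to skilled nursing facility", (_FACILITY,)),
        SuiteCase("supportive family", (_SUPPORT,)),
        SuiteCase("no family support", (_NO_SUPPORT,)),
        SuiteCase("patient in phone contact with adult children", (_SUPPORT,)),
        SuiteCase("accompanied to medical appointment by son", (_SUPPORT,)),
    ]
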