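import pytest
from hypothesis import HealthCheck, settings

from moonstone import chartparser as cp
from moonstone import textproc as tp
from moonstone.kb import load_default_kb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kb():
    return load_default_kb()


@pytest.fixture(scope="session")
def config():
    return cp.ParserConfig()


def parse_sentence(text, kb, config=None):
    """Run tokenize -> sentence -> word level -> negation -> chart parse for
    a single-sentence text; returns (tokens, sentence, forest)."""
    config = config or cp.ParserConfig()
    doc = tp.RawDocument("t", text)
    tokens = tp.tokenize(text)
    sections = tp.segment_sections(doc, tokens, kb.header_lexicon)
    sentences = [s for sec in sections for s in tp.split_sentences(sec, tokens)]
    assert len(sentences) == 1, f"expected one sentence in {text!r}"
    sentence = sentences[0]
    leaves = cp.apply_word_level(sentence, tokens, kb.word_rules)
    for leaf in leaves:
        leaf.negated = cp.detect_negation(
            sentence,
            tokens,
            leaf,
            kb.negation_pre_triggers,
            kb.negation_post_triggers,
            config.negation_scope,
        )
    forest = cp.chart_parse(leaves, kb.grammar_rules, kb.hierarchy, config=config)
    return tokens, sentence, forest
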