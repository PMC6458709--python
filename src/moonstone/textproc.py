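"""Document pre-processing: tokens, sections, sentences, template fields.

Clinical notes mix narrative prose with telegraphic one-line statements and
semi-structured template fields ("HOMELESS:1", "homeless:y").  This module
turns raw note text into:

* tokens (words, numbers, punctuation, symbols, newlines) with exact
  0-based half-open character offsets;
* named sections, found from a configurable header lexicon plus a fallback
  rule (line-initial Title-Case or ALL-CAPS phrase ending in ":"), with a
  default ``BODY`` section covering unheaded text;
* sentences, split at sentence-final punctuation and at newlines — in
  telegraphic notes a line without a final period is still one statement,
  so a newline ends the sentence unless the line trails off with a comma
  or hyphen;
* template fields, the minimal LABEL:VALUE pattern with a small
  affirmative/negative value vocabulary.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "RawDocument",
    "Token",
    "SectionSpan",
    "SentenceSpan",
    "TemplateField",
    "tokenize",
    "segment_sections",
    "split_sentences",
    "detect_template_fields",
    "DEFAULT_AFFIRMATIVE_VALUES",
    "DEFAULT_NEGATIVE_VALUES",
]


@dataclass(frozen=True)
class RawDocument:
    doc_id: str
    text: str

    def __post_init__(self):
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int  # half-open
    kind: str  # word | number | punctuation | symbol | newline
    norm: str  # lowercased surface for words; surface otherwise


@dataclass
class SectionSpan:
    header_label: str
    header_span: tuple[int, int]  # empty (i, i) for the default section
    body_span: tuple[int, int]
    token_range: tuple[int, int] = (0, 0)  # half-open indices into the token list


@dataclass
class SentenceSpan:
    span: tuple[int, int]
    token_range: tuple[int, int]  # half-open token indices
    section_label: str


@dataclass(frozen=True)
class TemplateField:
    label: str
    raw_value: str
    polarity: str  # affirmed | negated | unknown
    span: tuple[int, int]


_TOKEN_RE = re.compile(
    r"(?P<word>[A-Za-z]+(?:'[A-Za-z]+)?)|(?P<number>\d+(?:\.\d+)?)|(?P<newline>\n)|(?P<other>\S)"
)

_PUNCT = set(string.punctuation)


def tokenize(text: str) -> list[Token]:
    """Split *text* into word/number/punctuation/symbol/newline tokens.

    Tokens are sorted and non-overlapping; every non-space character is
    covered, so the original text can be reconstructed from token spans
    plus the skipped whitespace.
    """
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        surface = m.group(0)
        if m.lastgroup == "word":
            kind, norm = "word", surface.lower()
        elif m.lastgroup == "number":
            kind, norm = "number", surface
        elif m.lastgroup == "newline":
            kind, norm = "newline", surface
        else:
            kind = "punctuation" if surface in _PUNCT else "symbol"
            norm = surface
        tokens.append(Token(surface, m.start(), m.end(), kind, norm))
    return tokens


# ---------------------------------------------------------------------------
# Sections
# ---------------------------------------------------------------------------

# fallback: a short Title-Case or ALL-CAPS phrase at line start, ending in ":"
# with nothing (or only whitespace) after it on the line
_FALLBACK_HEADER_RE = re.compile(
    r"^(?P<label>[A-Z][A-Za-z/'\- ]{0,60}?)\s*:\s*$"
)


def _normalize_header(label: str) -> str:
    return " ".join(label.lower().split())


def segment_sections(
    doc: RawDocument,
    tokens: Sequence[Token],
    header_lexicon: Sequence[str] = (),
) -> list[SectionSpan]:
    """Group tokens into named sections.

    A line starts a section when its leading text up to a colon matches the
    lexicon (case-insensitive; content may follow the colon on the same
    line), or — fallback — when the whole line is a Title-Case/ALL-CAPS
    phrase ending in a colon.  Text before the first header (or all text,
    if no header matches) falls into a default ``BODY`` section, so the
    sections always partition the tokens.
    """
    text = doc.text
    lexicon = {_normalize_header(h) for h in header_lexicon if h.strip()}
    headers: list[tuple[int, int, str]] = []  # (header_start, header_end, label)
    pos = 0
    for line in text.split("\n"):
        stripped = line.strip()
        start = pos + (len(line) - len(line.lstrip()))
        if ":" in stripped:
            label_part = stripped.split(":", 1)[0].strip()
            if _normalize_header(label_part) in lexicon:
                headers.append((start, start + len(label_part) + 1, label_part))
            else:
                m = _FALLBACK_HEADER_RE.match(stripped)
                if m:
                    label = m.group("label").strip()
                    words = label.split()
                    title_or_caps = all(w[:1].isupper() or w.isupper() for w in words)
                    if 0 < len(words) <= 6 and title_or_caps:
                        headers.append((start, start + len(stripped), label))
        pos += len(line) + 1

    sections: list[SectionSpan] = []
    if not headers or headers[0][0] > 0:
        first = headers[0][0] if headers else len(text)
        sections.append(SectionSpan("BODY", (0, 0), (0, first)))
    for i, (h_start, h_end, label) in enumerate(headers):
        body_end = headers[i + 1][0] if i + 1 < len(headers) else len(text)
        sections.append(SectionSpan(label, (h_start, h_end), (h_end, body_end)))

    # assign token ranges: a token belongs to the section whose
    # [header_start, body_end) range contains its start
    bounds = [(s.header_span[0] if s.header_span[1] > s.header_span[0] else s.body_span[0],
               s.body_span[1]) for s in sections]
    ti = 0
    for sec, (lo, hi) in zip(sections, bounds):
        t0 = ti
        while ti < len(tokens) and tokens[ti].start < hi:
            ti += 1
        sec.token_range = (t0, ti)
    if sections:
        t0, _ = sections[-1].token_range
        sections[-1].token_range = (t0, len(tokens))
    return sections


# ---------------------------------------------------------------------------
# Sentences
# ---------------------------------------------------------------------------

_SENTENCE_FINAL = {".", "!", "?"}


def split_sentences(section: SectionSpan, tokens: Sequence[Token]) -> list[SentenceSpan]:
    """Partition a section's tokens into sentences.

    Boundaries fall after sentence-final punctuation and at newlines;
    a telegraphic line with no final period is one sentence, unless it
    ends in a comma or hyphen (continuation).
    """
    lo, hi = section.token_range
    sentences: list[SentenceSpan] = []
    start = lo
    i = lo
    last_content: Optional[Token] = None
    while i < hi:
        tok = tokens[i]
        boundary = False
        if tok.kind == "punctuation" and tok.surface in _SENTENCE_FINAL:
            boundary = True
        elif tok.kind == "newline":
            if last_content is not None and last_content.surface not in {",", "-"}:
                boundary = True
        if tok.kind != "newline":
            last_content = tok
        i += 1
        if boundary:
            # attach any immediately following newline tokens to this sentence
            while i < hi and tokens[i].kind == "newline":
                i += 1
            sentences.append(_make_sentence(section, tokens, start, i))
            start = i
            last_content = None
    if start < hi:
        sentences.append(_make_sentence(section, tokens, start, hi))
    return [s for s in sentences if s is not None]


def _make_sentence(section, tokens, start, end) -> Optional[SentenceSpan]:
    content = [t for t in tokens[start:end] if t.kind != "newline"]
    if not content:
        # a run of bare newlines still belongs to some sentence to keep the
        # partition property; glue it onto a zero-content sentence
        if end > start:
            span = (tokens[start].start, tokens[end - 1].end)
            return SentenceSpan(span, (start, end), section.header_label)
        return None
    span = (content[0].start, content[-1].end)
    return SentenceSpan(span, (start, end), section.header_label)


# ---------------------------------------------------------------------------
# Template fields
# ---------------------------------------------------------------------------

DEFAULT_AFFIRMATIVE_VALUES = frozenset({"1", "y", "yes", "x", "checked"})
DEFAULT_NEGATIVE_VALUES = frozenset({"0", "n", "no", "denies"})


def detect_template_fields(
    sentence: SentenceSpan,
    tokens: Sequence[Token],
    affirmative: frozenset = DEFAULT_AFFIRMATIVE_VALUES,
    negative: frozenset = DEFAULT_NEGATIVE_VALUES,
) -> list[TemplateField]:
    """Recognize LABEL:VALUE template fields inside one sentence.

    VALUE must come from the affirmative/negative vocabularies (a catch-all
    ``unknown`` polarity is *not* emitted: free text after a colon is
    narrative, not a checkbox).  The label is the run of word tokens
    immediately before the colon (up to 4).
    """
    lo, hi = sentence.token_range
    toks = [t for t in tokens[lo:hi] if t.kind != "newline"]
    fields: list[TemplateField] = []
    for i, tok in enumerate(toks):
        if tok.surface != ":" or i == 0 or i + 1 >= len(toks):
            continue
        value_tok = toks[i + 1]
        if value_tok.kind not in ("word", "number"):
            continue
        value = value_tok.norm
        if value in affirmative:
            polarity = "affirmed"
        elif value in negative:
            polarity = "negated"
        else:
            continue
        # label: contiguous word tokens immediately before the colon
        j = i - 1
        label_toks: list[Token] = []
        while j >= 0 and toks[j].kind == "word" and len(label_toks) < 4:
            label_toks.insert(0, toks[j])
            j -= 1
        if not label_toks:
            continue
        label = " ".join(t.surface for t in label_toks)
        fields.append(
            TemplateField(label, value_tok.surface, polarity, (label_toks[0].start, value_tok.end))
        )
    return fields
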