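# Methods

## Problem and approach

Housing situation, living alone, and social support are recorded almost
exclusively in free-text clinical notes, and much of the evidence is
implicit: "family at bedside" never states that the patient has social
support, it implies it.  String- or regex-matching extractors cannot close
that gap.  This package implements a rule-based extractor built from three
layers:

1. a **semantic grammar** whose categories are domain concepts
   (`:SPOUSE:`, `:PROVISION_OF_CARE:`, `<PERSON>`) rather than syntactic
   parts of speech, applied by an unordered bottom-up chart parser;
2. **TSL**, a typed, function-free first-order logic in which grammar
   rules attach meaning predicates to annotations and inference rules
   derive task conclusions from them (forward and backward chaining);
3. a seven-class output layer mapping internal summary constants to the
   mention classes *Homeless/marginally housed*, *Lives at home/not
   homeless*, *Lives in a facility*, *Does not live alone*, *Lives alone*,
   *Has social support*, *No social support* (three variable groups:
   housing 3, living-alone 2, support 2).

## Text processing

Tokens carry 0-based half-open character offsets and a kind (word, number,
punctuation, symbol, newline); words keep their original surface and a
lowercased normal form.  Section headers are found from a configurable
lexicon plus a fallback (a line-initial Title-Case or ALL-CAPS phrase
ending in a colon at end of line); unheaded text falls into a default
`BODY` section, so sections always partition the tokens.  Clinical prose
is telegraphic — lines frequently lack final punctuation — so a newline
ends a sentence unless the line trails off with a comma or hyphen;
sentence-final punctuation also splits.  Both rules are heuristics chosen
because no detection algorithm for either is standard in this genre.

Semi-structured template fields (`HOMELESS:1`, `homeless:y`) are matched
as LABEL:VALUE token patterns with a small value vocabulary (affirmative:
1, y, yes, x, checked; negative: 0, n, no, denies; both configurable).  A
sentence containing a recognized field is treated as a structured region:
the field's label mapping produces the annotation directly and the grammar
does not run there.  Distinguishing structured from narrative regions is a
genuinely open problem in this genre; this label-driven rule is a minimal,
explicit stand-in.

## Grammar and parsing

A word rule maps one or more phrases to a normalizing constant (e.g.
"husband", "wife", "significant other" → `:SPOUSE:`); matching is
case-insensitive, longest-match, left-to-right.  A grammar rule has a
pattern of constants and/or semantic types, validation tests, a result
constant/type, optional interpretation predicates, a weight in [0, 1],
an ordered flag, and a token window.

The parser is a CYK-flavoured bottom-up closure specialized for sparse
grammars over mostly irrelevant text: a rule may fire on **any**
combination of existing annotations with pairwise-disjoint token sets, in
any order unless the rule is marked ordered, with unknown words freely
intervening, as long as the whole match covers at most *window* tokens
(default 10 — the concrete reading of "close proximity", which is not
otherwise quantified).  Closure is bounded by forbidding duplicate
(rule, child-set) firings and by a per-sentence firing budget (default
5,000; exceeding it flags the sentence and returns the partial forest).
Unordered matching trades precision for recall deliberately; the
validation tests claw precision back.

Validation tests are TSL predicates over positional variables: `?N` binds
the annotation matched by the N-th (1-based) pattern element.  Three host
relations are bound by default: `notneg` / `neg` consult the annotation's
negation flag, and `precedes` compares token positions.  The bundled
support rule — friend/family + care phrase + patient — uses
`(notneg ?2)` so that "he receives no help from his family" cannot match,
and `(precedes ?2 ?3)` so that the care phrase must precede the patient
phrase: "the wife helps the patient with medications" fires, "the patient
helps the wife with medications" does not.  The precedes-test was chosen
over a fully ordered pattern because full left-to-right ordering would
reject the negated sentence on word order alone, making the negation test
unfalsifiable in running text.  Other role-sensitive rules (cohabitation,
discharged-home, home-with-companion, no-care-available) use the ordered
flag directly.

Negation is trigger-and-scope in the NegEx style: a pre-trigger ("no",
"not", "denies", "without", "lacks", ...) negates an annotation starting
within 5 content tokens after it; a post-trigger ("none", "absent")
negates one ending within 5 tokens before it.  Trigger file and scope are
configurable.  Negation flags are computed on word-level annotations,
where the tests consult them.

**Scoring and selection.**  Among alternative parses, each task-relevant
annotation is scored as the product of rule weights along its tree times
`(1 + 0.2)` per task-relevant constant contained — a two-factor criterion
(learned-weight likelihood × prevalence of task concepts) concretized
with all constants in config.  Weights are loadable data, not estimated:
no training corpus ships with the package, so bundled rules default to
0.9 and newly specialized rules to 0.5.  Selection is greedy by
descending score; a candidate is dropped only if its tokens overlap an
already-kept annotation from the *same* variable group, so one sentence
can legitimately yield, say, a housing and a living-alone label from
overlapping spans ("the patient lives with his wife at home").  Ties
break toward larger token coverage, then earlier span, then rule name.

## Inference

After parsing, each sentence contributes a fact set: `(subject C)` for
the earliest person-typed word annotation (a stand-in for grammatical
subjecthood — no syntactic parser is in scope), `(affirmed C)` /
`(negated C)` for every annotation's summary constant, and all ground
interpretation predicates attached by grammar rules.  Forward chaining
runs the bundled inference rules over this set with `isa` bound to
hierarchy subsumption; a derived `(concept :C:)` with a task constant
becomes a new annotation flagged `inferred`, spanning the sentence's
evidence, unless the sentence already carries that class.  This is how
"family at bedside" becomes *Has social support* (bedside presence →
involvement in care → support) and "Grandson currently living with the
patient in his apartment" becomes *Does not live alone* (kin subject +
affirmed cohabitation) even though no grammar rule concludes either.

The logic is deliberately function-free (constants, variables, relations
only), so forward chaining reaches a least fixpoint and terminates.
Backward chaining uses answer tabling (memoized subgoal answers iterated
to fixpoint) and is therefore complete for the language and terminating
under recursive rules; a depth bound (default 32) additionally guards
subgoal nesting and reports truncation.  Negation (`not`) is evaluated
against the stated facts plus host relations — classical negation over
the current fact set, not negation-as-failure over derivable facts.
An optional document-level forward-chaining pass (off by default) pools
all sentence facts before inference.

## Knowledge base

The KB ships as S-expression text files: `hierarchy.tsl` (types, parent
edges, constant membership), `words.tsl`, `grammar.tsl` (including two
domain-neutral abstract rules used by the training operation),
`inference.tsl`, `negation.txt`, `templates.tsl` (field-label mappings
and the seven target concepts), `headers.txt`.  `validate_kb` checks for
undeclared symbols, hierarchy cycles, out-of-range test positions,
unreachable rules (result never consumed, not a target, no interpretation
predicates) and the 3/2/2 class partition; the bundled KB validates
clean and is regression-gated by a canonical suite of 24 worked
sentences, including the negation contrast, the role-reversal contrast,
the has/needs minimal pair and the template forms.  Every bundled grammar
and inference rule is exercised by at least one suite sentence.

**Training.**  `specialize_rule` turns an abstract rule (pattern of broad
types, no result constant) plus a structurally matching parse tree and a
chosen target constant into a concrete task rule whose pattern is the
tree's child constants; tests and window are inherited, the weight starts
at the configured default.  It is exposed as a batch operation over
(tree, constant) pairs; no interactive trainer is included.

## Evaluation workbench

Gold and system annotations (eHOST-style XML; `annotations` root,
`annotation` children with `span start end`, `spannedText`,
`mentionClass`; offsets 0-based half-open) are matched greedily
one-to-one per document and class, largest overlap first, under either
`exact_span` or `any_overlap`.  Metrics are computed in exact rational
arithmetic; the F-score is the harmonic mean of the *unrounded* PPV and
sensitivity.  Display defaults to truncation at two decimals because the
published benchmark panel for this task is consistent with truncation and
not with rounding (79/118 = 0.6694 printed as 0.66).  Mention-level TN is
not derivable from annotation sets, so NPV and accuracy are emitted only
when a TN count is supplied explicitly.

## Synthetic corpus

Real notes for this task are PHI-restricted, so the test corpus is
generated.  Each document combines a section header, 2–4 neutral filler
sentences, at most one label-bearing sentence (prose template or, with
probability `template_rate`, a field rendering where the class has one),
and — independently, at the configured rates — a negation sentence, a
role-reversal sentence, and an ambiguous distractor, in shuffled order.
Negation, reversal and distractor sentences carry no gold label by
construction, which is why raising `negation_rate` can never add gold
affirmative labels.  The default class mix is uniform over the seven
classes plus "none" (1/8 each); defaults are `n_docs=200`,
`negation_rate=0.3`, `template_rate=0.3`, `role_reversal_rate=0.2`,
`distractor_rate=0.5`, chosen once as a balanced stress mix.  Generation
is fully deterministic given the config.

Templates marked *held out* (one to two per class, listed in
`synthcorpus.py`) recombine KB vocabulary in orderings and contexts no
grammar or word rule was written against — e.g. "Veteran is living alone
currently.", "Social support: none.", "Brought in by daughter today." —
so the recovery gate measures rule generality, not memorized strings.
The recovery gate (per-class F ≥ 0.90 on the default corpus, any-overlap)
is an engineering self-consistency target for the generator + KB pair.
What passing it shows: the pipeline's layers compose correctly over the
phenomena the generator emulates.  What it does not show: performance on
real clinical text, whose vocabulary breadth, misspellings, idiosyncratic
abbreviations and section conventions the generator does not model.

## Numerical and design choices

- Character offsets are 0-based half-open everywhere, including the XML.
- Metric display: truncation, 2 decimals (rounding available); exact
  rationals retained.
- Scoring constants (leaf score 1.0, target bonus 0.2), window 10,
  budget 5,000, negation scope 5, backward-chain depth 32 — all in
  `ParserConfig` / rule files, YAML-overridable.
- Degenerate inputs: empty documents yield empty results; a sentence with
  no lexicon hits is skipped; metrics with empty denominators are
  *undefined*, never 0.
- Problem sizes used by the self-checks: 200 synthetic documents, 200
  random logic KBs (≤ 5 constants, ≤ 5 rules), 24 canonical sentences —
  small enough to iterate on quickly, large enough to exercise every rule
  and both chaining engines.

## Known limitations

- No spelling correction, abbreviation expansion, coreference, or full
  syntactic parsing; the "subject" fact is a positional heuristic.
- Rule weights are not learned; the scoring bonus is a fixed constant.
- The bundled vocabulary is US-centric (kinship and housing terms).
- Unordered matching can over-fire on long sentences containing scattered
  trigger words; the window and validation tests bound but do not
  eliminate this.
- The seven-class mapping from internal constants is this package's
  convention; other deployments of this class scheme may bin marginal
  housing or facility terms differently.
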