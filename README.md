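# moonstone

Rule-based clinical NLP for inferring **social risk factors** — housing
situation, living alone, and social support — from free-text clinical
notes.

Much of the evidence for social risk is implicit: "family at bedside"
never says the patient has social support, it implies it; "discharged:
home with wife" implies both a stable home and not living alone.  Keyword
and regex extractors miss these.  This package extracts them with a
three-layer design:

- a **semantic grammar** whose categories are domain concepts
  (`:SPOUSE:`, `:PROVISION_OF_CARE:`, `<PERSON>`), applied by a
  bottom-up chart parser (a CYK variant) that matches rule patterns in
  any word order, with unknown words freely intervening inside a token
  window;
- **TSL**, a typed function-free first-order logic: grammar rules attach
  meaning predicates to annotations, and forward-/backward-chaining
  inference derives task conclusions from them (bedside presence →
  involvement in care → social support);
- a mention classifier over seven classes — *Homeless/marginally
  housed*, *Lives at home/not homeless*, *Lives in a facility*, *Does
  not live alone*, *Lives alone*, *Has social support*, *No social
  support* — written to eHOST-compatible XML or TSV.

Negation is trigger-and-scope ("pt **not** homeless" → *Lives at
home/not homeless*); semantic roles are enforced by validation tests
("the wife helps the patient" yields support, "the patient helps the
wife" yields nothing); semi-structured template fields (`HOMELESS:1`,
`homeless:y`) are mapped directly.  The knowledge base is plain
S-expression text (type hierarchy, word rules, grammar rules, inference
rules, negation triggers, template mappings) and is fully user-editable;
a seeded synthetic note generator with gold annotations makes the whole
stack testable without any restricted clinical data.

Audience: health-informatics researchers extracting social determinants
of health from notes, and anyone needing an inspectable, rule-based
extraction pipeline with logic inference.

## Worked example

```python
from moonstone import RawDocument, load_default_kb, process_document
from moonstone.pipeline import write_ehost_xml

kb = load_default_kb()
doc = RawDocument("note-1", "the patient lives with his wife at home.\nHOMELESS:0\n")
result = process_document(doc, kb)
for start, end, cls in result.labeled():
    print(start, end, repr(doc.text[start:end]), "->", cls)
```

prints

```
4 31 'patient lives with his wife' -> Does not live alone
12 39 'lives with his wife at home' -> Lives at home/not homeless
41 51 'HOMELESS:0' -> Lives at home/not homeless
```

One sentence legitimately yields two classes from different variable
groups (housing and living-alone), each anchored to the sub-span its
rule actually matched; the negated template field maps to *Lives at
home/not homeless*.  `write_ehost_xml(result, doc)` renders the
same annotations as eHOST-style XML with 0-based half-open offsets.

## Command line

```bash
moonstone run --input notes/ --out out/ --format ehost      # annotate a corpus
moonstone validate-kb --kb my_kb/                           # static KB checks (exit 2 on findings)
moonstone eval --gold gold/ --system out/ --match overlap --out report.tsv
moonstone synth --n 200 --seed 1 --out corpus/              # synthetic corpus + gold XML
```

## Knowledge-base format

A KB directory holds `hierarchy.tsl`, `words.tsl`, `grammar.tsl`,
`inference.tsl`, `negation.txt`, `templates.tsl` (plus optional
`headers.txt`).  The canonical examples, transcribed in the bundled KB:

```lisp
; words.tsl — phrases normalized to a constant
(defwords :SPOUSE: <FRIEND_FAMILY> "husband" "wife" "significant other")

; grammar.tsl — kin near a non-negated care phrase directed at the patient
(defrule support-interaction
  (pattern <FRIEND_FAMILY> :PROVISION_OF_CARE: :PATIENT:)
  (tests (notneg ?2) (precedes ?2 ?3))
  (result :POSSIBLE_SUPPORT: <SOCIAL_SUPPORT>)
  (weight 0.9)
  (window 10))

; inference.tsl — kin subject of a cohabitation phrase: not living alone
(definfer cohabiting-family-not-alone
  (if (and (subject ?s) (isa ?s <FRIEND_FAMILY>) (affirmed :LIVES_WITH:)))
  (then (concept :NOT_LIVING_ALONE:)))
```

`?N` in a test binds the annotation matched by the N-th pattern element;
`(notneg ?2)` therefore rejects "he receives no help from his family".

### XML schema (frozen)

```xml
<annotations textSource="note-1">
  <annotation>
    <span start="4" end="31"/>          <!-- 0-based, half-open -->
    <spannedText>patient lives with his wife</spannedText>
    <mentionClass>Does not live alone</mentionClass>
    <annotator>moonstone</annotator>
  </annotation>
</annotations>
```

`read_ehost_xml` accepts exactly this dialect; write → read is the
identity on (span, class) pairs.

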