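; TSL inference rules applied to the sentence-level fact set.
; Facts available per sentence: (subject :C:) for the earliest person
; mention, (affirmed :C:) / (negated :C:) for every annotation summary,
; and the ground interpretation predicates attached by grammar rules.
; (isa x <T>) is a host relation backed by the type hierarchy.

; A friend or family member as sentence subject of a non-negated
; cohabitation phrase: the patient does not live alone
; ("Grandson currently living with the patient in his apartment").
(definfer cohabiting-family-not-alone
  (if (and (subject ?s) (isa ?s <FRIEND_FAMILY>) (affirmed :LIVES_WITH:)))
  (then (concept :NOT_LIVING_ALONE:)))

; kin at the bedside are with the patient, hence involved in care
(definfer bedside-presence-implies-involvement
  (if (and (at-bedside ?p) (isa ?p <FRIEND_FAMILY>)))
  (then (involved-in-care ?p)))

(definfer accompaniment-implies-involvement
  (if (and (accompanies ?p) (isa ?p <FRIEND_FAMILY>)))
  (then (involved-in-care ?p)))

(definfer contact-implies-involvement
  (if (and (in-contact ?p) (isa ?p <FRIEND_FAMILY>)))
  (then (involved-in-care ?p)))

; involvement in the patient's care connotes social support
(definfer involvement-implies-support
  (if (involved-in-care ?p))
  (then (has-support :PATIENT:)))

(definfer support-concept
  (if (has-support :PATIENT:))
  (then (concept :HAVE_SUPPORT:)))
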