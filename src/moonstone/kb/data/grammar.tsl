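; Semantic grammar for the three social-risk variables.
; Positional variables in tests are 1-based: ?2 is the second pattern element.
; Rules are unordered unless (ordered true); "window" is the maximum number
; of tokens a match may cover, the concrete reading of "close proximity".

; A friend, family or church associate near a non-negated phrase connoting
; provision of care directed at the patient.  The (precedes ?2 ?3) test
; carries the semantic role: the care phrase must precede the patient
; phrase, so "the patient helps the wife" yields nothing.
(defrule support-interaction
  (pattern <FRIEND_FAMILY> :PROVISION_OF_CARE: :PATIENT:)
  (tests (notneg ?2) (precedes ?2 ?3))
  (result :POSSIBLE_SUPPORT: <SOCIAL_SUPPORT>)
  (interp (provides-care ?1))
  (weight 0.9)
  (window 10))

(defrule promote-possible-support
  (pattern :POSSIBLE_SUPPORT:)
  (result :HAVE_SUPPORT: <SOCIAL_SUPPORT>)
  (weight 0.9))

; "wife at bedside": presence of kin at the bedside; the support conclusion
; itself is drawn by the inference rules from (at-bedside ...).
(defrule person-at-bedside
  (pattern <FRIEND_FAMILY> :BEDSIDE:)
  (tests (notneg ?1))
  (result :PERSON_AT_BEDSIDE: <SOCIAL_SUPPORT>)
  (interp (at-bedside ?1))
  (weight 0.9)
  (window 8))

(defrule social-contact
  (pattern :CONTACT: <FRIEND_FAMILY>)
  (tests (notneg ?1))
  (result :SOCIAL_CONTACT: <SOCIAL_SUPPORT>)
  (interp (in-contact ?2))
  (weight 0.9)
  (window 10))

(defrule accompanied-by-family
  (pattern :ACCOMPANIED: <FRIEND_FAMILY>)
  (tests (notneg ?1))
  (result :PERSON_ACCOMPANIES: <SOCIAL_SUPPORT>)
  (interp (accompanies ?2))
  (weight 0.9)
  (window 10))

; direct mentions: "supportive family", "good system of support"
(defrule support-direct
  (pattern :SUPPORT_WORD:)
  (tests (notneg ?1))
  (result :HAVE_SUPPORT: <SOCIAL_SUPPORT>)
  (weight 0.9))

(defrule no-support-negated
  (pattern :SUPPORT_WORD:)
  (tests (neg ?1))
  (result :NO_SUPPORT: <SOCIAL_SUPPORT>)
  (weight 0.9))

; "he has no help with ADL needs" — possession of care, negated.  Ordered,
; so "he needs no help with ADL" (no possession verb) stays silent.
(defrule no-care-available
  (pattern :PATIENT: :HAVE: :PROVISION_OF_CARE:)
  (tests (neg ?3))
  (result :NO_SUPPORT: <SOCIAL_SUPPORT>)
  (weight 0.9)
  (ordered true)
  (window 8))

(defrule homeless-direct
  (pattern :HOMELESS_WORD:)
  (tests (notneg ?1))
  (result :HOMELESS: <HOUSING_STATUS>)
  (weight 0.9))

(defrule homeless-negated
  (pattern :HOMELESS_WORD:)
  (tests (neg ?1))
  (result :LIVE_AT_HOME: <HOUSING_STATUS>)
  (weight 0.9))

(defrule resides-at-home
  (pattern :RESIDES: :HOME:)
  (tests (notneg ?1))
  (result :LIVE_AT_HOME: <HOUSING_STATUS>)
  (weight 0.9)
  (window 6))

(defrule cohabit-at-home
  (pattern :LIVES_WITH: :HOME:)
  (tests (notneg ?1))
  (result :LIVE_AT_HOME: <HOUSING_STATUS>)
  (weight 0.9)
  (window 8))

(defrule discharged-home
  (pattern :DISCHARGE: :HOME:)
  (tests (notneg ?2))
  (result :LIVE_AT_HOME: <HOUSING_STATUS>)
  (weight 0.9)
  (ordered true)
  (window 6))

; "discharged: home with wife" -> the companion clause
(defrule home-with-companion
  (pattern :HOME: :WITH: <FRIEND_FAMILY>)
  (tests (notneg ?3))
  (result :NOT_LIVING_ALONE: <LIVING_SITUATION>)
  (weight 0.9)
  (ordered true)
  (window 6))

; "the patient lives with his wife" — patient-first, so that kin-first
; cohabitation statements are left to the inference engine.
(defrule cohabitation
  (pattern :PATIENT: :LIVES_WITH: <FRIEND_FAMILY>)
  (tests (notneg ?2))
  (result :NOT_LIVING_ALONE: <LIVING_SITUATION>)
  (interp (lives-with ?3))
  (weight 0.9)
  (ordered true)
  (window 10))

(defrule lives-alone
  (pattern :RESIDES: :ALONE:)
  (tests (notneg ?1))
  (result :LIVES_ALONE: <LIVING_SITUATION>)
  (weight 0.9)
  (ordered true)
  (window 6))

(defrule resides-in-facility
  (pattern :RESIDES: :FACILITY:)
  (tests (notneg ?1))
  (result :LIVE_IN_FACILITY: <HOUSING_STATUS>)
  (weight 0.9)
  (window 8))

(defrule discharged-to-facility
  (pattern :DISCHARGE: :FACILITY:)
  (tests (notneg ?2))
  (result :LIVE_IN_FACILITY: <HOUSING_STATUS>)
  (weight 0.9)
  (ordered true)
  (window 8))

; Domain-neutral abstract rules used by the training (specialization)
; operation; this inventory is this implementation's own.
(defabstract person-action-person
  (pattern <PERSON> <ACTION> <PERSON>)
  (tests (notneg ?2))
  (window 10))

(defabstract person-action-place
  (pattern <PERSON> <ACTION> <PLACE>)
  (tests (notneg ?2))
  (window 10))
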