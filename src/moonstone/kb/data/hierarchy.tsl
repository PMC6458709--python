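; Semantic type hierarchy for the social-risk knowledge base.
; Types use angle brackets, object constants use colon delimiters.

(deftype <ENTITY>)
(deftype <PERSON> <ENTITY>)
(deftype <FRIEND_FAMILY> <PERSON>)
(deftype <ACTION> <ENTITY>)
(deftype <PLACE> <ENTITY>)
(deftype <SOCIAL_SUPPORT> <ENTITY>)
(deftype <HOUSING_STATUS> <ENTITY>)
(deftype <LIVING_SITUATION> <ENTITY>)

(defconstants <PERSON> :PATIENT:)
(defconstants <FRIEND_FAMILY>
  :SPOUSE: :FAMILY: :CHILD: :GRANDCHILD: :FRIEND: :CHURCH_ASSOCIATE:)

(defconstants <ACTION>
  :PROVISION_OF_CARE: :LIVES_WITH: :RESIDES: :DISCHARGE:
  :HAVE: :CONTACT: :ACCOMPANIED:)

(defconstants <PLACE> :HOME: :FACILITY: :BEDSIDE:)

; instances of social support, including having or lacking a companion
; and having or lacking care
(defconstants <SOCIAL_SUPPORT>
  :HAVE_SUPPORT: :NO_SUPPORT: :POSSIBLE_SUPPORT: :SUPPORT_WORD:
  :PERSON_AT_BEDSIDE: :SOCIAL_CONTACT: :PERSON_ACCOMPANIES:
  :HAVING_COMPANION: :LACKING_COMPANION: :HAVING_CARE: :LACKING_CARE:)

(defconstants <HOUSING_STATUS>
  :HOMELESS: :LIVE_AT_HOME: :LIVE_IN_FACILITY: :HOMELESS_WORD:)

(defconstants <LIVING_SITUATION> :LIVES_ALONE: :NOT_LIVING_ALONE: :ALONE:)

(defconstants <ENTITY> :WITH: :ABSTRACT_MATCH:)
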