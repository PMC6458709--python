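; Word-level grammar rules: surface phrases normalized to object constants.
; Vocabulary is US-healthcare-centric (kinship and housing terms).

(defwords :PATIENT: <PERSON>
  "patient" "pt" "veteran" "vet" "he" "she" "him" "his" "her" "himself" "herself")

(defwords :SPOUSE: <FRIEND_FAMILY>
  "husband" "wife" "spouse" "significant other" "partner" "fiance" "fiancee")

(defwords :FAMILY: <FRIEND_FAMILY>
  "family" "family member" "family members" "relatives" "brother" "sister"
  "mother" "father" "cousin" "aunt" "uncle" "nephew" "niece")

(defwords :CHILD: <FRIEND_FAMILY>
  "son" "daughter" "children" "adult children" "kids" "stepson" "stepdaughter")

(defwords :GRANDCHILD: <FRIEND_FAMILY>
  "grandson" "granddaughter" "grandchild" "grandchildren")

(defwords :FRIEND: <FRIEND_FAMILY>
  "friend" "friends" "neighbor" "neighbors" "roommate" "companion")

(defwords :CHURCH_ASSOCIATE: <FRIEND_FAMILY>
  "church member" "church members" "church friends" "pastor" "church associate")

(defwords :PROVISION_OF_CARE: <ACTION>
  "help" "helps" "helping" "helped" "assist" "assists" "assistance"
  "cares for" "takes care of" "taking care of" "caring for" "looks after")

(defwords :LIVES_WITH: <ACTION>
  "lives with" "living with" "resides with" "residing with" "stays with" "staying with")

(defwords :RESIDES: <ACTION>
  "lives" "living" "resides" "residing" "stays" "staying")

(defwords :DISCHARGE: <ACTION>
  "discharged" "discharge" "discharged to" "d/c")

(defwords :HAVE: <ACTION> "has" "have")

(defwords :CONTACT: <ACTION>
  "phone contact" "in contact" "contact" "visits regularly" "visiting regularly"
  "checks on" "checks in on" "in touch")

(defwords :ACCOMPANIED: <ACTION>
  "accompanied" "accompanied by" "accompanied to" "brought in by" "escorted by")

(defwords :SUPPORT_WORD: <SOCIAL_SUPPORT>
  "support" "social support" "support system" "system of support" "supportive family")

(defwords :HOMELESS_WORD: <HOUSING_STATUS>
  "homeless" "undomiciled" "marginally housed" "shelter" "homeless shelter"
  "couch surfing" "living in his car" "living in her car")

(defwords :ALONE: <LIVING_SITUATION>
  "alone" "by himself" "by herself" "on his own" "on her own")

(defwords :HOME: <PLACE> "home" "own home" "house")

(defwords :FACILITY: <PLACE>
  "nursing home" "assisted living" "assisted living facility"
  "skilled nursing facility" "snf" "group home" "long term care facility"
  "rehab facility" "nursing facility")

(defwords :BEDSIDE: <PLACE> "bedside")

(defwords :WITH: "with")
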