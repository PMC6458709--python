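; Template-field label mappings: (deftemplate "label" AFFIRMED NEGATED)
; and the seven task-relevant target concepts with their output classes.

(deftemplate "homeless" :HOMELESS: :LIVE_AT_HOME:)
(deftemplate "lives alone" :LIVES_ALONE: :NOT_LIVING_ALONE:)
(deftemplate "alone" :LIVES_ALONE: :NOT_LIVING_ALONE:)
(deftemplate "social support" :HAVE_SUPPORT: :NO_SUPPORT:)
(deftemplate "support" :HAVE_SUPPORT: :NO_SUPPORT:)
(deftemplate "lives at home" :LIVE_AT_HOME: nil)

(deftarget :HOMELESS: housing "Homeless/marginally housed")
(deftarget :LIVE_AT_HOME: housing "Lives at home/not homeless")
(deftarget :LIVE_IN_FACILITY: housing "Lives in a facility")
(deftarget :NOT_LIVING_ALONE: living_alone "Does not live alone")
(deftarget :LIVES_ALONE: living_alone "Lives alone")
(deftarget :HAVE_SUPPORT: social_support "Has social support")
(deftarget :NO_SUPPORT: social_support "No social support")
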