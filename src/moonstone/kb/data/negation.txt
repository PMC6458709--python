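PRE	no
PRE	not
PRE	without
PRE	denies
PRE	denied
PRE	lacks
PRE	lacking
PRE	never
PRE	no one
PRE	nobody
POST	none
POST	absent
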