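# Negation rules in the NegEx style: trigger phrases before/after a mention
# negate it when they fall within scope_window tokens and no terminator
# intervenes.  Phrases are matched case-insensitively on word boundaries.
pre_triggers:
  - no evidence of
  - no evidence for
  - no signs of
  - no history of
  - not consistent with
  - rule out
  - ruled out
  - r/o
  - denies
  - negative for
  - without
  - resolved
  - "no"
post_triggers:
  - is ruled out
  - was ruled out
  - has been ruled out
  - is not present
  - not present
  - unlikely
  - has resolved
terminators:
  - but
  - however
  - although
  - though
  - except
  - apart from
  - ";"
  - ":"
scope_window: 6
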