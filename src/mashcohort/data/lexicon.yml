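# Default MASH/NASH keyword lexicon.  Each entry is a regular expression;
# word boundaries are added automatically at match time.  The two acronyms
# are matched case-sensitively so the common words "mash"/"gnash" in prose
# never fire.  Edit or replace this file to tune the detector.
entries:
  - pattern: "NASH"
    label: mash
    case_sensitive: true
  - pattern: "MASH"
    label: mash
    case_sensitive: true
  - pattern: "nonalcoholic steatohepatitis"
    label: mash
  - pattern: "non-alcoholic steatohepatitis"
    label: mash
  - pattern: "metabolic dysfunction-associated steatohepatitis"
    label: mash
  - pattern: "metabolic dysfunction–associated steatohepatitis"
    label: mash
  - pattern: "steatohepatitis"
    label: mash
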