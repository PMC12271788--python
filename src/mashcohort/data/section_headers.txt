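# Full section-header inventory used to terminate an extracted section.
# Case-insensitive regex, one per line, anchored at line starts at match time.
(?:history\s+of\s+present\s+illness|hpi)\s*:
(?:chief\s+complaint|cc)\s*:
subjective\s*:
objective\s*:
(?:physical\s+)?exam(?:ination)?\s*:
medications?\s*:
allergies\s*:
review\s+of\s+systems\s*:
ros\s*:
labs?\s*:
laboratory\s+(?:data|results)\s*:
imaging\s*:
past\s+medical\s+history\s*:
pmh\s*:
social\s+history\s*:
family\s+history\s*:
follow[\s\-]?up\s+instructions\s*:
signature\s*:
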