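# Assessment & Plan header patterns, tried in order; case-insensitive regex,
# one per line.  The last occurrence of the first matching pattern anchors
# the section (A&P conventionally ends a note).
\bassessment\s+(?:and|&)\s+plan\b\s*[:\-]?
\ba\s*&\s*p\b\s*[:\-]?
\bimpression\s+and\s+plan\b\s*[:\-]?
\bassessment\s*:
\bimpression\s*:
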