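# Default cirrhosis ICD-10 code list; one code per line, trailing * is a
# prefix wildcard.  Editable default — replace with a site-specific list.
K74.6*
K74.3
K74.4
K74.5
K70.30
K70.31
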