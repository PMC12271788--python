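# Default hepatic-decompensation ICD-10 code list (ascites, encephalopathy,
# varices, hepatorenal syndrome, SBP); prefix wildcards with trailing *.
R18.8
K72.90
K72.91
I85.0*
I85.1*
K76.7
K65.2
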