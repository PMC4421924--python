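# sources: HR,MTM,CSP
pattern,count
111,41
110,259
101,35
100,146
011,2
010,26
001,3
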