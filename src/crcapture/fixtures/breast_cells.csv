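# sources: HR,MTM,CSP
pattern,count
111,108
110,373
101,89
100,159
011,8
010,48
001,2
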