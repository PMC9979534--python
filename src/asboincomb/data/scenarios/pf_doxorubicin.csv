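# pf_doxorubicin: true DLT probabilities
# rows = PF-03084014 levels 1..2 (top to bottom), columns = doxorubicin levels 1..3
0.08,0.13,0.36
0.22,0.33,0.67
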