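# s06: true DLT probabilities
# rows = agent 2 levels 1..3 (top to bottom), columns = agent 1 levels 1..5
0.05,0.08,0.1,0.13,0.15
0.09,0.12,0.15,0.3,0.45
0.15,0.3,0.45,0.5,0.6
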