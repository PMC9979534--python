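# s09: true DLT probabilities
# rows = agent 2 levels 1..3 (top to bottom), columns = agent 1 levels 1..5
0.005,0.01,0.02,0.04,0.07
0.02,0.05,0.08,0.12,0.15
0.15,0.3,0.45,0.55,0.65
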