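# s02: true DLT probabilities
# rows = agent 2 levels 1..3 (top to bottom), columns = agent 1 levels 1..5
0.15,0.3,0.45,0.5,0.6
0.3,0.45,0.5,0.6,0.75
0.45,0.55,0.6,0.7,0.8
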