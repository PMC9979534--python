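# s05: true DLT probabilities
# rows = agent 2 levels 1..3 (top to bottom), columns = agent 1 levels 1..5
0.01,0.02,0.08,0.1,0.11
0.03,0.05,0.1,0.13,0.15
0.07,0.09,0.12,0.15,0.3
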