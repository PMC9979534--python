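{
 "name": "s03",
 "phi": 0.3,
 "agent1": "agent 1",
 "agent2": "agent 2",
 "mtdc": [
  [
   5,
   1
  ],
  [
   4,
   2
  ],
  [
   3,
   3
  ]
 ],
 "description": "Realistic two-agent toxicity scenario on a 5x3 grid, target DLT rate 0.3."
}
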