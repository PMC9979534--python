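{
 "name": "pf_doxorubicin",
 "phi": 0.33,
 "agent1": "doxorubicin",
 "agent2": "PF-03084014",
 "mtdc": [
  [
   2,
   2
  ]
 ],
 "description": "Logistic-regression toxicity estimates for PF-03084014 combined with doxorubicin in advanced triple-negative breast cancer; target DLT rate 0.33."
}
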