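name: arabinose
states: [x1, x2]
inputs: [u]
notes: >
  L-arabinose feedforward module: x1 is the transcription factor AraC
  (basal production c1 plus CRP-driven sigmoidal activation), x2 the output
  protein araBAD, activated sigmoidally by CRP (input u) and increasingly
  by AraC.  Hierarchical: x1 is unaffected by x2.
terms:
  - {name: c1, target: x1, kind: c, tag: positive-constant}
  - {name: c1u, target: x1, kind: c, arg: u, tag: sigmoidal}
  - {name: b11, target: x1, kind: b, mult: x1, tag: positive-constant}
  - {name: c2u1, target: x2, kind: c, arg: u, tag: sigmoidal,
     modulators: [{arg: x1, tag: increasing-asymptotically-constant}]}
  - {name: b22, target: x2, kind: b, mult: x2, tag: positive-constant}
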