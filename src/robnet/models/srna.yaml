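name: srna
states: [x1, x2]
inputs: []
notes: >
  Small-RNA silencing module: x1 is the target mRNA, x2 the sRNA.  Both are
  transcribed at constant rates and turned over linearly; binding produces
  an inactive complex, depleting one molecule of each species, with a
  mass-action rate shared by the two coupled conversion terms
  (b12 * x2 = b21 * x1 at all states).
terms:
  - {name: c1, target: x1, kind: c, tag: positive-constant}
  - {name: c2, target: x2, kind: c, tag: positive-constant}
  - {name: b11, target: x1, kind: b, mult: x1, tag: positive-constant}
  - {name: b22, target: x2, kind: b, mult: x2, tag: positive-constant}
  - {name: b12, target: x1, kind: b, mult: x2, arg: x1, coupling: k,
     tag: increasing-asymptotically-unbounded}
  - {name: b21, target: x2, kind: b, mult: x1, arg: x2, coupling: k,
     tag: increasing-asymptotically-unbounded}
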