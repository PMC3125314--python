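name: lac
states: [x1, x2, x3]
inputs: [u]
notes: >
  Reduced lac operon model: x1 nonfunctional permease (produced at a
  basal-plus-cooperative rate from internal inducer x3), x2 functional
  permease (maturation from x1), x3 internal inducer, imported by the
  permease at a rate saturating in external inducer u (a32) and consumed /
  effluxed by the permease at a rate saturating in x3 (b32).  The
  beta-galactosidase readout x4 = gamma*f1(x3*)/delta4 is slaved to x3 and
  is not a state.
terms:
  - {name: c13, target: x1, kind: c, arg: x3, tag: constant-sigmoidal}
  - {name: b11, target: x1, kind: b, mult: x1, tag: positive-constant}
  - {name: a21, target: x2, kind: a, mult: x1, tag: positive-constant}
  - {name: b22, target: x2, kind: b, mult: x2, tag: positive-constant}
  - {name: a32, target: x3, kind: a, mult: x2, arg: u,
     tag: increasing-asymptotically-constant}
  - {name: b32, target: x3, kind: b, mult: x2, arg: x3,
     tag: increasing-asymptotically-constant}
  - {name: b33, target: x3, kind: b, mult: x3, tag: positive-constant}
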