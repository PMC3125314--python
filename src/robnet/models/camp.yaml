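name: camp
states: [x1, x2, x3]
inputs: [u]
notes: >
  Simplified cAMP/PKA signaling module: x1 is active G protein (activated
  by glucose input u, with activation vanishing at the total amount
  theta1 = G_tot), x2 active PKA (activated by cAMP x3, vanishing at
  theta2 = PKA_tot), x3 cAMP.  cAMP production (d32 basal plus a31 driven
  by active G protein) is inhibited by PKA; degradation is carried by two
  phosphodiesterase routes, one proportional to PKA (b32) and one
  saturating in cAMP itself (b33).
terms:
  - {name: a1u, target: x1, kind: a, mult: u, arg: x1,
     tag: decreasing-exactly-null}
  - {name: b11, target: x1, kind: b, mult: x1, tag: positive-constant}
  - {name: a23, target: x2, kind: a, mult: x3, arg: x2,
     tag: decreasing-exactly-null}
  - {name: b22, target: x2, kind: b, mult: x2, tag: positive-constant}
  - {name: d32, target: x3, kind: d, arg: x2,
     tag: decreasing-asymptotically-null}
  - {name: a31, target: x3, kind: a, mult: x1, arg: x2,
     tag: decreasing-asymptotically-null}
  - {name: b32, target: x3, kind: b, mult: x2, arg: x3,
     tag: increasing-asymptotically-constant}
  - {name: b33, target: x3, kind: b, saturating_flux: true, arg: x3,
     tag: increasing-asymptotically-constant}
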