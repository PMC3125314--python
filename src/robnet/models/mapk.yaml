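name: mapk
states: [x1, x2, x4, x5, x7]
inputs: []
notes: >
  Reduced MAPK cascade: the conserved sums x2+x3+x4 = k and x5+x6+x7 = h
  eliminate the mono-phosphorylated forms, x3 = k - x2 - x4 and
  x6 = h - x5 - x7 (affine arguments below; k and h are instance
  constants).  Same term structure and couplings as the full model.
  An equilibrium requires the basal input c10 to stay below the ceiling of
  the saturating MAP3K turnover flux b11.
terms:
  - {name: c10, target: x1, kind: c, tag: positive-constant}
  - {name: a17, target: x1, kind: a, mult: x7, arg: x1, family: constant,
     tag: nonnegative-constant}
  - {name: b11, target: x1, kind: b, saturating_flux: true, arg: x1,
     tag: increasing-asymptotically-constant}

  - {name: c23, target: x2, kind: c, arg: {total: k, minus: [x2, x4]},
     coupling: g1, tag: increasing-asymptotically-constant}
  - {name: b21, target: x2, kind: b, mult: x1, arg: x2, coupling: e1,
     tag: increasing-asymptotically-constant}

  - {name: a41, target: x4, kind: a, mult: x1,
     arg: {total: k, minus: [x2, x4]}, coupling: e2,
     tag: increasing-asymptotically-constant}
  - {name: b44, target: x4, kind: b, saturating_flux: true, arg: x4,
     coupling: g2, tag: increasing-asymptotically-constant}

  - {name: c56, target: x5, kind: c, arg: {total: h, minus: [x5, x7]},
     coupling: g3, tag: increasing-asymptotically-constant}
  - {name: b54, target: x5, kind: b, mult: x4, arg: x5, coupling: e3,
     tag: increasing-asymptotically-constant}

  - {name: a74, target: x7, kind: a, mult: x4,
     arg: {total: h, minus: [x5, x7]}, coupling: e4,
     tag: increasing-asymptotically-constant}
  - {name: b77, target: x7, kind: b, saturating_flux: true, arg: x7,
     coupling: g4, tag: increasing-asymptotically-constant}
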