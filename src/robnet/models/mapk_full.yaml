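name: mapk_full
states: [x1, x2, x3, x4, x5, x6, x7]
inputs: []
notes: >
  Three-tier MAPK cascade with positive feedback, full coordinates.
  x1 = MAP3K (Mos); x2/x3/x4 = un-, mono-, bis-phosphorylated MAP2K (MEK);
  x5/x6/x7 = un-, mono-, bis-phosphorylated MAPK (p42).  Every
  phosphorylation flux is Michaelis-Menten in the substrate and linear in
  the kinase (x1 for the MEK tier, x4 for the p42 tier); every
  dephosphorylation flux is Michaelis-Menten.  Coupled term pairs encode
  that one reaction's outflow is another's inflow, which makes
  x2+x3+x4 and x5+x6+x7 conserved.  The feedback term mu*a17(x1)*x7
  (doubly phosphorylated MAPK promoting MAP3K synthesis) closes the loop;
  its family is swapped to probe constant / bounded-increasing /
  unbounded-increasing feedback.  c10 is the basal MAP3K input.
terms:
  - {name: c10, target: x1, kind: c, tag: positive-constant}
  - {name: a17, target: x1, kind: a, mult: x7, arg: x1, family: constant,
     tag: nonnegative-constant}
  - {name: b11, target: x1, kind: b, saturating_flux: true, arg: x1,
     tag: increasing-asymptotically-constant}

  - {name: c23, target: x2, kind: c, arg: x3, coupling: g1,
     tag: increasing-asymptotically-constant}
  - {name: b21, target: x2, kind: b, mult: x1, arg: x2, coupling: e1,
     tag: increasing-asymptotically-constant}

  - {name: a31, target: x3, kind: a, mult: x1, arg: x2, coupling: e1,
     tag: increasing-asymptotically-constant}
  - {name: c34, target: x3, kind: c, arg: x4, coupling: g2,
     tag: increasing-asymptotically-constant}
  - {name: b31, target: x3, kind: b, mult: x1, arg: x3, coupling: e2,
     tag: increasing-asymptotically-constant}
  - {name: b33, target: x3, kind: b, saturating_flux: true, arg: x3,
     coupling: g1, tag: increasing-asymptotically-constant}

  - {name: a41, target: x4, kind: a, mult: x1, arg: x3, coupling: e2,
     tag: increasing-asymptotically-constant}
  - {name: b44, target: x4, kind: b, saturating_flux: true, arg: x4,
     coupling: g2, tag: increasing-asymptotically-constant}

  - {name: c56, target: x5, kind: c, arg: x6, coupling: g3,
     tag: increasing-asymptotically-constant}
  - {name: b54, target: x5, kind: b, mult: x4, arg: x5, coupling: e3,
     tag: increasing-asymptotically-constant}

  - {name: a64, target: x6, kind: a, mult: x4, arg: x5, coupling: e3,
     tag: increasing-asymptotically-constant}
  - {name: c67, target: x6, kind: c, arg: x7, coupling: g4,
     tag: increasing-asymptotically-constant}
  - {name: b64, target: x6, kind: b, mult: x4, arg: x6, coupling: e4,
     tag: increasing-asymptotically-constant}
  - {name: b66, target: x6, kind: b, saturating_flux: true, arg: x6,
     coupling: g3, tag: increasing-asymptotically-constant}

  - {name: a74, target: x7, kind: a, mult: x4, arg: x6, coupling: e4,
     tag: increasing-asymptotically-constant}
  - {name: b77, target: x7, kind: b, saturating_flux: true, arg: x7,
     coupling: g4, tag: increasing-asymptotically-constant}
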