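# Ideal peptide covalent geometry (Engh/Huber-style standard values) used
# by the synthetic scaffold builder and backbone hydrogen placement.
bonds:
  N-CA: 1.458
  CA-C: 1.525
  C-N: 1.329
  C-O: 1.231
  N-H: 1.010
angles:
  N-CA-C: 111.0
  CA-C-N: 116.6
  C-N-CA: 121.7
  CA-C-O: 120.8
omega: 180.0
phi_psi:
  helix: [-57.0, -47.0]
  strand: [-139.0, 135.0]
backbone_charges:
  N: -0.35
  H: 0.25
  CA: 0.10
  C: 0.55
  O: -0.55
backbone_charges_pro:
  N: -0.20
  CA: 0.10
  C: 0.55
  O: -0.55
backbone_classes:
  N: N
  H: H
  CA: CT1
  C: C
  O: O
backbone_classes_gly:
  CA: CT2
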