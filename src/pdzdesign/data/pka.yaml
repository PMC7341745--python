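# EMBOSS-style side-chain and terminal pKa values for Henderson-Hasselbalch
# net-charge and isoelectric-point estimates.
acidic:
  C: 8.5
  D: 3.9
  E: 4.1
  Y: 10.1
basic:
  H: 6.5
  K: 10.8
  R: 12.5
n_terminus: 8.6
c_terminus: 3.6
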