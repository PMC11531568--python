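# Van der Waals radii (Å) by element, Bondi set with common extensions.
# Used for AV clash tests and Shrake-Rupley accessible-surface areas.
default: 1.70
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  P: 1.80
  S: 1.80
  CL: 1.75
  BR: 1.85
  I: 1.98
  SE: 1.90
  ZN: 1.39
  FE: 1.40
  MG: 1.73
  CA: 1.73
  NA: 2.27
  K: 2.75
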