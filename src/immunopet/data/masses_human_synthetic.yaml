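# Synthetic/placeholder adult-male organ-mass table (reference-man-style
# magnitudes, 70 kg total). Non-authoritative: supplied only so the
# mass-scaling formalism has a working default.
species: human
total_body_kg: 70.0
organ_masses_kg:
  liver: 1.80
  spleen: 0.150
  kidneys: 0.310
  lung: 1.20
  heart: 0.330
  red_marrow: 1.17
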