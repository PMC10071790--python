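# Synthetic/placeholder rabbit organ-mass table (literature-style magnitudes
# for a ~3 kg New Zealand White rabbit). Non-authoritative: supplied only so
# the mass-scaling formalism has a working default; replace with measured
# masses for any real analysis.
species: rabbit
total_body_kg: 3.0
organ_masses_kg:
  liver: 0.090
  spleen: 0.0012
  kidneys: 0.018
  lung: 0.018
  heart: 0.0075
  red_marrow: 0.045
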