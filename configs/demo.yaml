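# Demo study: 20-mer thymine strand on a 100-molecule Alq3 cluster,
# thymine-like interaction schedule, noise-free geometry.
scenario:
  n_alq3: 100
  sequence: "TTTTTTTTTTTTTTTTTTTT"
  fractions:
    TypeI: 0.04
    TypeII: 0.02
    HbondOnly: 0.06
    PiOnly: 0.88
  noise_sd: 0.0
  n_frames: 200
  dt: 2.0
  seed: 1
analysis:
  stacking_cutoff: 0.45
  hbond_distance_cutoff: 0.35
  hbond_angle_cutoff: 30.0
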