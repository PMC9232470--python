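# Default synthetic cohort: two groups (aperture angles 20 / 45 degrees),
# staircase-calibrated coherence levels, and generative condition effects
# emulating the observed pattern (lower drift for congruent double sources,
# lower threshold for incongruent double sources).
n_per_group: 20
group_angles: [20, 45]
c_low: 0.15
c_high: 0.20
group_means:
  v:   {CON: 0.85, CON_BSL: 1.05, INC: 0.70, INC_BSL: 0.70}
  a:   {CON: 1.60, CON_BSL: 1.60, INC: 1.45, INC_BSL: 1.60}
  ter: {CON: 0.35, CON_BSL: 0.35, INC: 0.35, INC_BSL: 0.35}
group_sds: {v: 0.30, a: 0.20, ter: 0.05}
drift_gain: 5.0
t_max: 4.0
dt: 0.001
seed: 7
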