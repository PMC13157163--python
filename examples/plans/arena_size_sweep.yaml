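arena:
  coral_radius: 0.15
  height: 4.0
  n_corals: 25
  seed: null
  t_max: 45.0
  v_max: 0.5
  walls_are_boundaries: true
  width: 4.0
mode: rate
n_environments: 5
noise_sigma: 0.1
population_scale: 1.0
rate_scale: 1.0
repeats: 1
seed: 0
strategies:
- hp
sweep: arena
sweep_values:
- 2
- 4
- 6
- 8
- 10
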