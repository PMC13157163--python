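# fishnav

Goal-directed underwater navigation without place or grid cells.

Electrophysiology in the goldfish telencephalon suggests that fish
navigate using **boundary vector cells (BVCs)** — neurons whose firing
falls off with distance to environmental boundaries along a preferred
egocentric direction — together with **hydrostatic pressure (HP)** as a
one-dimensional depth cue, rather than the place/grid-cell machinery of
the mammalian hippocampal formation. `fishnav` is a simulator for that
hypothesis: a virtual fish crosses a coral-strewn arena steered only by
boundary signals, a depth cue, and a fixed initial directional prior,
with its kinematic signals carried by a minimal spiking
population-coding (NEF-style) substrate at the low firing rates
(0.1–4 spikes/s) and small population sizes observed in vivo.

## The model in brief

The agent's velocity is `v(t) = s(t)·[cos θ(t), sin θ(t)]`. Each 1 ms
step:

* a 24-bin egocentric ray-cast (Δθ = 15°, range 1.4 m) measures
  distances `d_i` to coral surfaces and arena walls; a coral of radius
  `r` at distance `d` subtends the aperture `2·arctan(r/d)`;
* the forward distance `d₀` drives the speed law: inside the critical
  distance `D = 0.4 m` speed scales by the relative distance
  `d̂ = (d₀ − ε)/(D − ε)` (safety distance `ε = 0.03 m`), otherwise the
  agent accelerates back to `v_max = 0.5 m/s`;
* when blocked (`d₀ < D`) a winner-take-all over the filtered frontal
  clearances picks the clearest direction and the steering angle blends
  `θ_steer = 0.9·θ_new + 0.1·θ_old`;
* strategies differ only in the heading prior: **null** (random within
  ±45° of the true bearing), **azimuth** (true initial bearing), **hp**
  (climb/dive at ±π/2 until `|P_z − G_z| < 0.2 m`, then swim along the
  fixed binary prior `θ_HP ∈ {0, π}`), plus the **hp_max** (400 spikes/s
  LIF, 10× neurons) and **hp_default** (generic tuning) controls;
* within `r_vis = 0.3 m` of the target, the goal attractor
  `G = g − p` drives a direct final approach; velocity and heading track
  their commands through first-order `τ₂ = 100 ms` dynamics.

Trials are scored by reached flag, normalized time and distance, and
collision rate, combined as
`score = reached · [(1−time) + (1−dist) + (1−coll)]/3 ∈ [0, 1]`.
An A* planner (octile-cost 8-connected grid, 0.05 m cells) provides the
classical baseline in global-map and local-sensing (1.4 m, 20 Hz
replanning) modes.

## Worked example

```sh
python examples/run_single_trial.py
```

```
start [ 0.53 -1.54] -> target [-1.15  0.27]
reached:        True
time to target: 6.24 s (normalized 0.033)
path length:    2.61 m (normalized 0.007)
collision rate: 0.0000
total score:    0.987
```

The HP agent climbs to the target depth, then sweeps horizontally along
its fixed prior until the goal attractor captures it; 6.2 s against a
straight-line optimum of 4.9 s and a near-direct, collision-free path
give a score close to 1. Other example scripts cover
strategy comparison (`compare_strategies.py`), the planner baseline
(`astar_comparison.py`), trajectory repeatability via dynamic time
warping (`trajectory_similarity.py`), and the neural tuning
distributions (`tuning_distributions.py`). A thin CLI wraps the same
library calls: `fishnav run|astar|sweep|stats --help`; scaled-down plan
files for the published sweeps (obstacle count, arena size, population,
rate, noise) live in `examples/plans/` and run via
`fishnav sweep --plan examples/plans/complexity_sweep.yaml`.

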