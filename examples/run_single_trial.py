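"""Run one hydrostatic-pressure navigation trial and score it.

Builds a seeded 4x4 m arena with 25 corals, runs the HP strategy in
deterministic rate mode at the sigma=0.1 noise condition, and prints the
normalized trial metrics. A total score near 1 means the agent reached
the target quickly, directly, and without collisions.
"""

import numpy as np

from fishnav import ArenaConfig, ControlParams, generate_environment, run_trial

env = generate_environment(ArenaConfig(n_corals=25), seed=3)
params = ControlParams(noise_sigma=0.1)
traj, res = run_trial(env, "hp", params, mode="rate", seed=3)

print(f"start {np.round(env.start, 2)} -> target {np.round(env.target, 2)}")
print(f"reached:        {bool(res.reached)}")
if res.reached:
    print(f"time to target: {res.t_reach:.2f} s (normalized {res.time_norm:.3f})")
    print(f"path length:    {traj.path_length:.2f} m (normalized {res.dist_norm:.3f})")
print(f"collision rate: {res.collision_rate:.4f}")
print(f"total score:    {res.total_score:.3f}")
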