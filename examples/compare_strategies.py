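"""Compare navigation strategies across seeded environments.

Runs the null (random +-45 deg initial heading), azimuth (true initial
bearing) and HP (target depth + fixed binary horizontal prior)
strategies on the same 8 arenas and prints success rates and scores.
The HP strategy should dominate: the depth cue collapses the search to
one dimension, so detours around corals do not make it miss the target.
"""

from fishnav import ArenaConfig, ExperimentPlan, run_batch
from fishnav.metrics_stats import cohens_d, summarize_results

plan = ExperimentPlan(
    n_environments=8,
    strategies=("null", "azimuth", "hp"),
    arena=ArenaConfig(n_corals=25),
    noise_sigma=0.1,
    seed=0,
)
table = run_batch(plan, progress=True)
print()
print(summarize_results(table).to_string(index=False))

hp = table[table.strategy == "hp"].sort_values("env")["score"].to_numpy()
null = table[table.strategy == "null"].sort_values("env")["score"].to_numpy()
print(f"\nCohen's d (HP vs null, total score): {cohens_d(hp, null):.2f}")
print("d > 0.8 is conventionally a large effect.")
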