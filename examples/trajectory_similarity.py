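"""Inter-trajectory similarity (power analysis) of repeated trials.

Repeats one environment 6 times with the null and HP strategies and
computes all pairwise dynamic-time-warping distances between the
resampled routes (15 pairs per strategy here; the full protocol uses 10
repeats = 45 pairs). Small distances mean the strategy reproduces the
same route; the HP depth program is far more repeatable than a random
initial heading.
"""

from fishnav.experiments import run_power_analysis

out = run_power_analysis(strategies=("null", "hp"), repeats=6, seed=0)
for kind, dists in out.items():
    print(
        f"{kind:8s} n_pairs={len(dists):2d} "
        f"mean={dists.mean():8.2f}  sd={dists.std():7.2f}"
    )
print("\nlower mean distance = more mutually similar trajectories")
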