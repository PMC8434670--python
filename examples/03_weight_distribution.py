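"""Predict the batch weight distribution in 5-kg bins.

Body weight follows a Gompertz curve in accumulated intake; each entry
subgroup is a Normal component (cubic-polynomial variance in weeks since
entry) and the batch distribution is their head-count-weighted mixture —
the table a farmer uses to plan deliveries to the abattoir.
"""

from silogrowth import ScenarioConfig, merge_and_bin, process_batch, simulate
from silogrowth.growth import subgroup_distributions

sim = simulate(ScenarioConfig(seed=42))
res = process_batch(sim.series, sim.batch)

week = len(res.intake.week) - 1
comps = subgroup_distributions(res.intake, sim.batch, week)
dist = merge_and_bin(comps, bin_width=5.0)

print(f"week {week}: {len(comps)} entry subgroup(s)")
for c in comps:
    print(f"  subgroup {c.entry_index}: mean {c.mean:.1f} kg, "
          f"sd {c.variance ** 0.5:.1f} kg, {c.n_alive:.0f} animals")
print(f"\nexpected animals per 5-kg range (total {dist.total_count():.1f}):")
for low, high, count in dist.bins:
    if count >= 0.5:
        print(f"  [{low:5.0f}, {high:5.0f}) kg: {count:6.1f}  {'#' * int(count / 4)}")
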