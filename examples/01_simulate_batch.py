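"""Generate a ground-truthed fattening-batch scenario.

The digital twin drains a ~15,400 kg silo with the intake of 600 pigs over
18 weeks, refills it by a reorder policy with per-truckload density draws,
and emits the noisy 2-hourly level trace a real one-point laser sensor
would produce, alongside the farmer's batch record and the hidden truth.
"""

from pathlib import Path

from silogrowth import ScenarioConfig, simulate, write_scenario_outputs

cfg = ScenarioConfig(seed=42)
sim = simulate(cfg)

outdir = Path("scratch/example_batch")
paths = write_scenario_outputs(sim, outdir)

print(f"scenario seed {cfg.seed}: {cfg.n_animals} pigs, {cfg.horizon_weeks} weeks")
print(f"readings: {len(sim.series)} (2-hourly), refills: {len(sim.truth.refill_log)}")
print(f"initial fill: {sim.truth.initial_fill['weight_kg']:.0f} kg "
      f"at {sim.truth.initial_fill['density']:.1f} kg/m³")
print(f"total feed consumed: {sim.truth.total_consumption:.0f} kg")
print(f"final average weight: {sim.truth.subgroup_weekly_aw[0, -1]:.1f} kg")
print("files written:", ", ".join(str(p) for p in paths.values()))
# The truth file holds what the pipeline must recover: per-day intake,
# weekly average weights and the density of every truckload.
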