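"""Detect an underfeeding episode and notify the farmer.

From week 8 the pigs eat only 80% of the expected ration (feed quality or
sanitary problem).  The weekly deviation between sensor-based and
theoretical intake crosses the 10% threshold for two consecutive weeks and
a growth alert fires; if a refill in the affected span lacks its declared
weight, the data-accuracy check asks for the records first instead.
"""

from silogrowth import ScenarioConfig, dispatch, process_batch, simulate

base = ScenarioConfig(seed=7, noise_sd_fraction=0.0, missing_probability=0.0)
underfed = base.model_copy(update={"anomalies": [(8, 0.8)]})

for name, cfg in [("healthy batch", base), ("underfed from week 8", underfed)]:
    sim = simulate(cfg)
    res = process_batch(sim.series, sim.batch)
    print(f"{name}: {len(res.alerts)} alert(s)")
    for a in res.alerts:
        print(f"  week {a.week} [{a.kind}] deviation {a.magnitude:+.1%}")

# Delivery goes through a pluggable notifier contract (default: the log).
sim = simulate(underfed)
res = process_batch(sim.series, sim.batch)
report = dispatch(res.alerts)
print(f"dispatched: {report.n_delivered} delivered, {report.n_failed} failed")
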