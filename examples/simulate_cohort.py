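"""Generating a synthetic two-arm warfarin-management cohort.

Simulates app-managed (web) and conventionally managed (non-web) virtual
patients over 6 months and writes the registry, INR log and event log CSVs
that the analysis layer consumes.
"""

from inrkit import SimulationConfig, simulate_cohort, write_cohort

config = SimulationConfig(n_per_arm={"non_web": 80, "web": 80}, seed=42)
cohort = simulate_cohort(config)

print(f"patients: {len(cohort.registry)} "
      f"({dict(cohort.registry['arm'].value_counts())})")
print(f"INR records: {len(cohort.inr_log)} "
      f"(~{len(cohort.inr_log) / len(cohort.registry):.1f} per patient)")
print(f"clinical events: {len(cohort.events)}")
print(cohort.events["event_type"].value_counts().to_string())

manifest = write_cohort(cohort, "scratch/example_cohort")
print(f"wrote {sorted(manifest)} to scratch/example_cohort/")
# Identical (config, seed) always reproduce this cohort byte-for-byte.
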