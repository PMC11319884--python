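"""Full two-arm cohort comparison on synthetic data.

Simulates a cohort at the default configuration (260 conventional / 259
app-managed patients, 6-month follow-up), then runs the whole comparison:
arm TTR means, effectiveness proportions, the 5-level INR distribution with
per-row tests, first-event clinical outcome rates and log-rank p-values.
"""

from inrkit import SimulationConfig, analyze_cohort, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=1))
report = analyze_cohort(cohort.registry, cohort.inr_log, cohort.events)

cmp = report.ttr_comparison
for arm in ("non_web", "web"):
    s = cmp.summaries[arm]
    if "mean" in s:
        print(f"{arm}: mean TTR {s['mean']:.1f}% (SD {s['sd']:.1f})")
    else:
        print(f"{arm}: median TTR {s['median']:.1f}% (IQR {s['q1']:.1f}-{s['q3']:.1f})")
print(f"TTR comparison: {cmp.test.value}, p = {cmp.p_value:.2e}")

eff = report.effectiveness_comparison
for arm in ("non_web", "web"):
    s = eff.summaries[arm]
    print(f"{arm}: effective management (TTR>65%) {s['count']}/{s['total']} = {s['percent']}%")

print("\nINR distribution (% of records):")
print(report.inr_table.percents.to_string())

print("\nclinical events (first event per patient):")
for etype, c in report.event_comparisons.items():
    nw, w = c.summaries["non_web"], c.summaries["web"]
    p = "n/a" if c.p_value is None else f"{c.p_value:.3f}"
    lr = report.logrank_p[etype]
    lr = "n/a" if lr is None else f"{lr:.3f}"
    print(f"  {etype:<15} non-web {nw['count']:>3} ({nw['percent']}%)  "
          f"web {w['count']:>3} ({w['percent']}%)  p={p}  logrank p={lr}")
# The web arm should show a TTR mean roughly 10 points higher, a larger
# in-range share of INR records, and fewer minor bleeding events.
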