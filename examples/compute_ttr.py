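"""Rosendaal time-in-therapeutic-range for one patient's INR log.

Builds a short INR series for an atrial-fibrillation patient (target 2-3),
computes the linear-interpolation person-time decomposition and checks the
TTR>65% effectiveness benchmark.
"""

from inrkit import Indication, is_effective, resolve_target_range, rosendaal_ttr

target = resolve_target_range([Indication.ATRIAL_FIBRILLATION])
print(f"target range: {target.lower}-{target.upper}")

# (day, INR) pairs: starts low, overshoots, settles in range
series = [(0, 1.6), (7, 2.1), (14, 2.8), (28, 3.4), (42, 2.6), (70, 2.4)]
result = rosendaal_ttr(series, target)

print(f"days below range: {result.days_below:.1f}")
print(f"days in range:    {result.days_in:.1f}")
print(f"days above range: {result.days_above:.1f}")
print(f"TTR: {result.ttr:.1%}")
flag = is_effective(result)
print(f"effective anticoagulation (TTR > {flag.threshold:.0%}): {flag.effective}")
# The interpolated INR is in range whenever the line between consecutive
# measurements sits in [2, 3]; the days columns sum exactly to the 70-day span.
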