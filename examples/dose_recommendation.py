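"""Replaying the warfarin titration rules over an INR sequence.

Shows the hold/recheck state machine: an INR above 3 stops the drug for a
day; the drug resumes at a quarter-tablet less once the INR falls to 3 or
below.
"""

from inrkit import DoseState, TargetRange, run_titration

target = TargetRange(2.0, 3.0)
stream = [(0, 2.4), (14, 1.9), (21, 3.5), (22, 3.2), (23, 2.6), (37, 2.3)]

print(f"target {target.lower}-{target.upper}, starting dose 2.0 tablets/day")
for date, rec, state in run_titration(stream, target, DoseState(dose=2.0)):
    print(f"day {date:>3}: action={rec.action.value:<22} dose -> {state.dose:.2f} tablets"
          + (f" (recheck in {rec.recheck_in_days} day)" if rec.recheck_in_days else ""))
# day 14 (INR 1.9, just inside the -0.2 margin) leaves the dose unchanged;
# day 21 (INR 3.5) holds the drug; day 23 resumes at 1.75 tablets.
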