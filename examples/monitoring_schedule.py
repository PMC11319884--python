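"""The INR monitoring-interval ladder.

Monitoring starts weekly; two consecutive in-range results extend the
interval by a week (capped at 4 weeks); any dose change resets to weekly.
"""

from inrkit import schedule_trace

checks = [
    (True, False),   # in range
    (True, False),   # second consecutive -> extend afterwards
    (True, False),
    (True, False),
    (False, True),   # out of range, dose adjusted -> reset
    (True, False),
    (True, False),
]
intervals = schedule_trace(checks)
for k, ((in_range, dose_changed), weeks) in enumerate(zip(checks, intervals), 1):
    note = "dose changed" if dose_changed else ("in range" if in_range else "out of range")
    print(f"check {k}: taken at a {weeks}-week interval ({note})")
# The printed interval is the gap that preceded each check: 1,1,2,2,3 then
# the reset puts the following checks back on a weekly schedule.
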