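"""Decay-compensated framing: equal counts in every reconstructed frame.

With an 18F fill (half-life 109.77 min), later frames must lengthen to
collect the same number of true counts as the first. The schedule below
reproduces a 12-frame acquisition with a 5-minute first frame.
"""

import math

from scipy import integrate

from petprecision import equal_counts_schedule

sched = equal_counts_schedule(first_duration_min=5.0, n_frames=12, half_life_min=109.77)
lam = sched.decay_constant
print(f"{'frame':>5} {'start (min)':>12} {'duration (min)':>15} {'relative counts':>16}")
ref = None
for k, (t0, d) in enumerate(zip(sched.start_times_min, sched.durations_min), start=1):
    counts = integrate.quad(lambda t: math.exp(-lam * t), t0, t0 + d)[0]
    ref = ref or counts
    print(f"{k:>5} {t0:>12.2f} {d:>15.3f} {counts / ref:>16.6f}")
print(
    "\nDurations grow from 5.00 to "
    f"{sched.durations_min[-1]:.2f} min while relative counts stay at 1 to\n"
    "within 0.1% — the matched-count-statistics condition for replicate scans."
)
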