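"""Segment a single simulated reach and print its kinematic landmarks.

Builds one noise-free 240 Hz trace (reaction time 220 ms, duration 542 ms,
25 cm amplitude), then runs the full segmentation: 5-sample smoothing, 3D
speed, onset at 5 cm/s sustained for 100 ms, offset at the 0.3 N tap,
peak velocity restricted to the first 67% of the movement, and the
85%-of-peak crossings that delimit the early/mid/late phases.
"""

import numpy as np

from reachatten import ParticipantParams, SegmentationParams, segment_trial
from reachatten.synthetic_data import simulate_reach_trace

rng = np.random.default_rng(0)
params = ParticipantParams(kinematic_noise_sd_cm=0.0)
trace = simulate_reach_trace(params, rng, reaction_time_ms=220.0, duration_ms=542.0)

test_time = 370.0  # go-cue-locked probe
seg = segment_trial(trace, "t370", test_time, SegmentationParams())

print(f"movement onset    : {seg.onset_ms:7.1f} ms after the go cue")
print(f"85% rise crossing : {seg.ascend85_ms:7.1f} ms")
print(f"peak velocity     : {seg.peak_speed_cms:7.1f} cm/s at {seg.peak_time_ms:.1f} ms")
print(f"85% fall crossing : {seg.descend85_ms:7.1f} ms")
print(f"movement offset   : {seg.offset_ms:7.1f} ms (tap on the force sensor)")
print(f"movement duration : {seg.movement_duration_ms:7.1f} ms")
print(f"\ntest force at {test_time:.0f} ms -> phase '{seg.label}' "
      f"({seg.percent_time:.0f}% of the reach)")
print(
    "\nA probe inside [onset, 85%-rise) is 'early', inside the 85% band is\n"
    "'mid', and between the 85% fall and the tap is 'late'; probes outside\n"
    "[onset, offset) would invalidate the trial (exclusion criterion e)."
)
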