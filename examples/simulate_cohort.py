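"""Simulate a small cohort and look at its structure.

Generates three participants of the canonical force-discrimination design
(560 reaching + 56 baseline trials each), prints the trial schedule
composition and the realized reaching kinematics. The `gen_*` columns are
the generator's ground truth; the analysis pipeline never reads them.
"""

from reachatten import DesignConfig, simulate_cohort

cohort = simulate_cohort(3, design=DesignConfig(), seed=42, trace_mode="landmarks")

print("trials per participant:", len(cohort.trials) // 3)
print(cohort.trials["block"].value_counts().to_string())
print("\nscheduled slots (per participant):")
print(cohort.trials["scheduled_type"].value_counts().sort_index().floordiv(3).to_string())

lm = cohort.landmarks
dur = lm["offset_ms"] - lm["onset_ms"]
print(f"\nmovement duration (onset to tap): {dur.mean():.0f} +/- {dur.std():.0f} ms")
print(f"peak speed: {lm['peak_speed_cms'].mean():.0f} +/- {lm['peak_speed_cms'].std():.0f} cm/s")

truth = cohort.trials.query("block == 'reaching'")["gen_label"].value_counts()
print("\nground-truth phase of the test force across reaching trials:")
print(truth.to_string())
print(
    "\nThe three go-cue-locked probe times spread over early/mid/late phases\n"
    "because reaction times and movement durations vary trial to trial;\n"
    "'invalid' trials (probe before onset or after the tap) are later\n"
    "rejected by the quality-control filters."
)
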