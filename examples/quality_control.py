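"""Corrupt a clean cohort and audit the quality-control filters.

Injects trial-level artifacts that each violate exactly one exclusion
criterion (a: mis-applied test force, b: failed tap, c: displaced start,
d: comparison while moving, e: probe before movement onset, f: magnetic
distortion), then verifies the QC filters recover the corruption ledger
tag-for-tag.
"""

from reachatten import (
    DesignConfig,
    apply_trial_exclusions,
    inject_artifacts,
    segment_cohort,
    simulate_cohort,
)
from reachatten.config import PopulationConfig

quiet = PopulationConfig(
    rt_between_sd_ms=0, rt_within_sd_ms=0, duration_between_sd_ms=0,
    duration_within_sd_mean_ms=0, duration_within_sd_sd_ms=0,
    kinematic_noise_sd_cm=0, force_noise_sd_n=0, baseline_pse_sd_n=0,
    baseline_jnd_sd_n=0, slope_sd=0, dip_sd=0, residual_sd=0,
)
design = DesignConfig(reps_per_reaching_type=4, reps_baseline=2)
cohort = simulate_cohort(3, design=design, population=quiet, seed=7, trace_mode="full")

rates = {"a": 0.05, "b": 0.04, "c": 0.04, "d": 0.04, "e": 0.05, "f": 0.04}
corrupted, ledger = inject_artifacts(cohort, rates, seed=1)
print(f"injected {len(ledger)} corruptions:", ledger["tag"].value_counts().to_dict())

seg = segment_cohort(corrupted)
report = apply_trial_exclusions(corrupted.trials, seg, design)
print(f"QC rejected {report.n_rejected}/{report.n_total} trials "
      f"({100 * report.rejection_fraction:.1f}%)")
print("rejections by criterion:", {k: v for k, v in report.tag_counts.items() if v})

got = {
    (r.participant, int(r.trial_id), t)
    for r in report.decisions[report.decisions["rejected"]].itertuples()
    for t in r.tags.split(";")
}
want = {(r.participant, int(r.trial_id), r.tag) for r in ledger.itertuples()}
print("rejection set equals corruption ledger tag-for-tag:", got == want)
print("\nOn the uncorrupted cohort the same filters reject nothing, so every")
print("rejection above is attributable to an injected artifact.")
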