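"""Scaled-down two-group experiment: attenuation requires predicted self-touch.

Simulates a self-touch group (attenuation deepening over the reach) and a
no-self-touch control group (flat profile; the reach has no tactile
consequence for the other hand), runs both through the full pipeline, and
prints the mixed ANOVA, between-group contrasts, per-group slopes and the
one-sided Bayes factor assessing the control group's null slope.
"""

from reachatten import RunConfig, run_experiment2

config = RunConfig(
    experiment="exp2", seed=11, n_participants=14, n_no_self_touch=14,
    trace_mode="full",
)
report = run_experiment2(config)

print("normalized PSE group means [N]:")
for group, means in report.results["normalized_pse_mean"].items():
    cells = "  ".join(f"{k} {v:+.3f}" for k, v in means.items())
    print(f"  {group:14s} {cells}")

print("\nmixed ANOVA:")
for eff in report.results["mixed_anova"]["effects"]:
    print(f"  {eff['source']:11s} F({eff['df1']:.2f}, {eff['df2']:.2f}) = "
          f"{eff['F']:.2f}, p = {eff['p']:.2g}")

print("\nbetween-group contrasts (no_self_touch minus self_touch, BH-FDR):")
for c in report.results["between_group_comparisons"]:
    phase = c["name"].split(":")[0]
    print(f"  {phase:10s} {c['test_used']:10s} p_fdr = {c['p_fdr']:.4f} "
          f"effect = {c['effect_size']:+.2f}")

for group, t in report.results["slopes_early_target"]["group_tests"].items():
    print(f"\n{group}: slope {t['estimate']:+.2e} N/% ({t['test_used']}, "
          f"p = {t['p_raw']:.2g})")

bf = report.results["bf0_plus_no_self_touch_slope"]
print(f"\nBF0+ for the control group's slope: {bf['value']:.2f} ({bf['band']} "
      "support for the null)")
print(
    "\nThe self-touch group shows the deepening attenuation; the control\n"
    "group, whose reach predicts no touch on the left hand, does not."
)
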