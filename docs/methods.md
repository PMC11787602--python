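# Methods

This note documents the models, parameter choices and numerical conventions
behind `reachatten`: what the synthetic-data generator simulates and why its
defaults are what they are, how the analysis stages are defined at the sample
level, and what the test suite's passing (and one deliberately strict,
stochastic) checks do and do not establish about real data.

## The task being modelled

A two-interval force-discrimination task during reaching-to-self-touch. Each
participant contributes 616 trials: 560 reaching trials (7 comparison
intensities × 16 repetitions × 5 probe slots) and 56 baseline trials at rest
(7 × 8). The test force is fixed at 2 N for 100 ms; the comparison force
(1, 1.5, 1.75, 2, 2.25, 2.5 or 3 N) always follows 1200 ms later, after the
reach has ended. Three probe slots are go-cue-locked (250, 370 and 550 ms
after the cue; 100 ms later in the two-group experiment), two are
hardware-triggered: at the tap on the force sensor (plus a ~35 ms system
delay) and 300 ms after the tap. Because reaction times and movement
durations vary, the cue-locked probes are re-binned per trial into the
early/mid/late phases of the realized movement.

## Generative model

### Reach kinematics

Hand position runs along the start→target chord (amplitude 25 cm). The speed
profile over normalized movement time τ ∈ [0, 1] is a scaled Beta density,

    v(τ) = (A / D) · Beta(τ; a, b),

so position is the regularized incomplete beta function and every landmark
(threshold crossings, peak, 85% band) has a closed or invertible form. The
classical minimum-jerk profile is the exact special case (a, b) = (3, 3)
(speed 30τ²(1−τ)²), which the closed-form tests use. The default shape is
(2.5, 3.5), placing the velocity peak at 37.5% of the movement: empirical
point-to-point reaches of this kind peak early (≈200 ms into a ≈540 ms
movement), and a symmetric profile would both contradict that and push the
370 ms probe almost entirely into the early bin, collapsing the design.

Reaction times and movement durations are truncated-normal draws:
between-participant means 220 ± 42 ms (RT) and 542 ± 46 ms (duration), with
within-participant SDs of 40 ms (RT; chosen — only a single printed spread is
available and it is taken as between-participant) and 77 ± 20 ms (duration).
Position samples at 240 Hz carry isotropic Gaussian noise of 0.02 cm (0.2 mm,
typical of an electromagnetic tracker; large enough to exercise the smoothing,
small enough that the 5 cm/s onset rule is stable). Self-touch trials end with
a 130 ms half-sine 6 N tap pulse at movement end; no-self-touch trials record
a distance-sensor trigger when 97% of the amplitude is covered. Measured test
and comparison forces get Gaussian actuator noise of SD 0.03 N, so the
[1.85, 2.15] N window of exclusion criterion (a) fires only on injected
artifacts, not on clean data (5σ margin).

### Observer

The perceived intensity of the test force is

    perceived = baseline_PSE + attenuation(phase),

with attenuation 0 in the baseline, slope · min(percent, 100) during the
reach (percent = realized probe time as % of movement duration), slope · 100 +
dip at the target, and a residual post-reach. The response is Bernoulli with

    P(comparison stronger) = logistic((comparison − perceived) · log 3 / JND),

which makes the generative model the exact inverse of the logistic fit the
pipeline estimates (β₁ = log 3 / JND, β₀ = −perceived · β₁).

Psychophysical defaults: baseline PSE 2.0 ± 0.1 N (veridical on average; the
baseline subtraction removes the between-participant level), baseline JND
0.25 ± 0.05 N (the 1–3 N ladder then spans the psychometric curve),
attenuation slope −2.293 × 10⁻³ ± 1.7 × 10⁻³ N per % reach time, target dip
−0.08 ± 0.02 N, post-reach residual −0.08 ± 0.02 N. Two of these deserve
comment:

* **Slope SD 1.7 × 10⁻³.** Published per-participant slope SDs of this task
  (≈1.6–2.5 × 10⁻³) include slope-*estimation* noise, which the simulator
  re-adds when responses are drawn. Propagating the PSE fit error through the
  four-point regression gives an estimation component of ≈1.1 × 10⁻³;
  deconvolving it from the two published values gives ≈1.2–2.2 × 10⁻³, and the
  default is their midpoint. Using the raw printed SD as the population SD
  would double-count.
* **Post-reach residual −0.08 N.** A detectable residual is required for the
  post-reach between-group contrast to be resolvable at n ≈ 28 (the published
  effect there is d ≈ −0.6, i.e. a ≈0.09 N group difference); a token residual
  of −0.02 N would sit at d ≈ 0.2 and be invisible in any single cohort.

The no-self-touch condition forces the whole attenuation profile to zero: a
reach that predicts no contact generates no prediction-based attenuation.

### What the generator does not emulate

No visual/proprioceptive feedback loop or online corrections; no actuator or
EMG physics; no lapses, response bias or attention drift in the observer; no
block structure, fatigue or learning; distortion flags are injected labels
rather than a physical model of electromagnetic interference; movement-time
variability is pure trial-level jitter (no slow drift across blocks). Passing
tests therefore establish that the *analysis* is correct and calibrated under
the stated statistical structure — not that real data satisfy that structure.

## Analysis conventions

* **Smoothing**: centered 5-sample moving average (~21 ms at 240 Hz); at the
  first/last two samples the window shrinks symmetrically, which preserves
  affine signals everywhere and keeps input and output lengths equal.
* **Speed**: Euclidean norm of central differences (one-sided at the edges).
* **Onset**: first sample from which 24 consecutive samples (= ceil(0.1 s ×
  240 Hz)) exceed 5 cm/s; the reported time is the linearly interpolated
  upward threshold crossing just before that sample. Sample-snapped timing is
  available via `SegmentationParams(interpolate_crossings=False)` and is what
  the brute-force oracle tests use.
* **Offset**: first upward 0.3 N crossing of the tap force after onset
  (interpolated), or the recorded distance trigger.
* **Peak velocity**: argmax of speed restricted to the first 67% of the
  movement (excludes the terminal tap transient); ties break to the earliest
  sample.
* **85% crossings**: first time in [onset, peak] at or above 85% of the peak,
  and first time after the peak below it; if the speed never drops below 85%
  before the offset, the offset is used. Crossings are clamped into
  [onset, offset], so early/mid/late always partition [onset, offset).
* **Binning**: [onset, ascend85) → early, [ascend85, descend85) → mid,
  [descend85, offset) → late; a scheduled probe outside [onset, offset) voids
  the trial (criterion e). Hardware-triggered trials keep their provenance
  labels.
* **QC**: all six criteria are evaluated independently and tags accumulate
  (order-free audit). The start-position rule is operationalized as: reject
  when the trial's initial x position is ≥ 5 cm from the configured start
  (the source description of this rule is ambiguous; the displacement reading
  is the physically sensible one). The distortion veto window is
  [onset − 50 ms, offset + 350 ms], configurable. The "<10 trials" and
  "≥95% identical responses" participant rules are applied to every trial
  type symmetrically.
* **Psychometric fit**: Newton/IRLS on the binomial log-likelihood, tolerance
  1e-8, ≤100 iterations; under complete separation (or any non-convergence)
  the fit is redone with a ridge penalty of 1e-6 and flagged
  `converged=False`. McFadden R² is 1 − LL/LL₀ with LL₀ the intercept-only
  likelihood. Comparison forces are rebinned to the nearest canonical
  intensity with midpoint ties broken upward (measure-zero under the noise
  model; the choice is for determinism).
* **ANOVA**: decompositions and Greenhouse–Geisser epsilon via pingouin; the
  GG correction is applied to the degrees of freedom whenever ε̂ < 1 (the
  conventional "apply when Mauchly rejects" gate is deliberately not used —
  applying the correction continuously avoids a dichotomous analysis choice).
  A table with no within-participant variation at all returns F = 0, p = 1.
* **Planned comparisons**: Shapiro–Wilk at α = 0.05 on the paired differences
  (or per group) gates parametric vs rank tests. Paired contrasts are
  second-minus-first. Wilcoxon W is the positive-rank sum (mid-ranks, zeros
  dropped), rank-biserial r_rb = 2W/S − 1 with S = n(n+1)/2; independent
  r_rb = 2U₁/(n₁n₂) − 1. Rank-test CIs are Hodges–Lehmann (Walsh averages /
  pairwise differences, normal-approximation critical rank — verified against
  R's `wilcox.test(conf.int=TRUE)`); t-test CIs are the standard intervals;
  independent t tests are Welch-corrected. FDR is Benjamini–Hochberg within
  each planned family.
* **Slopes**: per-participant OLS of normalized PSE on the participant's mean
  realized % reach time of early/mid/late probes, with the target pinned at
  100% (span `early_target`) or excluded (span `early_late`); post-reach never
  enters the slope. Group tests reuse the normality-gated machinery.
* **Bayes factor**: one-sided JZS BF₀₊ = t-likelihood under the null divided
  by its marginal under a half-Cauchy (scale 0.707) prior on the standardized
  effect, by adaptive quadrature (split at 10 prior scales to handle the
  Cauchy tail); evidence bands 1–3/3–10/>10 attached as labels. Cross-checked
  against an independent trapezoid quadrature and (two-sided) against
  pingouin.

## Calibration results and statistical power

With the defaults above, a simulated 29-participant cohort rejects ≈7–9% of
trials (dominated by criterion e, cue-locked probes falling outside the
realized movement), realizes mean probe times of ≈11/36/64% of the reach for
early/mid/late, and recovers the generative slope without detectable bias
(200-cohort mean within sampling error of −2.293 × 10⁻³ N/% when the profile
is purely linear; the slope-vs-zero test rejects in >95% of sloped cohorts and
in ≈5% of flat ones, with BF₀₊ > 1 in the large majority of flat cohorts).

Two design-level facts are worth stating plainly, because they bound what any
single simulated (or real) cohort can show:

* **Goodness-of-fit ceiling.** At the default JND of 0.25 N the *asymptotic*
  McFadden R² on this intensity ladder is 0.46, so individual ~100-trial fits
  scatter around that value and a quarter of clean fits land below 0.40.
  Reports of uniformly higher R² in comparable experiments imply finer
  discrimination (JND ≈ 0.15–0.2 N) than this package's default observer.
* **Single-cohort power for the between-group pattern.** The mid and
  post-reach between-group differences under the defaults are ≈0.08 N against
  a per-cell SD of ≈0.12–0.14 N (dominated by the 56-trial baseline fit
  entering every normalized cell), i.e. d ≈ 0.6–0.7 and ≈60–75% power at
  n = 29/27 after FDR. Across seeded default runs the *full* pattern (early
  null plus all four later contrasts significant) therefore appears in only
  about half of cohorts, while the robust signatures — negative, significant
  self-touch slope; null control slope with BF₀₊ > 1; minimum at the target;
  between-group slope separation; significant target contrast — appear in
  essentially all. The end-to-end acceptance test runs one default-seed
  cohort and asserts the full pattern; its marginal sub-assertions are
  expected to flicker at exactly the rate this power analysis predicts.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run on small designs (4–6 repetitions per slot, 3–10
participants) and the fast landmark mode, in which kinematic landmarks are
derived analytically from the Beta profile instead of synthesizing and
re-segmenting 240 Hz traces; the trace path is exercised end-to-end by the
segmentation-oracle, QC round-trip and replication tests. Calibration checks
use 200 sloped and 500 flat cohorts at full sample size (n = 29/27, 616
trials each) in landmark mode; the acceptance script runs both experiments at
full scale with full traces plus 60 recovery and 200 null replicates. These
sizes were chosen so the whole suite runs comfortably on a single CPU while
keeping every Monte-Carlo bound at least ~3 SEs wide.

## Known limitations

* The attenuation profile is a phenomenological stand-in (piecewise linear +
  dip + residual), not a mechanistic forward-model simulation; recovered
  slopes quantify the analysis, not the brain.
* Landmark-mode cohorts treat the analytic landmarks as exact; trace-based
  segmentation differs by ~1–3 ms (interpolation, tap rise time), which is
  negligible for binning but visible if landmarks are compared directly.
* The Hodges–Lehmann critical rank uses the normal approximation; for n < ~10
  the achieved confidence differs slightly from 95%.
* External data can be ingested only in the documented CSV dialect (trial
  table, optional landmark table, or pre-binned labels); no reader for any
  instrument's native format is provided.
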