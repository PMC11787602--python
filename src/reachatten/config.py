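"""Configuration objects for the reaching / force-discrimination experiments.

The experiment modelled here is a two-interval force-discrimination task in
which a constant 2 N *test* force is applied to the resting left index finger
at different phases of a right-hand reaching movement (or at rest, in the
baseline block), followed 1200 ms later by a variable *comparison* force.
These dataclasses hold the design of that task, the per-participant generative
parameters used by the synthetic-data generator, and the parameters of the
kinematic segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "DesignConfig",
    "AttenuationProfile",
    "ParticipantParams",
    "PopulationConfig",
    "SegmentationParams",
    "REACHING_TYPES",
    "PHASE_LABELS",
    "DEFAULT_DESIGN",
]

#: The five reaching trial types entering the statistical analysis, in the
#: temporal order of the probed phase (plus the separate resting baseline).
REACHING_TYPES: tuple[str, ...] = ("early", "mid", "late", "target", "post_reach")

#: All phase labels a trial can end up with after segmentation and binning.
PHASE_LABELS: tuple[str, ...] = REACHING_TYPES + ("baseline", "invalid")


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class DesignConfig:
    """Trial schedule and stimulus timing of one experiment.

    Defaults reproduce the canonical design: seven comparison intensities
    spanning 1–3 N around the fixed 2 N test force, 16 repetitions per
    reaching trial type (5 types) and 8 in the baseline, i.e. 560 reaching
    + 56 baseline = 616 trials per participant.
    """

    comparison_intensities: tuple[float, ...] = (1.0, 1.5, 1.75, 2.0, 2.25, 2.5, 3.0)
    reps_per_reaching_type: int = 16
    reps_baseline: int = 8
    test_force_n: float = 2.0
    test_duration_ms: float = 100.0
    comparison_delay_ms: float = 1200.0
    #: go-cue-locked delivery times of the time-scheduled test forces
    scheduled_force_times_ms: tuple[float, ...] = (250.0, 370.0, 550.0)
    #: test-force delay after the tap in post-reach trials
    post_reach_offset_ms: float = 300.0
    #: latency between the hardware trigger (tap / distance sensor) and force onset
    system_delay_ms: float = 35.0
    #: all scheduled deliveries are shifted by this amount in Experiment 2
    experiment2_shift_ms: float = 100.0
    #: test-force time after trial onset in baseline trials
    baseline_test_time_ms: float = 100.0

    def __post_init__(self) -> None:
        ints = np.asarray(self.comparison_intensities, dtype=float)
        if ints.size == 0:
            raise ConfigurationError("comparison_intensities must be non-empty")
        if not np.all(np.diff(ints) > 0):
            raise ConfigurationError("comparison_intensities must be strictly increasing")
        if not np.any(np.isclose(ints, self.test_force_n)):
            raise ConfigurationError("test_force_n must be one of comparison_intensities")
        if self.reps_per_reaching_type < 1 or self.reps_baseline < 1:
            raise ConfigurationError("repetition counts must be >= 1")
        for name in (
            "test_duration_ms",
            "comparison_delay_ms",
            "post_reach_offset_ms",
            "system_delay_ms",
            "experiment2_shift_ms",
            "baseline_test_time_ms",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.scheduled_force_times_ms) == 0:
            raise ConfigurationError("at least one scheduled force time is required")
        if any(t < 0 for t in self.scheduled_force_times_ms):
            raise ConfigurationError("scheduled force times must be >= 0")

    @property
    def scheduled_kinds(self) -> tuple[str, ...]:
        """Provenance labels of the scheduled slots (``t250`` … plus hardware slots)."""
        timed = tuple(f"t{t:g}" for t in self.scheduled_force_times_ms)
        return timed + ("target", "post_reach")

    @property
    def timed_kinds(self) -> tuple[str, ...]:
        return tuple(f"t{t:g}" for t in self.scheduled_force_times_ms)

    @property
    def n_reaching(self) -> int:
        return (
            len(self.comparison_intensities)
            * self.reps_per_reaching_type
            * len(self.scheduled_kinds)
        )

    @property
    def n_baseline(self) -> int:
        return len(self.comparison_intensities) * self.reps_baseline

    @property
    def n_trials(self) -> int:
        return self.n_reaching + self.n_baseline


@dataclass(frozen=True)
class AttenuationProfile:
    """Generative attenuation of the perceived test force over the reach.

    The perceived intensity of the test force equals the participant's
    baseline PSE plus this profile evaluated at the phase at which the test
    force was physically delivered. The profile is anchored at 0 N at 0% of
    the reach, falls linearly with elapsed reach time (``slope_per_percent``,
    in N per % of reach duration), takes an extra dip at the moment of the
    tap (``target_extra_dip``), and relaxes to a small residual 300 ms after
    the reach (``post_reach_residual``).
    """

    slope_per_percent: float = -2.293e-3
    target_extra_dip: float = -0.08
    post_reach_residual: float = -0.08

    @classmethod
    def flat(cls) -> "AttenuationProfile":
        return cls(0.0, 0.0, 0.0)

    def at(self, label: str, percent: float | np.ndarray = 0.0):
        """Attenuation (N, signed) for a trial of phase ``label``.

        ``percent`` is the realized test-force time as % of the reach
        duration and is only used for the within-reach scheduled phases.
        """
        if label == "target":
            return self.slope_per_percent * 100.0 + self.target_extra_dip
        if label == "post_reach":
            return self.post_reach_residual
        if label == "baseline":
            return 0.0 if np.isscalar(percent) else np.zeros_like(np.asarray(percent, float))
        return self.slope_per_percent * np.clip(percent, 0.0, 100.0)


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters of one simulated participant."""

    reaction_time_mean_ms: float = 220.0
    reaction_time_sd_ms: float = 40.0
    movement_duration_mean_ms: float = 542.0
    movement_duration_within_sd_ms: float = 77.0
    reach_amplitude_cm: float = 25.0
    sampling_rate_hz: float = 240.0
    kinematic_noise_sd_cm: float = 0.02
    force_noise_sd_n: float = 0.03
    baseline_pse_n: float = 2.0
    baseline_jnd_n: float = 0.25
    attenuation: AttenuationProfile = field(default_factory=AttenuationProfile)
    condition: str = "self_touch"
    #: Beta(a, b) shape of the speed profile over normalized movement time;
    #: (3, 3) is the exact minimum-jerk profile, the default (2.5, 3.5) puts
    #: the velocity peak at 37.5% of the movement as observed empirically.
    speed_shape: tuple[float, float] = (2.5, 3.5)
    #: fraction of the reach amplitude at which the distance sensor triggers
    #: (no-self-touch condition only)
    trigger_amplitude_fraction: float = 0.97

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")
        if self.reach_amplitude_cm <= 0:
            raise ConfigurationError("reach_amplitude_cm must be > 0")
        if self.movement_duration_mean_ms <= 0:
            raise ConfigurationError("movement_duration_mean_ms must be > 0")
        if self.baseline_jnd_n <= 0:
            raise ConfigurationError("baseline_jnd_n must be > 0")
        for name in (
            "reaction_time_sd_ms",
            "movement_duration_within_sd_ms",
            "kinematic_noise_sd_cm",
            "force_noise_sd_n",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.condition not in ("self_touch", "no_self_touch"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        a, b = self.speed_shape
        if a <= 1 or b <= 1:
            raise ConfigurationError("speed_shape parameters must be > 1 (single-peaked)")
        if not 0 < self.trigger_amplitude_fraction < 1:
            raise ConfigurationError("trigger_amplitude_fraction must be in (0, 1)")

    def with_(self, **kwargs) -> "ParticipantParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PopulationConfig:
    """Between-participant distributions from which cohorts are drawn.

    Means and SDs of the truncated-normal draws of each participant's
    kinematic and psychophysical parameters. Kinematic defaults follow the
    printed group statistics of the task (reaction time 220 ± 42 ms, movement
    duration 542 ± 46 ms between participants with a 77 ± 20 ms within-
    participant SD); psychophysical defaults are the simulator's calibration
    (see docs/methods.md).
    """

    rt_mean_ms: float = 220.0
    rt_between_sd_ms: float = 42.0
    rt_within_sd_ms: float = 40.0
    duration_mean_ms: float = 542.0
    duration_between_sd_ms: float = 46.0
    duration_within_sd_mean_ms: float = 77.0
    duration_within_sd_sd_ms: float = 20.0
    reach_amplitude_cm: float = 25.0
    kinematic_noise_sd_cm: float = 0.02
    force_noise_sd_n: float = 0.03
    baseline_pse_mean_n: float = 2.0
    baseline_pse_sd_n: float = 0.1
    baseline_jnd_mean_n: float = 0.25
    baseline_jnd_sd_n: float = 0.05
    slope_mean: float = -2.293e-3
    slope_sd: float = 1.7e-3
    dip_mean: float = -0.08
    dip_sd: float = 0.02
    residual_mean: float = -0.08
    residual_sd: float = 0.02
    condition: str = "self_touch"
    speed_shape: tuple[float, float] = (2.5, 3.5)

    @classmethod
    def no_self_touch(cls, **kwargs) -> "PopulationConfig":
        """Control population: same movements, flat attenuation profile."""
        kwargs.setdefault("condition", "no_self_touch")
        return cls(**kwargs)

    @classmethod
    def flat(cls, **kwargs) -> "PopulationConfig":
        """Self-touch condition but a null (all-zero) attenuation profile."""
        kwargs.update(slope_mean=0.0, slope_sd=0.0, dip_mean=0.0, dip_sd=0.0,
                      residual_mean=0.0, residual_sd=0.0)
        return cls(**kwargs)

    def draw_participant(self, rng: np.random.Generator) -> ParticipantParams:
        def trunc(mean, sd, lower):
            if sd == 0:
                return float(mean)
            x = rng.normal(mean, sd)
            while x <= lower:
                x = rng.normal(mean, sd)
            return float(x)

        if self.condition == "no_self_touch":
            # no predicted self-touch -> no predictive attenuation, by design
            profile = AttenuationProfile.flat()
        else:
            profile = AttenuationProfile(
                slope_per_percent=float(rng.normal(self.slope_mean, self.slope_sd))
                if self.slope_sd > 0 else self.slope_mean,
                target_extra_dip=float(rng.normal(self.dip_mean, self.dip_sd))
                if self.dip_sd > 0 else self.dip_mean,
                post_reach_residual=float(rng.normal(self.residual_mean, self.residual_sd))
                if self.residual_sd > 0 else self.residual_mean,
            )
        return ParticipantParams(
            reaction_time_mean_ms=trunc(self.rt_mean_ms, self.rt_between_sd_ms, 80.0),
            reaction_time_sd_ms=self.rt_within_sd_ms,
            movement_duration_mean_ms=trunc(
                self.duration_mean_ms, self.duration_between_sd_ms, 250.0
            ),
            movement_duration_within_sd_ms=trunc(
                self.duration_within_sd_mean_ms, self.duration_within_sd_sd_ms, 0.0
            )
            if self.duration_within_sd_sd_ms > 0
            else self.duration_within_sd_mean_ms,
            reach_amplitude_cm=self.reach_amplitude_cm,
            kinematic_noise_sd_cm=self.kinematic_noise_sd_cm,
            force_noise_sd_n=self.force_noise_sd_n,
            baseline_pse_n=trunc(self.baseline_pse_mean_n, self.baseline_pse_sd_n, 1.2),
            baseline_jnd_n=trunc(self.baseline_jnd_mean_n, self.baseline_jnd_sd_n, 0.08),
            attenuation=profile,
            condition=self.condition,
            speed_shape=self.speed_shape,
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the kinematic preprocessing and segmentation.

    Defaults follow the analysis conventions of the task: a 5-sample moving
    average (~21 ms at 240 Hz), movement onset at the first time the 3D speed
    exceeds 5 cm/s for 100 ms sequentially, movement offset at the first
    0.3 N crossing on the tap sensor, peak velocity restricted to the first
    67% of the movement, and phase boundaries at 85% of the peak speed.
    """

    smooth_span: int = 5
    onset_speed_threshold: float = 5.0  # cm/s
    onset_hold_ms: float = 100.0
    tap_force_threshold: float = 0.3  # N
    peak_window_fraction: float = 0.67
    phase_velocity_fraction: float = 0.85
    sampling_rate_hz: float = 240.0
    #: sub-sample linear interpolation of threshold crossings; set False for
    #: strictly sample-snapped replication
    interpolate_crossings: bool = True
    #: window around the movement used to veto magnetically distorted trials
    distortion_pre_ms: float = 50.0
    distortion_post_ms: float = 350.0

    def __post_init__(self) -> None:
        if self.smooth_span < 1 or self.smooth_span % 2 == 0:
            raise ConfigurationError("smooth_span must be odd and >= 1")
        if not 0 < self.peak_window_fraction < 1:
            raise ConfigurationError("peak_window_fraction must be in (0, 1)")
        if not 0 < self.phase_velocity_fraction < 1:
            raise ConfigurationError("phase_velocity_fraction must be in (0, 1)")
        if self.onset_speed_threshold <= 0 or self.tap_force_threshold <= 0:
            raise ConfigurationError("thresholds must be > 0")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")

    @property
    def onset_hold_samples(self) -> int:
        """Number of consecutive supra-threshold samples required for onset."""
        return int(np.ceil(self.onset_hold_ms / 1000.0 * self.sampling_rate_hz))


DEFAULT_DESIGN = DesignConfig()
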