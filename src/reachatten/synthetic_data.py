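"""Synthetic cohorts for the reaching / force-discrimination task.

The generator emulates the statistical structure the analysis assumes:

* a trial schedule of 7 comparison intensities x 16 repetitions x 5 reaching
  trial slots (three go-cue-locked test-force times plus the hardware-
  triggered target and post-reach slots), with a separate baseline block;
* bell-shaped single-peaked reaches: the speed profile over normalized
  movement time is a Beta(a, b) density scaled by amplitude/duration, of
  which the classical minimum-jerk profile is the exact (3, 3) special case;
  reaction times and movement durations are truncated-normal draws;
* a logistic observer whose perceived test-force intensity is the baseline
  PSE plus a phase-dependent attenuation (linear in elapsed reach time, with
  an extra dip at the moment of self-touch and a small post-reach residual);
* controlled corruption (`inject_artifacts`) that makes individual trials
  violate exactly one of the exclusion criteria (a)-(f), with a ground-truth
  ledger, for testing the quality-control filters.

Every draw is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import betainc, betaincinv, expit

from .config import (
    AttenuationProfile,
    ConfigurationError,
    DesignConfig,
    ParticipantParams,
    PopulationConfig,
)
from .kinematics import KinematicTrace

__all__ = [
    "Cohort",
    "make_trial_schedule",
    "simulate_reach_trace",
    "p_comparison_stronger",
    "simulate_observer_response",
    "simulate_cohort",
    "inject_artifacts",
    "reach_landmarks",
    "TRIAL_COLUMNS",
    "LANDMARK_COLUMNS",
]

LOG3 = float(np.log(3.0))

TRIAL_COLUMNS = [
    "participant",
    "trial_id",
    "block",
    "scheduled_type",
    "test_commanded_n",
    "test_measured_n",
    "comparison_commanded_n",
    "comparison_measured_n",
    "test_time_ms",
    "comparison_time_ms",
    "response",
    "corruption_flags",
]

LANDMARK_COLUMNS = [
    "participant",
    "trial_id",
    "onset_ms",
    "ascend85_ms",
    "peak_time_ms",
    "peak_speed_cms",
    "descend85_ms",
    "offset_ms",
    "start_x_cm",
    "moved_before_cue",
    "distortion_overlap",
]


# ---------------------------------------------------------------------------
# speed-profile geometry


@lru_cache(maxsize=16)
class _SpeedShape:
    """Cached geometry of a Beta(a, b) speed profile.

    Speed over normalized movement time tau in [0, 1] is
    v(tau) = (A / D) * Beta.pdf(tau; a, b), so position is the regularized
    incomplete beta function and all landmarks have closed or invertible
    forms. The 85%-of-peak crossings are shape constants (scale-free);
    the onset crossing depends on the absolute threshold and is inverted on
    a dense grid of the rising branch.
    """

    def __init__(self, a: float, b: float, phase_fraction: float = 0.85):
        self.a, self.b = float(a), float(b)
        self.mode = (self.a - 1.0) / (self.a + self.b - 2.0)
        self.peak_density = float(sps.beta.pdf(self.mode, self.a, self.b))
        self._tau_rise = np.linspace(1e-9, self.mode, 4096)
        self._dens_rise = sps.beta.pdf(self._tau_rise, self.a, self.b)
        tau_fall = np.linspace(self.mode, 1.0 - 1e-9, 4096)
        dens_fall = sps.beta.pdf(tau_fall, self.a, self.b)
        level = phase_fraction * self.peak_density
        self.tau_ascend85 = float(np.interp(level, self._dens_rise, self._tau_rise))
        # falling branch: density decreasing, interpolate on the reversed arrays
        self.tau_descend85 = float(
            np.interp(level, dens_fall[::-1], tau_fall[::-1])
        )

    def tau_at_speed_rising(self, density_target: np.ndarray) -> np.ndarray:
        return np.interp(density_target, self._dens_rise, self._tau_rise)

    def cdf(self, tau: np.ndarray) -> np.ndarray:
        return betainc(self.a, self.b, np.clip(tau, 0.0, 1.0))

    def pdf(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.zeros_like(tau)
        inside = (tau > 0) & (tau < 1)
        out[inside] = sps.beta.pdf(tau[inside], self.a, self.b)
        return out

    def peak_speed(self, amplitude_cm: float, duration_ms: float) -> float:
        return amplitude_cm / (duration_ms / 1000.0) * self.peak_density


def reach_landmarks(
    params: ParticipantParams,
    reaction_time_ms: np.ndarray,
    duration_ms: np.ndarray,
    onset_speed_threshold: float = 5.0,
) -> pd.DataFrame:
    """Analytic kinematic landmarks of noise-free Beta-profile reaches.

    Returns onset (first crossing of the 5 cm/s analysis threshold),
    85%-of-peak crossings, peak time/speed and offset (tap at movement end
    for self-touch; distance-sensor trigger for no-self-touch), in ms from
    the go-cue, for vectors of reaction times and durations.
    """
    shape = _SpeedShape(*params.speed_shape)
    rt = np.asarray(reaction_time_ms, dtype=float)
    dur = np.asarray(duration_ms, dtype=float)
    a_cm = params.reach_amplitude_cm
    density_target = onset_speed_threshold * (dur / 1000.0) / a_cm
    tau_on = shape.tau_at_speed_rising(density_target)
    onset = rt + tau_on * dur
    ascend = rt + shape.tau_ascend85 * dur
    descend = rt + shape.tau_descend85 * dur
    peak_t = rt + shape.mode * dur
    peak_v = a_cm / (dur / 1000.0) * shape.peak_density
    if params.condition == "no_self_touch":
        tau_trig = float(
            betaincinv(shape.a, shape.b, params.trigger_amplitude_fraction)
        )
        offset = rt + tau_trig * dur
    else:
        offset = rt + dur
    return pd.DataFrame(
        {
            "onset_ms": onset,
            "ascend85_ms": ascend,
            "peak_time_ms": peak_t,
            "peak_speed_cms": peak_v,
            "descend85_ms": descend,
            "offset_ms": offset,
        }
    )


# ---------------------------------------------------------------------------
# schedule


def make_trial_schedule(design: DesignConfig, rng_seed: int) -> pd.DataFrame:
    """Ordered trial stubs for one participant.

    Every (comparison intensity x reaching slot) cell appears exactly
    ``reps_per_reaching_type`` times; the reaching order is a seeded random
    permutation; baseline trials form a separate block appended at the end
    (counterbalancing of block order does not affect the analysis).
    """
    rng = np.random.default_rng(rng_seed)
    kinds = np.asarray(design.scheduled_kinds, dtype=object)
    ints = np.asarray(design.comparison_intensities, dtype=float)
    reps = design.reps_per_reaching_type
    kind_col = np.repeat(kinds, ints.size * reps)
    int_col = np.tile(np.repeat(ints, reps), kinds.size)
    order = rng.permutation(kind_col.size)
    base_int = np.repeat(ints, design.reps_baseline)
    out = pd.DataFrame(
        {
            "trial_id": np.arange(1, kind_col.size + base_int.size + 1),
            "block": np.concatenate(
                [np.repeat("reaching", kind_col.size),
                 np.repeat("baseline", base_int.size)]
            ),
            "scheduled_type": np.concatenate(
                [kind_col[order], np.repeat("baseline", base_int.size)]
            ),
            "comparison_commanded_n": np.concatenate([int_col[order], base_int]),
        }
    )
    out["test_commanded_n"] = design.test_force_n
    return out


# ---------------------------------------------------------------------------
# single-trial simulators


def simulate_reach_trace(
    params: ParticipantParams,
    rng: np.random.Generator,
    reaction_time_ms: float,
    duration_ms: float,
    test_time_ms: float = np.nan,
    comparison_time_ms: float = np.nan,
) -> KinematicTrace:
    """One 240 Hz kinematic trace of a reaching trial.

    The hand rests at the start position (x = amplitude) until the reaction
    time, then follows the Beta-profile trajectory to x = 0 over the given
    duration, with isotropic Gaussian positional noise. Self-touch trials
    end with a tap-force pulse on the sensor at movement end; no-self-touch
    trials record the distance-sensor trigger instead.
    """
    if duration_ms <= 0:
        raise ConfigurationError("duration_ms must be > 0")
    if reaction_time_ms < 0:
        raise ConfigurationError("reaction_time_ms must be >= 0")
    shape = _SpeedShape(*params.speed_shape)
    dt = 1000.0 / params.sampling_rate_hz
    t0, t_end = -250.0, reaction_time_ms + duration_ms + 450.0
    n = int(np.floor((t_end - t0) / dt)) + 1
    t = t0 + np.arange(n) * dt
    tau = (t - reaction_time_ms) / duration_ms
    x = params.reach_amplitude_cm * (1.0 - shape.cdf(tau))
    pos = np.zeros((n, 3))
    pos[:, 0] = x
    if params.kinematic_noise_sd_cm > 0:
        pos += rng.normal(0.0, params.kinematic_noise_sd_cm, size=(n, 3))
    move_end = reaction_time_ms + duration_ms
    events = {"go_cue_ms": 0.0}
    if np.isfinite(test_time_ms):
        events["test_ms"] = float(test_time_ms)
    if np.isfinite(comparison_time_ms):
        events["comparison_ms"] = float(comparison_time_ms)
    if params.condition == "self_touch":
        tap = np.zeros(n)
        in_pulse = (t >= move_end) & (t <= move_end + 130.0)
        tap[in_pulse] = 6.0 * np.sin(np.pi * (t[in_pulse] - move_end) / 130.0)
        return KinematicTrace(
            t_ms=t, position_cm=pos, tap_force_n=tap, events=events,
            condition="self_touch",
        )
    tau_trig = float(betaincinv(shape.a, shape.b, params.trigger_amplitude_fraction))
    trigger = reaction_time_ms + tau_trig * duration_ms
    return KinematicTrace(
        t_ms=t, position_cm=pos, distance_trigger_ms=trigger, events=events,
        condition="no_self_touch",
    )


def p_comparison_stronger(
    comparison_n: np.ndarray, perceived_pse_n: np.ndarray, jnd_n: np.ndarray
) -> np.ndarray:
    """Logistic observer: P("comparison stronger") for given PSE and JND.

    The JND is the 0.75-minus-0.5 threshold distance, so the logistic slope
    is log(3)/JND and P = 0.75 exactly one JND above the PSE.
    """
    jnd_n = np.asarray(jnd_n, dtype=float)
    if np.any(jnd_n <= 0):
        raise ConfigurationError("jnd must be > 0")
    return expit((np.asarray(comparison_n, float) - perceived_pse_n) * LOG3 / jnd_n)


def simulate_observer_response(
    comparison_n: float,
    perceived_pse_n: float,
    jnd_n: float,
    rng: np.random.Generator,
) -> str:
    """Draw one Bernoulli response from the logistic observer."""
    p = p_comparison_stronger(comparison_n, perceived_pse_n, jnd_n)
    return "comparison_stronger" if rng.random() < p else "test_stronger"


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class Cohort:
    """A simulated (or ingested) dataset: trial table, kinematics, provenance."""

    trials: pd.DataFrame
    participants: pd.DataFrame
    landmarks: pd.DataFrame | None
    traces: dict | None
    design: DesignConfig
    manifest: dict = field(default_factory=dict)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants["participant"])

    def copy(self) -> "Cohort":
        return Cohort(
            trials=self.trials.copy(),
            participants=self.participants.copy(),
            landmarks=None if self.landmarks is None else self.landmarks.copy(),
            traces=None if self.traces is None else dict(self.traces),
            design=self.design,
            manifest=dict(self.manifest),
        )


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    """Truncated-normal (> low) draws via vectorized rejection sampling."""
    if sd == 0:
        return np.full(size, max(mean, low), dtype=float)
    x = rng.normal(mean, sd, size)
    bad = x <= low
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = x <= low
    return x


def _simulate_participant(
    pid: str,
    design: DesignConfig,
    params: ParticipantParams,
    rng: np.random.Generator,
    experiment: str,
    trace_mode: str,
):
    sched = make_trial_schedule(design, int(rng.integers(2**31)))
    n_all = len(sched)
    reach_mask = (sched["block"] == "reaching").to_numpy()
    n_reach = int(reach_mask.sum())

    rt = _trunc_normal(rng, params.reaction_time_mean_ms, params.reaction_time_sd_ms,
                       80.0, n_reach)
    dur = _trunc_normal(rng, params.movement_duration_mean_ms,
                        params.movement_duration_within_sd_ms, 250.0, n_reach)
    lm = reach_landmarks(params, rt, dur)
    shift = design.experiment2_shift_ms if experiment == "exp2" else 0.0

    kinds = sched.loc[reach_mask, "scheduled_type"].to_numpy()
    test_t = np.empty(n_reach)
    for kind_name, sched_t in zip(design.timed_kinds, design.scheduled_force_times_ms):
        test_t[kinds == kind_name] = sched_t + shift
    offs = lm["offset_ms"].to_numpy()
    test_t[kinds == "target"] = offs[kinds == "target"] + design.system_delay_ms
    test_t[kinds == "post_reach"] = offs[kinds == "post_reach"] + design.post_reach_offset_ms
    comp_t = test_t + design.comparison_delay_ms

    onset = lm["onset_ms"].to_numpy()
    pct = 100.0 * (test_t - onset) / (offs - onset)
    gen_label = np.select(
        [
            kinds == "target",
            kinds == "post_reach",
            (test_t < onset) | (test_t >= offs),
            test_t < lm["ascend85_ms"].to_numpy(),
            test_t < lm["descend85_ms"].to_numpy(),
        ],
        ["target", "post_reach", "invalid", "early", "mid"],
        default="late",
    )

    atten = np.where(
        kinds == "target",
        params.attenuation.at("target"),
        np.where(
            kinds == "post_reach",
            params.attenuation.at("post_reach"),
            params.attenuation.at("early", np.clip(pct, 0.0, 100.0)),
        ),
    )
    perceived = np.full(n_all, params.baseline_pse_n)
    perceived[reach_mask] = params.baseline_pse_n + atten

    trials = sched.copy()
    trials.insert(0, "participant", pid)
    trials["test_measured_n"] = trials["test_commanded_n"] + rng.normal(
        0.0, params.force_noise_sd_n, n_all
    )
    trials["comparison_measured_n"] = trials["comparison_commanded_n"] + rng.normal(
        0.0, params.force_noise_sd_n, n_all
    )
    t_all = np.full(n_all, design.baseline_test_time_ms)
    t_all[reach_mask] = test_t
    c_all = t_all + design.comparison_delay_ms
    trials["test_time_ms"] = t_all
    trials["comparison_time_ms"] = c_all
    p_comp = p_comparison_stronger(
        trials["comparison_measured_n"].to_numpy(), perceived, params.baseline_jnd_n
    )
    trials["response"] = np.where(
        rng.random(n_all) < p_comp, "comparison_stronger", "test_stronger"
    )
    trials["corruption_flags"] = ""
    trials["gen_label"] = "baseline"
    trials.loc[reach_mask, "gen_label"] = gen_label
    trials["gen_percent"] = np.nan
    trials.loc[reach_mask, "gen_percent"] = pct
    trials = trials[TRIAL_COLUMNS + ["gen_label", "gen_percent"]]

    lm_out = lm.copy()
    lm_out.insert(0, "trial_id", sched.loc[reach_mask, "trial_id"].to_numpy())
    lm_out.insert(0, "participant", pid)
    lm_out["start_x_cm"] = params.reach_amplitude_cm
    lm_out["moved_before_cue"] = False
    lm_out["distortion_overlap"] = False
    lm_out = lm_out[LANDMARK_COLUMNS]

    traces = {}
    if trace_mode == "full":
        ids = sched.loc[reach_mask, "trial_id"].to_numpy()
        for i, tid in enumerate(ids):
            traces[(pid, int(tid))] = simulate_reach_trace(
                params, rng, rt[i], dur[i], test_t[i], comp_t[i]
            )
    return trials, lm_out, traces


def simulate_cohort(
    n_participants: int,
    design: DesignConfig | None = None,
    population: PopulationConfig | None = None,
    seed: int = 0,
    experiment: str = "exp1",
    trace_mode: str = "full",
) -> Cohort:
    """Simulate a cohort of participants performing one experiment.

    ``trace_mode='full'`` emits a 240 Hz kinematic trace per reaching trial;
    ``trace_mode='landmarks'`` skips trace synthesis and carries the
    analytically derived kinematic landmarks instead (orders of magnitude
    faster; used for many-replicate calibration studies). Both modes carry
    the generator's ground-truth labels in ``gen_label`` / ``gen_percent``,
    which the analysis pipeline never reads.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    if trace_mode not in ("full", "landmarks"):
        raise ConfigurationError(f"unknown trace_mode {trace_mode!r}")
    if experiment not in ("exp1", "exp2"):
        raise ConfigurationError(f"unknown experiment {experiment!r}")
    design = design or DesignConfig()
    population = population or PopulationConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    all_trials, all_lm, all_traces, part_rows = [], [], {}, []
    for i, child in enumerate(children):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng(child)
        params = population.draw_participant(rng)
        trials, lm, traces = _simulate_participant(
            pid, design, params, rng, experiment, trace_mode
        )
        all_trials.append(trials)
        all_lm.append(lm)
        all_traces.update(traces)
        part_rows.append(
            {
                "participant": pid,
                "condition": params.condition,
                "reaction_time_mean_ms": params.reaction_time_mean_ms,
                "movement_duration_mean_ms": params.movement_duration_mean_ms,
                "movement_duration_within_sd_ms": params.movement_duration_within_sd_ms,
                "baseline_pse_n": params.baseline_pse_n,
                "baseline_jnd_n": params.baseline_jnd_n,
                "slope_per_percent": params.attenuation.slope_per_percent,
                "target_extra_dip": params.attenuation.target_extra_dip,
                "post_reach_residual": params.attenuation.post_reach_residual,
            }
        )
    return Cohort(
        trials=pd.concat(all_trials, ignore_index=True),
        participants=pd.DataFrame(part_rows),
        landmarks=pd.concat(all_lm, ignore_index=True),
        traces=all_traces if trace_mode == "full" else None,
        design=design,
        manifest={
            "seed": int(seed),
            "n_participants": int(n_participants),
            "experiment": experiment,
            "trace_mode": trace_mode,
            "condition": population.condition,
            "corruption_ledger": [],
        },
    )


# ---------------------------------------------------------------------------
# controlled corruption


VALID_CRITERIA = ("a", "b", "c", "d", "e", "f")


def inject_artifacts(
    cohort: Cohort, rates: dict, seed: int = 0
) -> tuple[Cohort, pd.DataFrame]:
    """Corrupt a cohort so selected trials violate exactly one QC criterion.

    ``rates`` maps criterion tags (a)-(f) to per-trial corruption
    probabilities. Each corrupted trial is altered so that exactly the named
    criterion fires: (a) mis-applied test force; (b) failed tap / trigger;
    (c) start position displaced toward the sensor; (d) comparison force
    delivered before movement offset; (e) scheduled test force before
    movement onset; (f) electromagnetic distortion overlapping the
    segmentation window. A trial receives at most one corruption. Returns
    the corrupted cohort and the ground-truth ledger
    (participant, trial_id, tag).
    """
    unknown = set(rates) - set(VALID_CRITERIA)
    if unknown:
        raise ConfigurationError(f"unknown criterion name(s): {sorted(unknown)}")
    for tag, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"rate for {tag!r} must be in [0, 1]")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    trials = out.trials
    lm = out.landmarks
    lm_index = (
        lm.set_index(["participant", "trial_id"]) if lm is not None else None
    )
    corrupted: set[tuple[str, int]] = set()
    ledger_rows: list[dict] = []

    reaching = trials["block"] == "reaching"
    timed = trials["scheduled_type"].isin(out.design.timed_kinds)

    def _pick(mask: pd.Series, rate: float) -> pd.DataFrame:
        cand = trials[mask]
        cand = cand[
            ~cand.apply(
                lambda r: (r["participant"], r["trial_id"]) in corrupted, axis=1
            )
        ] if len(corrupted) else cand
        if cand.empty or rate == 0.0:
            return cand.iloc[:0]
        keep = rng.random(len(cand)) < rate
        return cand[keep]

    def _record(rows: pd.DataFrame, tag: str) -> None:
        for r in rows.itertuples():
            key = (r.participant, int(r.trial_id))
            corrupted.add(key)
            ledger_rows.append(
                {"participant": r.participant, "trial_id": int(r.trial_id), "tag": tag}
            )
            i = r.Index
            flags = trials.at[i, "corruption_flags"]
            trials.at[i, "corruption_flags"] = tag if not flags else flags + ";" + tag

    for tag in VALID_CRITERIA:
        rate = float(rates.get(tag, 0.0))
        if rate == 0.0:
            continue
        if tag == "a":
            rows = _pick(pd.Series(True, index=trials.index), rate)
            trials.loc[rows.index, "test_measured_n"] = 1.5
            _record(rows, tag)
        elif tag == "b":
            rows = _pick(reaching, rate)
            for r in rows.itertuples():
                key = (r.participant, int(r.trial_id))
                if out.traces is not None and key in out.traces:
                    tr = out.traces[key]
                    tr = KinematicTrace(
                        t_ms=tr.t_ms.copy(),
                        position_cm=tr.position_cm.copy(),
                        tap_force_n=None
                        if tr.tap_force_n is None
                        else np.zeros_like(tr.tap_force_n),
                        distance_trigger_ms=None,
                        distortion=tr.distortion.copy(),
                        events=dict(tr.events),
                        condition=tr.condition,
                    )
                    out.traces[key] = tr
                if lm_index is not None:
                    for col in ("offset_ms", "ascend85_ms", "descend85_ms"):
                        lm_index.loc[key, col] = np.nan
            _record(rows, tag)
        elif tag == "c":
            rows = _pick(reaching, rate)
            for r in rows.itertuples():
                key = (r.participant, int(r.trial_id))
                if out.traces is not None and key in out.traces:
                    tr = out.traces[key]
                    pos = tr.position_cm.copy()
                    pos[:, 0] -= 6.0
                    out.traces[key] = KinematicTrace(
                        t_ms=tr.t_ms.copy(), position_cm=pos,
                        tap_force_n=None if tr.tap_force_n is None else tr.tap_force_n.copy(),
                        distance_trigger_ms=tr.distance_trigger_ms,
                        distortion=tr.distortion.copy(), events=dict(tr.events),
                        condition=tr.condition,
                    )
                if lm_index is not None:
                    lm_index.loc[key, "start_x_cm"] = (
                        lm_index.loc[key, "start_x_cm"] - 6.0
                    )
            _record(rows, tag)
        elif tag == "d":
            rows = _pick(reaching & timed, rate)
            for r in rows.itertuples():
                key = (r.participant, int(r.trial_id))
                offset = (
                    float(lm_index.loc[key, "offset_ms"])
                    if lm_index is not None
                    else np.nan
                )
                if np.isfinite(offset) and offset - 30.0 > trials.at[r.Index, "test_time_ms"]:
                    trials.at[r.Index, "comparison_time_ms"] = offset - 30.0
                else:
                    rows = rows.drop(index=r.Index)
            _record(rows, tag)
        elif tag == "e":
            rows = _pick(reaching & timed, rate)
            for r in rows.itertuples():
                key = (r.participant, int(r.trial_id))
                onset = (
                    float(lm_index.loc[key, "onset_ms"])
                    if lm_index is not None
                    else np.nan
                )
                if np.isfinite(onset) and onset - 60.0 > 30.0:
                    trials.at[r.Index, "test_time_ms"] = onset - 60.0
                else:
                    rows = rows.drop(index=r.Index)
            _record(rows, tag)
        elif tag == "f":
            rows = _pick(reaching, rate)
            for r in rows.itertuples():
                key = (r.participant, int(r.trial_id))
                if out.traces is not None and key in out.traces:
                    tr = out.traces[key]
                    dist = tr.distortion.copy()
                    peak = float(lm_index.loc[key, "peak_time_ms"])
                    dist[(tr.t_ms >= peak - 20.0) & (tr.t_ms <= peak + 20.0)] = True
                    out.traces[key] = KinematicTrace(
                        t_ms=tr.t_ms.copy(), position_cm=tr.position_cm.copy(),
                        tap_force_n=None if tr.tap_force_n is None else tr.tap_force_n.copy(),
                        distance_trigger_ms=tr.distance_trigger_ms,
                        distortion=dist, events=dict(tr.events),
                        condition=tr.condition,
                    )
                if lm_index is not None:
                    lm_index.loc[key, "distortion_overlap"] = True
            _record(rows, tag)

    if lm_index is not None:
        out.landmarks = lm_index.reset_index()[LANDMARK_COLUMNS]
    ledger = pd.DataFrame(ledger_rows, columns=["participant", "trial_id", "tag"])
    out.manifest["corruption_ledger"] = ledger.to_dict("records")
    return out, ledger
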