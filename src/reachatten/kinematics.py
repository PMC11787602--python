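"""Kinematic preprocessing and segmentation of reaching trials.

Implements the standard velocity-threshold analysis of point-to-point
reaches recorded with a motion tracker at 240 Hz: position smoothing, 3D
speed, movement onset (speed > 5 cm/s sustained for 100 ms), movement offset
(first 0.3 N crossing on the tap force sensor, or the distance-sensor
trigger), a peak-velocity search restricted to the first 67% of the
movement, the 85%-of-peak crossings that delimit the peak-velocity phase,
and the binning of test-force times into early / mid / late phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SegmentationParams

__all__ = [
    "KinematicTrace",
    "SegmentedTrial",
    "KinematicsError",
    "NoOnsetError",
    "NoOffsetError",
    "smooth_positions",
    "compute_speed",
    "detect_movement_onset",
    "detect_reach_offset",
    "find_peak_velocity",
    "compute_phase_crossings",
    "bin_trial",
    "segment_trial",
    "segment_cohort",
    "SEGMENTATION_COLUMNS",
]


class KinematicsError(RuntimeError):
    """Base class for segmentation failures (the trial is later rejected)."""


class NoOnsetError(KinematicsError):
    """No sustained supra-threshold speed run was found."""


class NoOffsetError(KinematicsError):
    """No tap-force crossing / distance trigger was found."""


@dataclass
class KinematicTrace:
    """One reaching trial's 240 Hz kinematic record.

    Times are in ms relative to the go-cue (t = 0). ``tap_force_n`` holds
    the force on the tap sensor (self-touch condition); in the
    no-self-touch condition it is None and ``distance_trigger_ms`` holds the
    time at which the distance sensor fired.
    """

    t_ms: np.ndarray
    position_cm: np.ndarray  # (n, 3)
    tap_force_n: np.ndarray | None = None
    distance_trigger_ms: float | None = None
    distortion: np.ndarray | None = None
    events: dict = field(default_factory=dict)
    condition: str = "self_touch"

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.position_cm = np.asarray(self.position_cm, dtype=float)
        if self.position_cm.ndim != 2 or self.position_cm.shape[1] != 3:
            raise ValueError("position_cm must have shape (n, 3)")
        if self.position_cm.shape[0] != self.t_ms.shape[0]:
            raise ValueError("t_ms and position_cm must have equal length")
        if self.t_ms.size >= 2:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
        if self.distortion is None:
            self.distortion = np.zeros(self.t_ms.shape[0], dtype=bool)
        else:
            self.distortion = np.asarray(self.distortion, dtype=bool)
        if self.tap_force_n is not None:
            self.tap_force_n = np.asarray(self.tap_force_n, dtype=float)
            if self.tap_force_n.shape[0] != self.t_ms.shape[0]:
                raise ValueError("tap_force_n must match trace length")

    @property
    def dt_ms(self) -> float:
        return float(np.mean(np.diff(self.t_ms)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dt = np.diff(self.t_ms)
        return bool(dt.size == 0 or np.allclose(dt, dt[0], rtol=rtol, atol=1e-9))

    def shifted(self, delta_ms: float) -> "KinematicTrace":
        """Copy of the trace translated in time by ``delta_ms``."""
        return replace(
            self,
            t_ms=self.t_ms + delta_ms,
            position_cm=self.position_cm.copy(),
            tap_force_n=None if self.tap_force_n is None else self.tap_force_n.copy(),
            distance_trigger_ms=None
            if self.distance_trigger_ms is None
            else self.distance_trigger_ms + delta_ms,
            distortion=self.distortion.copy(),
            events={k: v + delta_ms for k, v in self.events.items()},
        )


@dataclass
class SegmentedTrial:
    """Kinematic landmarks and phase label of one reaching trial."""

    onset_ms: float = np.nan
    offset_ms: float = np.nan
    peak_time_ms: float = np.nan
    peak_speed_cms: float = np.nan
    ascend85_ms: float = np.nan
    descend85_ms: float = np.nan
    label: str = "invalid"
    invalid_reason: str | None = None
    percent_time: float = np.nan
    start_x_cm: float = np.nan
    moved_before_cue: bool = False
    distortion_overlap: bool = False

    @property
    def movement_duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


SEGMENTATION_COLUMNS = [
    "participant",
    "trial_id",
    "onset_ms",
    "offset_ms",
    "movement_duration_ms",
    "peak_time_ms",
    "peak_speed_cms",
    "ascend85_ms",
    "descend85_ms",
    "label",
    "invalid_reason",
    "percent_time",
    "start_x_cm",
    "moved_before_cue",
    "distortion_overlap",
]


def smooth_positions(trace: KinematicTrace, params: SegmentationParams) -> KinematicTrace:
    """Centered moving average (span ``smooth_span``) applied per coordinate.

    Output length equals input length; the first and last ``span // 2``
    samples use a symmetric shrinking window. Timestamps are unchanged.
    """
    span = params.smooth_span
    n = trace.t_ms.shape[0]
    if n < span:
        raise KinematicsError(f"trace of length {n} shorter than smooth span {span}")
    if span == 1:
        return replace(trace, position_cm=trace.position_cm.copy())
    half = span // 2
    pos = trace.position_cm
    csum = np.vstack([np.zeros((1, 3)), np.cumsum(pos, axis=0)])
    out = np.empty_like(pos)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    # shrink symmetrically at the edges so the window stays centered
    width = np.minimum(idx - lo, hi - idx)
    lo = idx - width
    hi = idx + width
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]
    return replace(trace, position_cm=out)


def compute_speed(trace: KinematicTrace) -> np.ndarray:
    """3D speed (cm/s): Euclidean norm of the time derivative of position.

    Central differences on interior samples, one-sided at the edges.
    Requires uniform timestamps.
    """
    if not trace.is_uniform():
        raise KinematicsError("compute_speed requires uniformly sampled timestamps")
    t_s = trace.t_ms / 1000.0
    vel = np.gradient(trace.position_cm, t_s, axis=0)
    return np.linalg.norm(vel, axis=1)


def _interp_crossing(t0, t1, v0, v1, level) -> float:
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def detect_movement_onset(
    t_ms: np.ndarray,
    speed: np.ndarray,
    params: SegmentationParams,
    search_from_ms: float = 0.0,
) -> float:
    """First time the speed exceeds the onset threshold for the full hold.

    Returns the time of the first sample ``i`` (at or after
    ``search_from_ms``) such that every sample in ``[i, i + hold)`` is above
    threshold, where the hold is 100 ms of consecutive samples (24 at
    240 Hz). With ``interpolate_crossings`` the returned time is the linear
    interpolation of the upward threshold crossing immediately before that
    sample.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    speed = np.asarray(speed, dtype=float)
    hold = params.onset_hold_samples
    above = speed > params.onset_speed_threshold
    n = speed.shape[0]
    if n < hold:
        raise NoOnsetError("trace shorter than the onset hold window")
    # windowed count of above-threshold samples: a start index qualifies when
    # all `hold` samples from it are above threshold
    csum = np.concatenate([[0], np.cumsum(above)])
    full_run = (csum[hold:] - csum[:-hold]) == hold
    eligible = full_run & (t_ms[: n - hold + 1] >= search_from_ms)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise NoOnsetError("no sustained supra-threshold speed run found")
    i = int(idx[0])
    if (
        params.interpolate_crossings
        and i > 0
        and speed[i - 1] <= params.onset_speed_threshold
        and t_ms[i - 1] >= search_from_ms
    ):
        return _interp_crossing(
            t_ms[i - 1], t_ms[i], speed[i - 1], speed[i], params.onset_speed_threshold
        )
    return float(t_ms[i])


def detect_reach_offset(
    trace: KinematicTrace, onset_ms: float, params: SegmentationParams
) -> float:
    """Movement offset: first tap-force crossing after onset, or the trigger.

    Self-touch condition: the first upward crossing of the tap-force
    threshold (0.3 N) after movement onset. No-self-touch condition: the
    recorded distance-sensor trigger time.
    """
    if trace.condition == "no_self_touch":
        if trace.distance_trigger_ms is None:
            raise NoOffsetError("distance sensor was not triggered")
        return float(trace.distance_trigger_ms)
    if trace.tap_force_n is None:
        raise NoOffsetError("no tap-force series recorded")
    force = trace.tap_force_n
    thr = params.tap_force_threshold
    after = trace.t_ms > onset_ms
    crossing = after & (force > thr)
    idx = np.flatnonzero(crossing)
    if idx.size == 0:
        raise NoOffsetError("tap force never exceeded threshold after onset")
    i = int(idx[0])
    if params.interpolate_crossings and i > 0 and force[i - 1] <= thr:
        return _interp_crossing(trace.t_ms[i - 1], trace.t_ms[i], force[i - 1], force[i], thr)
    return float(trace.t_ms[i])


def find_peak_velocity(
    t_ms: np.ndarray,
    speed: np.ndarray,
    onset_ms: float,
    offset_ms: float,
    params: SegmentationParams,
) -> tuple[float, float]:
    """Peak speed within the first ``peak_window_fraction`` of the movement.

    Restricting the search window to 67% of the movement duration captures
    the transport peak and not the terminal tap. Ties break to the earliest
    sample.
    """
    if not onset_ms < offset_ms:
        raise KinematicsError("onset must precede offset")
    window_end = onset_ms + params.peak_window_fraction * (offset_ms - onset_ms)
    mask = (t_ms >= onset_ms) & (t_ms <= window_end)
    if not np.any(mask):
        raise KinematicsError("empty peak-velocity search window")
    idx = np.flatnonzero(mask)
    sub = speed[idx]
    j = int(idx[int(np.argmax(sub))])  # np.argmax returns the first maximum
    return float(t_ms[j]), float(speed[j])


def compute_phase_crossings(
    t_ms: np.ndarray,
    speed: np.ndarray,
    onset_ms: float,
    offset_ms: float,
    peak_time_ms: float,
    peak_speed_cms: float,
    params: SegmentationParams,
) -> tuple[float, float]:
    """85%-of-peak crossings delimiting the peak-velocity phase.

    ``ascend85``: first time in [onset, peak] with speed >= 85% of the peak.
    ``descend85``: first time after the peak with speed < 85% of the peak;
    if the speed never drops below the level before the offset, the offset
    is returned.
    """
    level = params.phase_velocity_fraction * peak_speed_cms
    t_ms = np.asarray(t_ms, dtype=float)
    speed = np.asarray(speed, dtype=float)

    up_mask = (t_ms >= onset_ms) & (t_ms <= peak_time_ms) & (speed >= level)
    idx = np.flatnonzero(up_mask)
    if idx.size == 0:
        ascend = peak_time_ms
    else:
        i = int(idx[0])
        if params.interpolate_crossings and i > 0 and speed[i - 1] < level:
            ascend = _interp_crossing(t_ms[i - 1], t_ms[i], speed[i - 1], speed[i], level)
        else:
            ascend = float(t_ms[i])
    ascend = max(ascend, onset_ms)

    down_mask = (t_ms > peak_time_ms) & (speed < level)
    idx = np.flatnonzero(down_mask)
    descend = None
    if idx.size > 0:
        i = int(idx[0])
        if t_ms[i] <= offset_ms:
            if params.interpolate_crossings and i > 0 and speed[i - 1] >= level:
                descend = _interp_crossing(
                    t_ms[i - 1], t_ms[i], speed[i - 1], speed[i], level
                )
            else:
                descend = float(t_ms[i])
    if descend is None or descend > offset_ms:
        descend = float(offset_ms)
    descend = max(descend, ascend)
    return float(ascend), float(descend)


def bin_trial(
    scheduled_type: str,
    test_time_ms: float,
    seg: SegmentedTrial,
) -> tuple[str, str | None, float]:
    """Map a trial's test-force time to its phase label.

    Hardware-triggered trials keep their provenance labels (``target``,
    ``post_reach``). Time-scheduled trials are binned by where the test
    force fell within [onset, offset): [onset, ascend85) -> early,
    [ascend85, descend85) -> mid, [descend85, offset) -> late. A test force
    before onset or at/after the offset invalidates the trial (criterion e).

    Returns (label, invalid_reason, percent_time).
    """
    if scheduled_type in ("target", "post_reach"):
        pct = 100.0 if scheduled_type == "target" else np.nan
        return scheduled_type, None, pct
    needed = (seg.onset_ms, seg.ascend85_ms, seg.descend85_ms, seg.offset_ms)
    if any(not np.isfinite(v) for v in needed):
        return "invalid", "b", np.nan
    if np.isnan(test_time_ms):
        return "invalid", "a", np.nan
    if test_time_ms < seg.onset_ms or test_time_ms >= seg.offset_ms:
        return "invalid", "e", np.nan
    pct = 100.0 * (test_time_ms - seg.onset_ms) / (seg.offset_ms - seg.onset_ms)
    if test_time_ms < seg.ascend85_ms:
        return "early", None, pct
    if test_time_ms < seg.descend85_ms:
        return "mid", None, pct
    return "late", None, pct


def segment_trial(
    trace: KinematicTrace,
    scheduled_type: str,
    test_time_ms: float,
    params: SegmentationParams,
) -> SegmentedTrial:
    """Full segmentation of one reaching trial.

    Smoothing, speed, onset/offset detection, constrained peak search and
    85% crossings; on failure the trial is returned with an invalid label
    and the exclusion-criterion tag that the failure maps onto. Also
    computes the auxiliary quantities that the quality-control filters
    inspect (start position, pre-cue movement, distortion overlap).
    """
    seg = SegmentedTrial()
    pre = trace.t_ms < 0
    seg.start_x_cm = float(
        np.mean(trace.position_cm[pre, 0]) if np.any(pre) else trace.position_cm[0, 0]
    )
    try:
        smoothed = smooth_positions(trace, params)
        speed = compute_speed(smoothed)
    except KinematicsError:
        seg.invalid_reason = "a"
        return seg
    try:
        onset = detect_movement_onset(trace.t_ms, speed, params, search_from_ms=trace.t_ms[0])
        if onset < 0.0:
            seg.moved_before_cue = True
            onset = detect_movement_onset(trace.t_ms, speed, params, search_from_ms=0.0)
        seg.onset_ms = onset
        seg.offset_ms = detect_reach_offset(trace, onset, params)
        seg.peak_time_ms, seg.peak_speed_cms = find_peak_velocity(
            trace.t_ms, speed, onset, seg.offset_ms, params
        )
        seg.ascend85_ms, seg.descend85_ms = compute_phase_crossings(
            trace.t_ms, speed, onset, seg.offset_ms, seg.peak_time_ms,
            seg.peak_speed_cms, params,
        )
    except KinematicsError:
        seg.label = "invalid"
        seg.invalid_reason = "b"
        return seg
    if trace.distortion is not None and np.any(trace.distortion):
        win = (trace.t_ms >= seg.onset_ms - params.distortion_pre_ms) & (
            trace.t_ms <= seg.offset_ms + params.distortion_post_ms
        )
        seg.distortion_overlap = bool(np.any(trace.distortion & win))
    seg.label, seg.invalid_reason, seg.percent_time = bin_trial(
        scheduled_type, test_time_ms, seg
    )
    return seg


def segment_cohort(cohort, params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segmentation table for every reaching trial of a cohort.

    Uses the 240 Hz traces when present; for landmark-mode cohorts (no
    traces) the generator's analytically derived landmarks are re-binned
    with the same rules, so the downstream pipeline is identical.
    """
    params = params or SegmentationParams()
    trials = cohort.trials
    reaching = trials[trials["block"] == "reaching"]
    if cohort.traces is None:
        if cohort.landmarks is None:
            raise KinematicsError("cohort has neither traces nor landmarks")
        return _segment_from_landmark_table(reaching, cohort.landmarks)
    rows: list[dict] = []
    for rec in reaching.itertuples():
        key = (rec.participant, rec.trial_id)
        trace = cohort.traces.get(key)
        if trace is None:
            seg = SegmentedTrial(invalid_reason="missing")
        else:
            seg = segment_trial(trace, rec.scheduled_type, rec.test_time_ms, params)
        rows.append(
            {
                "participant": rec.participant,
                "trial_id": rec.trial_id,
                "onset_ms": seg.onset_ms,
                "offset_ms": seg.offset_ms,
                "movement_duration_ms": seg.movement_duration_ms,
                "peak_time_ms": seg.peak_time_ms,
                "peak_speed_cms": seg.peak_speed_cms,
                "ascend85_ms": seg.ascend85_ms,
                "descend85_ms": seg.descend85_ms,
                "label": seg.label,
                "invalid_reason": seg.invalid_reason,
                "percent_time": seg.percent_time,
                "start_x_cm": seg.start_x_cm,
                "moved_before_cue": seg.moved_before_cue,
                "distortion_overlap": seg.distortion_overlap,
            }
        )
    return pd.DataFrame(rows, columns=SEGMENTATION_COLUMNS)


def _segment_from_landmark_table(
    reaching: pd.DataFrame, landmarks: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized binning when analytic landmarks stand in for traces."""
    m = reaching[["participant", "trial_id", "scheduled_type", "test_time_ms"]].merge(
        landmarks, on=["participant", "trial_id"], how="left"
    )
    onset = m["onset_ms"].to_numpy(dtype=float)
    offset = m["offset_ms"].to_numpy(dtype=float)
    ascend = m["ascend85_ms"].to_numpy(dtype=float)
    descend = m["descend85_ms"].to_numpy(dtype=float)
    test = m["test_time_ms"].to_numpy(dtype=float)
    kind = m["scheduled_type"].to_numpy()
    in_lm = m["peak_time_ms"].notna().to_numpy() | m["onset_ms"].notna().to_numpy()
    hardware = np.isin(kind, ("target", "post_reach"))
    landmarks_ok = np.isfinite(onset) & np.isfinite(offset) & np.isfinite(ascend) & np.isfinite(descend)
    out_of_reach = landmarks_ok & ~hardware & ((test < onset) | (test >= offset))
    label = np.select(
        [
            ~in_lm,
            hardware & (kind == "target"),
            hardware & (kind == "post_reach"),
            ~landmarks_ok,
            out_of_reach,
            landmarks_ok & (test < ascend),
            landmarks_ok & (test < descend),
        ],
        ["invalid", "target", "post_reach", "invalid", "invalid", "early", "mid"],
        default="late",
    )
    reason = np.select(
        [~in_lm, hardware, ~landmarks_ok, out_of_reach],
        ["missing", "", "b", "e"],
        default="",
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (test - onset) / (offset - onset)
    pct = np.where(np.isin(label, ("early", "mid", "late")), pct, np.nan)
    pct = np.where(label == "target", 100.0, pct)
    out = pd.DataFrame(
        {
            "participant": m["participant"],
            "trial_id": m["trial_id"],
            "onset_ms": onset,
            "offset_ms": offset,
            "movement_duration_ms": offset - onset,
            "peak_time_ms": m["peak_time_ms"].to_numpy(dtype=float),
            "peak_speed_cms": m["peak_speed_cms"].to_numpy(dtype=float),
            "ascend85_ms": ascend,
            "descend85_ms": descend,
            "label": label,
            "invalid_reason": pd.Series(reason).replace("", None),
            "percent_time": pct,
            "start_x_cm": m.get("start_x_cm", pd.Series(np.nan, index=m.index)),
            "moved_before_cue": m.get(
                "moved_before_cue", pd.Series(False, index=m.index)
            ).fillna(False).astype(bool),
            "distortion_overlap": m.get(
                "distortion_overlap", pd.Series(False, index=m.index)
            ).fillna(False).astype(bool),
        },
        columns=SEGMENTATION_COLUMNS,
    )
    return out
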