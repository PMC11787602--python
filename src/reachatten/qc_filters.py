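"""Trial- and participant-level exclusion criteria with a full audit log.

Trial-level criteria (tags match the experiment's exclusion rules):

a. the 2 N test force was not properly applied (measured force outside
   [1.85, 2.15] N), or the response / kinematic data were not registered;
b. the tap (or distance-sensor trigger) failed, or movement onset/offset
   could not be segmented;
c. the participant moved before the auditory go-cue, or started the trial
   from a position displaced toward the sensor (>= 5 cm on x from the
   configured starting position);
d. the comparison force was delivered while the hand was still moving
   (before movement offset);
e. a time-scheduled test force fell before movement onset or after the tap;
f. the motion sensor was inside the electromagnetic distortion range at
   times used for segmentation.

All criteria are evaluated independently and tags accumulate, so the audit
is order-free. Participant-level rules: missing kinematics, fewer than 10
retained trials in any reaching trial type, or >= 95% identical responses
within any trial type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import REACHING_TYPES, DesignConfig

__all__ = [
    "ExclusionRule",
    "QcReport",
    "apply_trial_exclusions",
    "apply_participant_exclusions",
    "DEFAULT_RULES",
]


@dataclass(frozen=True)
class ExclusionRule:
    """Parameters of the trial-level exclusion criteria."""

    force_window_n: tuple[float, float] = (1.85, 2.15)
    start_displacement_cm: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.force_window_n
        if not lo < hi:
            raise ValueError("force window must satisfy lo < hi")
        if self.start_displacement_cm <= 0:
            raise ValueError("start_displacement_cm must be > 0")


DEFAULT_RULES = ExclusionRule()


@dataclass
class QcReport:
    """Per-trial decisions, per-type retained counts and cohort totals."""

    decisions: pd.DataFrame
    retained_trials: pd.DataFrame
    n_total: int
    n_rejected: int
    tag_counts: dict = field(default_factory=dict)

    @property
    def rejection_fraction(self) -> float:
        return self.n_rejected / self.n_total if self.n_total else 0.0

    def retained_counts(self) -> pd.DataFrame:
        """Retained trials per participant x phase label."""
        return (
            self.retained_trials.groupby(["participant", "label"], observed=False)
            .size()
            .unstack(fill_value=0)
        )

    def to_dict(self) -> dict:
        return {
            "n_total": int(self.n_total),
            "n_rejected": int(self.n_rejected),
            "rejection_fraction": float(self.rejection_fraction),
            "tag_counts": {k: int(v) for k, v in self.tag_counts.items()},
        }


def apply_trial_exclusions(
    trials: pd.DataFrame,
    segmentation: pd.DataFrame,
    design: DesignConfig | None = None,
    rules: ExclusionRule = DEFAULT_RULES,
    start_x_cm: float = 25.0,
) -> QcReport:
    """Evaluate criteria (a)-(f) on every trial and drop the tagged ones.

    ``segmentation`` is the per-reaching-trial landmark table produced by
    :func:`reachatten.kinematics.segment_cohort`. A reaching trial with no
    segmentation row counts as unregistered kinematics (criterion a); one
    whose onset/offset could not be derived carries criterion b. Baseline
    trials are only subject to criterion a. Retained trials are returned
    with their phase label and percent reach time attached.
    """
    design = design or DesignConfig()
    seg_cols = [
        "participant", "trial_id", "onset_ms", "offset_ms", "label",
        "invalid_reason", "percent_time", "start_x_cm", "moved_before_cue",
        "distortion_overlap",
    ]
    merged = trials.merge(
        segmentation[seg_cols], on=["participant", "trial_id"], how="left"
    )
    reaching = (merged["block"] == "reaching").to_numpy()
    timed = merged["scheduled_type"].isin(design.timed_kinds).to_numpy()
    # a reaching trial can miss its segmentation row entirely, or carry an
    # explicit 'missing' marker: either way its kinematics were not registered
    seg_missing = reaching & merged["label"].isna().to_numpy()
    unregistered = merged["invalid_reason"].fillna("") == "missing"

    lo, hi = rules.force_window_n
    test = merged["test_measured_n"].to_numpy(dtype=float)
    tag_a = (
        (test < lo)
        | (test > hi)
        | ~np.isfinite(test)
        | merged["response"].isna().to_numpy()
        | (reaching & (seg_missing | unregistered.to_numpy()))
    )
    onset = merged["onset_ms"].to_numpy(dtype=float)
    offset = merged["offset_ms"].to_numpy(dtype=float)
    landmarks_bad = ~np.isfinite(onset) | ~np.isfinite(offset)
    tag_b = reaching & ~seg_missing & ~unregistered.to_numpy() & landmarks_bad

    start_x = merged["start_x_cm"].to_numpy(dtype=float)
    displaced = np.isfinite(start_x) & (
        np.abs(start_x - start_x_cm) >= rules.start_displacement_cm
    )
    moved_early = (
        merged["moved_before_cue"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    )
    tag_c = reaching & (moved_early | displaced)

    comp_t = merged["comparison_time_ms"].to_numpy(dtype=float)
    tag_d = reaching & np.isfinite(offset) & (comp_t < offset)

    tag_e = (
        reaching
        & timed
        & (merged["invalid_reason"].fillna("") == "e").to_numpy()
    )
    tag_f = reaching & (
        merged["distortion_overlap"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    )

    tag_matrix = {"a": tag_a, "b": tag_b, "c": tag_c, "d": tag_d, "e": tag_e, "f": tag_f}
    rejected = np.zeros(len(merged), dtype=bool)
    tags = np.array([""] * len(merged), dtype=object)
    for tag, mask in tag_matrix.items():
        rejected |= mask
        tags[mask] = np.where(tags[mask] == "", tag, tags[mask] + ";" + tag)

    decisions = merged[["participant", "trial_id", "block", "scheduled_type"]].copy()
    decisions["tags"] = tags
    decisions["rejected"] = rejected

    retained = merged[~rejected].copy()
    retained["label"] = np.where(
        retained["block"] == "baseline", "baseline", retained["label"]
    )
    report = QcReport(
        decisions=decisions,
        retained_trials=retained,
        n_total=len(merged),
        n_rejected=int(rejected.sum()),
        tag_counts={tag: int(mask.sum()) for tag, mask in tag_matrix.items()},
    )
    return report


def apply_participant_exclusions(
    retained_trials: pd.DataFrame,
    min_trials_per_type: int = 10,
    same_response_limit: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants whose retained data cannot support reliable fits.

    A participant is excluded when (i) no reaching trial has usable
    kinematics, (ii) any reaching trial type retains fewer than
    ``min_trials_per_type`` trials, or (iii) at least
    ``same_response_limit`` of the responses within any trial type are
    identical (an unreliable, near-separated psychometric fit).

    Returns (retained trials, exclusion log).
    """
    log_rows: list[dict] = []
    all_parts = list(pd.unique(retained_trials["participant"]))
    reach = retained_trials[
        (retained_trials["block"] == "reaching")
        & retained_trials["label"].isin(REACHING_TYPES)
    ]
    counts = (
        reach.groupby(["participant", "label"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=REACHING_TYPES, fill_value=0)
        .reindex(all_parts, fill_value=0)
    )
    labelled = retained_trials[retained_trials["label"].notna()]
    labelled = labelled[labelled["label"] != "invalid"]
    resp = (
        labelled.groupby(["participant", "label", "response"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    frac = resp.div(resp.sum(axis=1), axis=0).max(axis=1)
    keep_parts: list[str] = []
    for pid in all_parts:
        row = counts.loc[pid]
        if row.sum() == 0:
            log_rows.append({"participant": pid, "reason": "missing_kinematics"})
            continue
        short = [t for t in REACHING_TYPES if row[t] < min_trials_per_type]
        if short:
            log_rows.append(
                {"participant": pid, "reason": f"too_few_trials:{','.join(short)}"}
            )
            continue
        f = frac.loc[pid] if pid in frac.index.get_level_values(0) else pd.Series(dtype=float)
        monotone = sorted(str(lbl) for lbl, v in f.items() if v >= same_response_limit)
        if monotone:
            log_rows.append(
                {"participant": pid, "reason": f"same_response:{','.join(monotone)}"}
            )
            continue
        keep_parts.append(pid)
    retained = retained_trials[retained_trials["participant"].isin(keep_parts)].copy()
    log = pd.DataFrame(log_rows, columns=["participant", "reason"])
    return retained, log
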