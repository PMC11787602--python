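"""Serialization of cohorts and ingestion of externally supplied tables.

A cohort on disk is a directory of plain-text files:

* ``trials.csv`` — one row per discrimination trial (see
  :data:`reachatten.synthetic_data.TRIAL_COLUMNS`);
* ``landmarks.csv`` — per-reaching-trial kinematic landmarks (optional);
* ``participants.csv`` — per-participant generative/identity parameters;
* ``manifest.json`` — seeds, design, provenance, corruption ledger;
* ``traces/`` — optional per-trial 240 Hz kinematics
  (``trace_<participant>_<trial>.csv``) with a JSON sidecar of events.

Externally supplied data in the same trial-table dialect can be ingested
with row-level validation; tables that already carry phase labels
(pre-binned) let the pipeline resume at the psychometric stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DesignConfig
from .kinematics import KinematicTrace
from .synthetic_data import Cohort, LANDMARK_COLUMNS, TRIAL_COLUMNS

__all__ = ["write_cohort", "read_cohort", "ingest_trials", "SchemaError"]

_VALID_RESPONSES = {"test_stronger", "comparison_stronger", ""}
_VALID_BLOCKS = {"reaching", "baseline"}


class SchemaError(ValueError):
    pass


def write_cohort(cohort: Cohort, path, include_traces: bool = False) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.trials.to_csv(path / "trials.csv", index=False)
    cohort.participants.to_csv(path / "participants.csv", index=False)
    if cohort.landmarks is not None:
        cohort.landmarks.to_csv(path / "landmarks.csv", index=False)
    manifest = dict(cohort.manifest)
    manifest["design"] = dataclasses.asdict(cohort.design)
    manifest["has_traces"] = bool(include_traces and cohort.traces)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    if include_traces and cohort.traces:
        tdir = path / "traces"
        tdir.mkdir(exist_ok=True)
        meta = {}
        for (pid, tid), trace in cohort.traces.items():
            name = f"trace_{pid}_{tid}"
            df = pd.DataFrame(
                {
                    "t_ms": trace.t_ms,
                    "x_cm": trace.position_cm[:, 0],
                    "y_cm": trace.position_cm[:, 1],
                    "z_cm": trace.position_cm[:, 2],
                    "tap_force_n": trace.tap_force_n
                    if trace.tap_force_n is not None
                    else np.nan,
                    "distortion": trace.distortion.astype(int),
                }
            )
            df.to_csv(tdir / f"{name}.csv", index=False)
            meta[name] = {
                "condition": trace.condition,
                "distance_trigger_ms": trace.distance_trigger_ms,
                "events": trace.events,
            }
        with open(tdir / "meta.json", "w") as fh:
            json.dump(meta, fh, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_cohort(path) -> Cohort:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    design_kwargs = manifest.pop("design", {})
    for key in ("comparison_intensities", "scheduled_force_times_ms"):
        if key in design_kwargs:
            design_kwargs[key] = tuple(design_kwargs[key])
    design = DesignConfig(**design_kwargs) if design_kwargs else DesignConfig()
    trials = pd.read_csv(path / "trials.csv")
    trials["corruption_flags"] = trials.get(
        "corruption_flags", pd.Series("", index=trials.index)
    ).fillna("")
    participants = pd.read_csv(path / "participants.csv")
    landmarks = None
    if (path / "landmarks.csv").exists():
        landmarks = pd.read_csv(path / "landmarks.csv")
    traces = None
    tdir = path / "traces"
    if manifest.get("has_traces") and tdir.exists():
        with open(tdir / "meta.json") as fh:
            meta = json.load(fh)
        traces = {}
        for name, info in meta.items():
            _, pid, tid = name.split("_")
            df = pd.read_csv(tdir / f"{name}.csv")
            tap = df["tap_force_n"].to_numpy()
            traces[(pid, int(tid))] = KinematicTrace(
                t_ms=df["t_ms"].to_numpy(),
                position_cm=df[["x_cm", "y_cm", "z_cm"]].to_numpy(),
                tap_force_n=None if np.all(np.isnan(tap)) else tap,
                distance_trigger_ms=info.get("distance_trigger_ms"),
                distortion=df["distortion"].to_numpy().astype(bool),
                events=info.get("events", {}),
                condition=info.get("condition", "self_touch"),
            )
    return Cohort(
        trials=trials,
        participants=participants,
        landmarks=landmarks,
        traces=traces,
        design=design,
        manifest=manifest,
    )


def ingest_trials(
    trials_path,
    landmarks_path=None,
    design: DesignConfig | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Ingest an externally supplied trial table with row-level validation.

    Malformed rows are skipped and reported (file line number, message);
    well-formed rows are loaded. The returned cohort has no kinematic
    traces; when a landmark table is supplied the pipeline can segment and
    QC from it, and when the trial table already carries ``label`` (and
    optionally ``percent_time``) columns the analysis resumes at the
    psychometric stage.
    """
    design = design or DesignConfig()
    trials = pd.read_csv(trials_path)
    required = [
        "participant", "trial_id", "block", "scheduled_type",
        "comparison_measured_n", "test_measured_n", "response",
    ]
    missing = [c for c in required if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table lacks required columns: {missing}")
    errors: list[dict] = []
    keep = np.ones(len(trials), dtype=bool)
    for i, row in trials.iterrows():
        line = i + 2  # header is line 1
        problems = []
        if row["block"] not in _VALID_BLOCKS:
            problems.append(f"invalid block {row['block']!r}")
        resp = row["response"] if isinstance(row["response"], str) else ""
        if resp not in _VALID_RESPONSES:
            problems.append(f"invalid response {row['response']!r}")
        for col in ("comparison_measured_n", "test_measured_n"):
            val = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if not np.isfinite(val) or not 0.0 < val < 20.0:
                problems.append(f"malformed {col}: {row[col]!r}")
        if problems:
            keep[i] = False
            errors.append({"line": line, "message": "; ".join(problems)})
    clean = trials[keep].copy()
    for col in ("comparison_measured_n", "test_measured_n"):
        clean[col] = pd.to_numeric(clean[col])
    for col in TRIAL_COLUMNS:
        if col not in clean.columns:
            clean[col] = np.nan if col != "corruption_flags" else ""
    landmarks = None
    if landmarks_path is not None:
        landmarks = pd.read_csv(landmarks_path)
        lm_missing = [c for c in LANDMARK_COLUMNS if c not in landmarks.columns]
        if lm_missing:
            raise SchemaError(f"landmark table lacks columns: {lm_missing}")
    participants = pd.DataFrame(
        {"participant": sorted(clean["participant"].unique())}
    )
    cohort = Cohort(
        trials=clean.reset_index(drop=True),
        participants=participants,
        landmarks=landmarks,
        traces=None,
        design=design,
        manifest={"source": str(trials_path), "ingest_errors": errors},
    )
    return cohort, pd.DataFrame(errors, columns=["line", "message"])
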