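"""Cohort persistence: CSV metadata plus HDF5 traces.

On-disk layout of a cohort directory::

    metadata.csv        participant, trial, condition, coherence, direction,
                        onset_time, target_speed
    traces.h5           group <participant>/t<trial:04d> with datasets
                        eye_x, eye_y, eye_mask, cursor_x, cursor_y;
                        rates stored as group attributes; root attributes
                        schema_version and provenance
    participants.csv    ground-truth participant parameters (optional)
    ground_truth.csv    ground-truth per-trial scalars (optional)
    events.csv          planted saccade/blink intervals (optional)

Units on disk: deg, deg/s, seconds; coherence as signed fraction; direction
as +-1. Positions round-trip bit-exactly (float64).

Externally recorded data can be imported by writing the same layout; the
column/unit mapping above is the import contract.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .types import CohortData, GroundTruth, Interval, RawTrace, TrialMeta, TrialRecord

SCHEMA_VERSION = "asemlab-cohort-1"

_META_COLUMNS = ["participant", "trial", "condition", "coherence",
                 "direction", "onset_time", "target_speed"]


class CohortIOError(ValueError):
    """Base class for cohort layout problems."""


class MalformedMetadataError(CohortIOError):
    pass


class MissingTraceError(CohortIOError):
    pass


class SchemaVersionError(CohortIOError):
    pass


def _trial_group(participant: str, trial: int) -> str:
    return f"{participant}/t{trial:04d}"


def write_cohort(cohort: CohortData, path, ground_truth: Optional[GroundTruth] = None
                 ) -> None:
    """Write a cohort (and optional ground truth) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.metadata.to_csv(path / "metadata.csv", index=False)

    with h5py.File(path / "traces.h5", "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["provenance"] = json.dumps(cohort.provenance)
        for record in cohort.trials:
            grp = fh.create_group(_trial_group(record.meta.participant,
                                               record.meta.trial))
            grp.attrs["eye_rate"] = record.eye.rate
            grp.attrs["cursor_rate"] = record.cursor.rate
            grp.attrs["eye_t0"] = float(record.eye.time[0])
            grp.attrs["cursor_t0"] = float(record.cursor.time[0])
            grp.create_dataset("eye_x", data=record.eye.x)
            grp.create_dataset("eye_y", data=record.eye.y)
            grp.create_dataset("eye_mask", data=record.eye.mask)
            grp.create_dataset("cursor_x", data=record.cursor.x)
            grp.create_dataset("cursor_y", data=record.cursor.y)

    if ground_truth is not None:
        ground_truth.participants.to_csv(path / "participants.csv", index=False)
        ground_truth.trials.to_csv(path / "ground_truth.csv", index=False)
        rows = []
        for kind, events in (("saccade", ground_truth.saccades),
                             ("blink", ground_truth.blinks)):
            for (pid, trial), intervals in events.items():
                for iv in intervals:
                    rows.append({"participant": pid, "trial": trial,
                                 "kind": kind, "start": iv.start, "end": iv.end})
        pd.DataFrame(rows, columns=["participant", "trial", "kind",
                                    "start", "end"]).to_csv(
            path / "events.csv", index=False)


def read_cohort(path) -> Tuple[CohortData, Optional[GroundTruth]]:
    """Read a cohort directory; validates schema and trace completeness."""
    path = Path(path)
    meta_path = path / "metadata.csv"
    if not meta_path.exists():
        raise MalformedMetadataError(f"no metadata.csv in {path}")
    metadata = pd.read_csv(meta_path)
    missing_cols = [c for c in _META_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise MalformedMetadataError(f"metadata.csv lacks columns {missing_cols}")

    records = []
    with h5py.File(path / "traces.h5", "r") as fh:
        version = fh.attrs.get("schema_version", "")
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"unknown schema version {version!r}, expected {SCHEMA_VERSION!r}")
        provenance = json.loads(fh.attrs.get("provenance", "{}"))
        for row in metadata.itertuples(index=False):
            key = _trial_group(row.participant, int(row.trial))
            if key not in fh:
                raise MissingTraceError(
                    f"no trace group for participant {row.participant} "
                    f"trial {int(row.trial)}")
            grp = fh[key]
            eye_rate = float(grp.attrs["eye_rate"])
            cur_rate = float(grp.attrs["cursor_rate"])
            ex = grp["eye_x"][()]
            eye = RawTrace(
                time=float(grp.attrs.get("eye_t0", 0.0)) + np.arange(len(ex)) / eye_rate,
                x=ex, y=grp["eye_y"][()], rate=eye_rate,
                mask=grp["eye_mask"][()].astype(bool),
            )
            cx = grp["cursor_x"][()]
            cursor = RawTrace(
                time=float(grp.attrs.get("cursor_t0", 0.0)) + np.arange(len(cx)) / cur_rate,
                x=cx, y=grp["cursor_y"][()], rate=cur_rate,
            )
            meta = TrialMeta(
                participant=str(row.participant), trial=int(row.trial),
                condition=str(row.condition), coherence=float(row.coherence),
                direction=int(row.direction), onset_time=float(row.onset_time),
                target_speed=float(row.target_speed),
            )
            records.append(TrialRecord(meta=meta, eye=eye, cursor=cursor))

    cohort = CohortData(trials=records, metadata=metadata, provenance=provenance)

    truth = None
    if (path / "ground_truth.csv").exists():
        trials_df = pd.read_csv(path / "ground_truth.csv")
        if "violation" in trials_df.columns:
            trials_df["violation"] = trials_df["violation"].fillna("")
        participants = (pd.read_csv(path / "participants.csv")
                        if (path / "participants.csv").exists() else pd.DataFrame())
        saccades, blinks = {}, {}
        if (path / "events.csv").exists():
            events = pd.read_csv(path / "events.csv")
            for row in events.itertuples(index=False):
                key = (str(row.participant), int(row.trial))
                target = saccades if row.kind == "saccade" else blinks
                target.setdefault(key, []).append(Interval(row.start, row.end))
        truth = GroundTruth(participants=participants, trials=trials_df,
                            saccades=saccades, blinks=blinks)
    return cohort, truth
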