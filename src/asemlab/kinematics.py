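"""Per-trial scalar features and trial exclusion rules.

ASEM velocity is the mean desaccaded horizontal eye velocity over the closed
window spanning 50 ms before and after target-motion onset. Interception
onset is the first cursor sample whose 2-D speed exceeds 1.0 deg/s (the
search starts at the trial start so pre-onset movement is detectable), and
latency is interception onset minus target onset. Trials are excluded for
blinks during target motion, saccades overlapping the ASEM epoch,
interception movements initiated before target onset, or latencies beyond
500 ms; all violated rules are reported, and retention is equivalent to an
empty reason set.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .preprocess import preprocess_cursor, preprocess_eye
from .types import (CohortData, ExclusionOutcome, ExclusionReason,
                    Interval, KinematicSeries, SaccadeInterval, TrialFeatures,
                    TrialRecord)


class WindowError(ValueError):
    """Requested analysis window exceeds the trace."""


def compute_asem_velocity(eye: KinematicSeries, target_onset: float,
                          halfwindow: float = 0.050) -> float:
    """Mean horizontal eye velocity over [onset - hw, onset + hw] (closed)."""
    lo, hi = target_onset - halfwindow, target_onset + halfwindow
    if lo < eye.time[0] - 1e-9 or hi > eye.time[-1] + 1e-9:
        raise WindowError("ASEM window exceeds the eye trace")
    sel = (eye.time >= lo - 1e-12) & (eye.time <= hi + 1e-12)
    return float(np.mean(eye.vx[sel]))


def resign_by_direction(asem_velocity: float, direction: int) -> float:
    """Re-sign so that the target-motion direction is positive."""
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    return asem_velocity * direction


def detect_interception_onset(cursor: KinematicSeries,
                              threshold: float = 1.0,
                              start_time: Optional[float] = None
                              ) -> Optional[float]:
    """Time of the first sample with 2-D cursor speed above ``threshold``.

    Returns ``None`` when the cursor never exceeds the criterion (the trial
    is unusable for latency analyses).
    """
    speed = cursor.speed()
    sel = np.ones(len(speed), dtype=bool)
    if start_time is not None:
        sel = cursor.time >= start_time
    idx = np.flatnonzero(sel & (speed > threshold))
    if len(idx) == 0:
        return None
    return float(cursor.time[idx[0]])


def compute_hand_features(
    cursor: KinematicSeries,
    target_x,
    target_y,
    target_onset: float,
    start_position: Tuple[float, float],
    interception_onset: Optional[float],
    accel_window: float = 0.100,
) -> dict:
    """Hand-kinematic scalars for one trial.

    ``target_x``/``target_y`` give the target position at each cursor sample
    time (arrays aligned with ``cursor.time``). Initial accelerations are
    means over the first ``accel_window`` seconds after target onset; the
    initial direction is the angle from the +y midline (rightward positive)
    of the vector from the start position to the cursor position at peak 2-D
    acceleration magnitude; endpoint error is the absolute x distance to the
    target at the first sample where the cursor reaches the target's
    y-position. Endpoint fields are NaN when the cursor never crosses.
    """
    t = cursor.time
    out = {
        "movement_time": math.nan, "initial_direction": math.nan,
        "endpoint_error": math.nan, "peak_velocity_x": math.nan,
        "peak_velocity_y": math.nan, "initial_accel_x": math.nan,
        "initial_accel_y": math.nan,
    }

    acc_sel = (t > target_onset) & (t <= target_onset + accel_window + 1e-12)
    if acc_sel.any():
        out["initial_accel_x"] = float(np.mean(cursor.ax[acc_sel]))
        out["initial_accel_y"] = float(np.mean(cursor.ay[acc_sel]))

    if interception_onset is None:
        return out

    move_sel = t >= interception_onset
    out["peak_velocity_x"] = float(np.max(np.abs(cursor.vx[move_sel])))
    out["peak_velocity_y"] = float(np.max(np.abs(cursor.vy[move_sel])))

    acc_mag = cursor.accel_magnitude()
    masked = np.where(move_sel, acc_mag, -np.inf)
    pk = int(np.argmax(masked))
    dx = cursor.x[pk] - start_position[0]
    dy = cursor.y[pk] - start_position[1]
    out["initial_direction"] = math.degrees(math.atan2(dx, dy))

    target_x = np.asarray(target_x, dtype=float)
    target_y = np.asarray(target_y, dtype=float)
    crossed = np.flatnonzero(move_sel & (cursor.y >= target_y))
    if len(crossed):
        k = crossed[0]
        out["endpoint_error"] = float(abs(cursor.x[k] - target_x[k]))
        out["movement_time"] = float(t[k] - interception_onset)
    return out


def apply_exclusion_rules(
    target_onset: float,
    trial_end: float,
    latency: Optional[float],
    saccades: Sequence[SaccadeInterval],
    blinks: Sequence[Interval],
    pre_onset_moving: bool,
    config: AnalysisConfig = None,
) -> ExclusionOutcome:
    """Evaluate the four exclusion rules independently; report all violations.

    A missing interception onset (``latency`` None) counts as a latency
    violation: the trial never yields a usable latency.
    """
    cfg = config or AnalysisConfig()
    reasons = set()
    hw = cfg.asem_halfwindow
    if any(b.overlaps(target_onset, trial_end) for b in blinks):
        reasons.add(ExclusionReason.BLINK_DURING_MOTION)
    if any(s.overlaps(target_onset - hw, target_onset + hw) for s in saccades):
        reasons.add(ExclusionReason.SACCADE_IN_ASEM_EPOCH)
    if pre_onset_moving or (latency is not None and latency < 0):
        reasons.add(ExclusionReason.PRE_ONSET_MOVEMENT)
    if latency is None or latency > cfg.max_latency:
        reasons.add(ExclusionReason.LATENCY_OVER_500MS)
    return ExclusionOutcome(retained=not reasons, reasons=frozenset(reasons))


def _target_trajectory(meta, times: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Horizontal constant-velocity target on the trial clock."""
    x = np.where(times >= meta.onset_time,
                 meta.direction * meta.target_speed * (times - meta.onset_time),
                 0.0)
    return x, np.zeros_like(times)


def extract_trial_features(
    record: TrialRecord,
    config: AnalysisConfig = None,
    start_position: Optional[Tuple[float, float]] = None,
) -> Tuple[TrialFeatures, ExclusionOutcome]:
    """Preprocess one trial and compute its features and exclusion outcome.

    ``start_position`` defaults to the cursor position at trial start.
    """
    cfg = config or AnalysisConfig()
    meta = record.meta
    eye, saccades, blinks = preprocess_eye(record.eye, cfg)
    cursor = preprocess_cursor(record.cursor, cfg)
    if start_position is None:
        start_position = (float(cursor.x[0]), float(cursor.y[0]))

    asem = compute_asem_velocity(eye, meta.onset_time, cfg.asem_halfwindow)
    # search from the trial start (pre-onset movement must be detectable) but
    # skip the filter warm-up guard where one-sided differentiation is noisy
    onset = detect_interception_onset(cursor, cfg.onset_speed_threshold,
                                      start_time=cfg.pre_onset_guard)
    latency = None if onset is None else onset - meta.onset_time

    pre_sel = (cursor.time >= cfg.pre_onset_guard) & (cursor.time < meta.onset_time)
    pre_moving = bool(np.any(cursor.speed()[pre_sel] > cfg.onset_speed_threshold))

    tx, ty = _target_trajectory(meta, cursor.time)
    hand = compute_hand_features(
        cursor, tx, ty, meta.onset_time, start_position, onset,
        accel_window=cfg.initial_accel_window,
    )
    outcome = apply_exclusion_rules(
        meta.onset_time, float(record.eye.time[-1]), latency,
        saccades, blinks, pre_moving, cfg,
    )
    features = TrialFeatures(
        participant=meta.participant, trial=meta.trial,
        condition=meta.condition, coherence=meta.coherence,
        direction=meta.direction,
        asem_velocity=asem,
        asem_velocity_signed=resign_by_direction(asem, meta.direction),
        interception_onset=math.nan if onset is None else onset,
        latency=math.nan if latency is None else latency,
        **hand,
    )
    return features, outcome


def build_feature_table(cohort: CohortData, config: AnalysisConfig = None,
                        ground_truth=None) -> pd.DataFrame:
    """Feature rows for every trial of a cohort, with exclusion bookkeeping.

    When ``ground_truth`` is given, its per-trial truth columns are merged in
    for recovery tests.
    """
    cfg = config or AnalysisConfig()
    rows = []
    for record in cohort.trials:
        features, outcome = extract_trial_features(record, cfg)
        row = features.__dict__.copy()
        row["retained"] = outcome.retained
        row["exclusion_reasons"] = ";".join(sorted(r.value for r in outcome.reasons))
        rows.append(row)
    table = pd.DataFrame(rows)
    if ground_truth is not None:
        truth = ground_truth.trials[
            ["participant", "trial", "true_asem", "true_latency", "violation"]
        ]
        table = table.merge(truth, on=["participant", "trial"], how="left")
    return table
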