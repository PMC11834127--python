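"""Signal chain: zero-phase Butterworth filtering, central-difference
differentiation, saccade detection, desaccading, blink detection.

The chain for eye traces is fixed: position low-passed at 15 Hz ->
central-difference velocity -> 30 Hz low-pass -> central-difference
acceleration -> 30 Hz low-pass -> saccade detection on the horizontal axis
(velocity > 30 deg/s AND |acceleration| > 1000 deg/s^2) -> saccade intervals
excised from the filtered position and bridged by linear interpolation ->
velocity/acceleration recomputed from the desaccaded position. Cursor traces
are low-passed at 20 Hz and differentiated the same way.

Filtering is forward-backward (scipy ``filtfilt``), so event timing is not
phase-shifted; the effective magnitude response is the square of the
second-order design.
"""

from __future__ import annotations

import logging
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .types import Interval, KinematicSeries, RawTrace, SaccadeInterval

logger = logging.getLogger(__name__)


class TraceLengthError(ValueError):
    """Series too short for the requested operation."""


class AllMissingError(ValueError):
    """Every sample of the trace is masked as missing."""


def lowpass_filter(series: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    """Second-order Butterworth low-pass, applied zero-phase (filtfilt).

    DC gain is exactly 1. Raises if ``cutoff`` is at or above Nyquist or the
    series is shorter than the filtfilt warm-up length.
    """
    series = np.asarray(series, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    nyquist = rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    if cutoff > 0.6 * nyquist:
        logger.info("cutoff %.1f Hz is close to Nyquist %.1f Hz", cutoff, nyquist)
    b, a = signal.butter(2, cutoff, btype="low", fs=rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(series) <= padlen:
        raise TraceLengthError(
            f"series length {len(series)} <= filter warm-up {padlen}")
    return signal.filtfilt(b, a, series)


def butterworth_gain_squared(rate: float, cutoff: float, freq: float) -> float:
    """Squared magnitude response of the designed digital filter at ``freq``.

    This is the effective gain of the zero-phase (forward-backward) pass;
    exposed so tests can compare measured attenuation against the design.
    """
    b, a = signal.butter(2, cutoff, btype="low", fs=rate)
    _, h = signal.freqz(b, a, worN=[freq], fs=rate)
    return float(np.abs(h[0]) ** 2)


def central_difference(series: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference derivative; one-sided differences at the endpoints.

    Interior sample i maps to (x[i+1] - x[i-1]) * rate / 2, exact for
    polynomials of degree <= 2.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise TraceLengthError("central difference needs >= 3 samples")
    out = np.empty_like(series)
    out[1:-1] = (series[2:] - series[:-2]) * (rate / 2.0)
    out[0] = (series[1] - series[0]) * rate
    out[-1] = (series[-1] - series[-2]) * rate
    return out


def detect_saccades(
    velocity: np.ndarray,
    acceleration: np.ndarray,
    rate: float,
    velocity_threshold: float = 30.0,
    accel_threshold: float = 1000.0,
    pad: float = 0.010,
    t0: float = 0.0,
) -> List[SaccadeInterval]:
    """Find saccade intervals from the joint velocity/acceleration criterion.

    An interval seeds wherever velocity > ``velocity_threshold`` AND
    |acceleration| > ``accel_threshold`` simultaneously, grows over the
    surrounding run of super-threshold velocity, is padded by ``pad`` seconds
    on each side, and overlapping intervals are merged. ``velocity`` is
    expected as a speed-like (non-negative comparison uses its absolute
    value). Times are seconds on the trace clock starting at ``t0``.
    """
    velocity = np.asarray(velocity, dtype=float)
    acceleration = np.asarray(acceleration, dtype=float)
    if velocity.shape != acceleration.shape:
        raise ValueError("velocity and acceleration must have equal lengths")
    fast = np.abs(velocity) > velocity_threshold
    joint = fast & (np.abs(acceleration) > accel_threshold)
    if not joint.any():
        return []

    # maximal runs of super-threshold velocity that contain a joint sample
    idx = np.flatnonzero(fast)
    runs = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))

    dt = 1.0 / rate
    intervals: List[Tuple[float, float, float, float]] = []
    for lo, hi in runs:
        if not joint[lo:hi + 1].any():
            continue
        start = t0 + lo * dt - pad
        end = t0 + hi * dt + pad
        pk_v = float(np.max(np.abs(velocity[lo:hi + 1])))
        pk_a = float(np.max(np.abs(acceleration[lo:hi + 1])))
        intervals.append((start, end, pk_v, pk_a))

    merged: List[Tuple[float, float, float, float]] = []
    for start, end, pk_v, pk_a in intervals:
        if merged and start <= merged[-1][1]:
            ps, pe, pv, pa = merged[-1]
            merged[-1] = (ps, max(pe, end), max(pv, pk_v), max(pa, pk_a))
        else:
            merged.append((start, end, pk_v, pk_a))
    return [SaccadeInterval(s, e, v, a) for s, e, v, a in merged]


def saccade_sample_labels(
    n: int, rate: float, intervals: Sequence[SaccadeInterval],
    t0: float = 0.0, pad: float = 0.0,
) -> np.ndarray:
    """Boolean per-sample labels for a list of intervals, shrunk by ``pad``.

    With ``pad`` equal to the detection padding, the labels cover only the
    super-threshold core of each interval.
    """
    labels = np.zeros(n, dtype=bool)
    times = t0 + np.arange(n) / rate
    for iv in intervals:
        labels |= (times >= iv.start + pad) & (times <= iv.end - pad)
    return labels


def remove_and_interpolate(
    position: np.ndarray,
    intervals: Sequence,
    rate: float,
    t0: float = 0.0,
) -> np.ndarray:
    """Replace samples strictly inside each interval by linear interpolation.

    The bridging line joins the last sample at or before the interval start
    and the first sample at or after its end; every other sample is returned
    bit-unchanged. Idempotent for a fixed interval list.
    """
    position = np.asarray(position, dtype=float)
    out = position.copy()
    n = len(position)
    for iv in intervals:
        lo_idx = int(np.floor((iv.start - t0) * rate))
        hi_idx = int(np.ceil((iv.end - t0) * rate))
        lo_idx = max(lo_idx, 0) if iv.start >= t0 - 1e-12 else -1
        if lo_idx < 0 or hi_idx > n - 1:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}] outside trace bounds")
        if hi_idx - lo_idx < 2:
            continue  # no strictly interior sample
        inner = np.arange(lo_idx + 1, hi_idx)
        frac = (inner - lo_idx) / (hi_idx - lo_idx)
        out[inner] = out[lo_idx] + frac * (out[hi_idx] - out[lo_idx])
    return out


def detect_blinks(raw: RawTrace, pad: float = 0.050) -> List[Interval]:
    """Maximal runs of missing samples, padded by ``pad`` seconds each side.

    Padded intervals that touch are merged, so runs separated by less than
    twice the padding coalesce (pupil-loss transients around a blink).
    """
    mask = raw.mask
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    t = raw.time
    runs = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))

    intervals = [(t[lo] - pad, t[hi] + pad) for lo, hi in runs]
    merged: List[Tuple[float, float]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return [Interval(s, e) for s, e in merged]


def _differentiate_and_filter(pos: np.ndarray, rate: float, cutoff: float):
    v = lowpass_filter(central_difference(pos, rate), rate, cutoff)
    a = lowpass_filter(central_difference(v, rate), rate, cutoff)
    return v, a


def preprocess_eye(
    raw: RawTrace, config: AnalysisConfig = None,
) -> Tuple[KinematicSeries, List[SaccadeInterval], List[Interval]]:
    """Run the full eye chain; returns the desaccaded kinematics plus events.

    Missing samples are bridged by linear interpolation before filtering so
    the filters see a gap-free series; blink intervals are reported for the
    exclusion rules. Raises :class:`AllMissingError` for an all-masked trace.
    """
    cfg = config or AnalysisConfig()
    if raw.mask.all():
        raise AllMissingError("eye trace has no valid samples")
    t0 = float(raw.time[0])

    x, y = raw.x, raw.y
    if raw.mask.any():
        good = ~raw.mask
        x = x.copy()
        y = y.copy()
        x[raw.mask] = np.interp(raw.time[raw.mask], raw.time[good], x[good])
        y[raw.mask] = np.interp(raw.time[raw.mask], raw.time[good], y[good])
    blinks = detect_blinks(raw, pad=cfg.blink_pad)

    fx = lowpass_filter(x, raw.rate, cfg.eye_position_cutoff)
    fy = lowpass_filter(y, raw.rate, cfg.eye_position_cutoff)
    vx, ax = _differentiate_and_filter(fx, raw.rate, cfg.eye_velocity_cutoff)
    vy, ay = _differentiate_and_filter(fy, raw.rate, cfg.eye_velocity_cutoff)

    if cfg.saccade_axis == "x":
        det_v, det_a = vx, ax
    else:
        det_v, det_a = np.hypot(vx, vy), np.hypot(ax, ay)
    saccades = detect_saccades(
        det_v, det_a, raw.rate,
        velocity_threshold=cfg.saccade_velocity_threshold,
        accel_threshold=cfg.saccade_accel_threshold,
        pad=cfg.saccade_pad, t0=t0,
    )
    # clip detected intervals to the trace so boundary saccades remain removable
    t_end = float(raw.time[-1])
    clipped = [
        SaccadeInterval(max(s.start, t0), min(s.end, t_end),
                        s.peak_velocity, s.peak_acceleration)
        for s in saccades
    ]

    dx = remove_and_interpolate(fx, clipped, raw.rate, t0=t0)
    dy = remove_and_interpolate(fy, clipped, raw.rate, t0=t0)
    vx_d, ax_d = _differentiate_and_filter(dx, raw.rate, cfg.eye_velocity_cutoff)
    vy_d, ay_d = _differentiate_and_filter(dy, raw.rate, cfg.eye_velocity_cutoff)

    series = KinematicSeries(
        time=raw.time, x=dx, y=dy, vx=vx_d, vy=vy_d, ax=ax_d, ay=ay_d,
        rate=raw.rate, desaccaded=True,
    )
    return series, saccades, blinks


def preprocess_cursor(raw: RawTrace, config: AnalysisConfig = None) -> KinematicSeries:
    """Filter the cursor at 20 Hz and differentiate with the same contract.

    At the study's 60 Hz sampling the 20 Hz cutoff sits close to Nyquist;
    this is allowed and logged by :func:`lowpass_filter`.
    """
    cfg = config or AnalysisConfig()
    fx = lowpass_filter(raw.x, raw.rate, cfg.cursor_cutoff)
    fy = lowpass_filter(raw.y, raw.rate, cfg.cursor_cutoff)
    vx, ax = _differentiate_and_filter(fx, raw.rate, cfg.cursor_cutoff)
    vy, ay = _differentiate_and_filter(fy, raw.rate, cfg.cursor_cutoff)
    return KinematicSeries(
        time=raw.time, x=fx, y=fy, vx=vx, vy=vy, ax=ax, ay=ay,
        rate=raw.rate, desaccaded=False,
    )
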