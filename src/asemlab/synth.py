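"""Synthetic cohort generator and random-dot-motion stimulus kinematics.

The generator emulates the study design (10 participants x 2 conditions x 9
signed coherence levels x 20 trials; eye at 1 kHz, cursor at 60 Hz; target at
8.0 deg/s) with known ground truth, so every downstream stage of the pipeline
can be tested for parameter recovery.

Statistical structure per participant i and trial:

* true ASEM velocity  v = a_i/2 (1 + erf((x - mu_i)/(sigma_i sqrt(2)))) + b_i
  + trial noise, with the height a_i drawn per condition (a_gap > a_control),
* true latency  L = d_i + c_i exp(-(x - mu_i)^2 / (2 sigma_i^2))
  + beta0_i + beta1_i * (direction-signed v) + residual,

so the coupling coefficient beta1 (s per deg/s) is the quantity the
mixed-effects layer should recover. Non-violation latencies are clipped into
the retainable range; the explicit violation mode plants excludable trials
(blinks during motion, ASEM-epoch saccades, pre-onset movement, latencies
beyond 500 ms) for exclusion-bookkeeping tests.

Trace shape: the eye is fixational noise until 0.3 s before target onset,
ramps smoothly (smoothstep velocity) to the trial's true ASEM velocity with
the ramp ending 80 ms *before* onset, holds that plateau through the ASEM
measurement window, and then relaxes first-order to the 8.0 deg/s pursuit
after a 100 ms pursuit latency. The plateau makes the windowed mean identify
the generative value exactly. The cursor is stationary until the true
latency, then follows a minimum-jerk (bell-velocity) reach to the analytic
interception point.

Spontaneous saccades and blinks are injected only *outside* the windows that
trigger trial exclusion; exclusion-triggering events are planted exclusively
by the violation mode, so the planted violation fraction is the expected
exclusion rate by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .types import (CohortData, GroundTruth, Interval, RawTrace, TrialMeta,
                    TrialRecord)

VIOLATION_TYPES = ("blink", "saccade", "pre_onset", "latency")


# ---------------------------------------------------------------------------
# model curves (shared with the fitting layer)

def cumulative_gaussian(x, a, mu, sigma, b):
    """Sigmoid linking signed coherence to ASEM velocity (deg/s)."""
    from scipy.special import erf
    x = np.asarray(x, dtype=float)
    return a / 2.0 * (1.0 + erf((x - mu) / (sigma * math.sqrt(2.0)))) + b


def gaussian_latency(x, c, mu, sigma, d):
    """Gaussian linking signed coherence to interception latency (s)."""
    x = np.asarray(x, dtype=float)
    return c * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2)) + d


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def minimum_jerk_position(u: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10.0 * u ** 3 - 15.0 * u ** 4 + 6.0 * u ** 5


# ---------------------------------------------------------------------------
# participant / trial scalars

def sample_participant_params(config: SimulationConfig, rng: np.random.Generator
                              ) -> pd.DataFrame:
    """Draw per-participant sigmoid, latency and coupling parameters."""
    sp, lp = config.sigmoid_population, config.latency_population
    rows = []
    for i in range(config.n_participants):
        pid = f"p{i + 1:02d}"
        row = {"participant": pid}
        for name in ("a_control", "a_gap", "mu", "sigma", "b"):
            mean, sd = getattr(sp, name)
            row[name] = rng.normal(mean, sd) if sd > 0 else mean
        row["sigma"] = max(row["sigma"], 0.05)  # keep the sigmoid identifiable
        for name in ("c", "mu", "sigma", "d", "beta0", "beta1"):
            mean, sd = getattr(lp, name)
            key = f"lat_{name}" if name in ("mu", "sigma") else name
            row[key] = rng.normal(mean, sd) if sd > 0 else mean
        row["lat_sigma"] = max(row["lat_sigma"], 0.05)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_trial_table(config: SimulationConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-trial scalar ground truth without rendering traces.

    Returns ``(participants, trials)``. This is the statistical core the
    trace renderer consumes; the inference layer can be exercised directly
    on its output when trace-level effects are not under test.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    participants = sample_participant_params(config, rng)

    cells = [(cond, coh) for cond in config.conditions
             for coh in config.coherence_levels]
    lp = config.latency_population
    rows = []
    for _, p in participants.iterrows():
        cell_list = [cell for cell in cells for _ in range(config.trials_per_cell)]
        order = rng.permutation(len(cell_list))
        for trial_idx, cell_i in enumerate(order, start=1):
            cond, coh = cell_list[cell_i]
            direction = int(np.sign(coh)) if coh != 0 else int(rng.choice([-1, 1]))
            a = p["a_gap"] if cond == "gap" else p["a_control"]
            v = float(cumulative_gaussian(coh, a, p["mu"], p["sigma"], p["b"]))
            if config.asem_trial_sd > 0:
                v += rng.normal(0.0, config.asem_trial_sd)
            certainty = float(gaussian_latency(coh, p["c"], p["lat_mu"],
                                               p["lat_sigma"], 0.0))
            lat = (p["d"] + certainty + p["beta0"] + p["beta1"] * direction * v)
            if lp.residual_sd > 0:
                lat += rng.normal(0.0, lp.residual_sd)
            lat = float(np.clip(lat, config.latency_floor, config.latency_ceiling))

            violation = ""
            if config.violation_fraction > 0 and rng.random() < config.violation_fraction:
                violation = VIOLATION_TYPES[rng.integers(len(VIOLATION_TYPES))]
                if violation == "latency":
                    lat = float(rng.uniform(0.52, 0.62))
                elif violation == "pre_onset":
                    lat = float(-rng.uniform(0.10, 0.20))
            rows.append({
                "participant": p["participant"], "trial": trial_idx,
                "condition": cond, "coherence": coh, "direction": direction,
                "true_asem": v, "true_latency": lat, "violation": violation,
                "onset_time": config.onset_time,
            })
    return participants, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trace-level building blocks

def inject_saccade(trace: RawTrace, time: float, amplitude: float,
                   duration: float, direction: Tuple[float, float] = (1.0, 0.0)
                   ) -> RawTrace:
    """Add a smooth (minimum-jerk, bell-velocity) gaze step to a trace.

    The displacement ramps from 0 to ``amplitude`` deg over ``duration``
    seconds along ``direction`` and persists afterwards, as a real saccade
    displaces the eye permanently. Samples before ``time`` are unchanged.
    """
    if duration <= 0:
        raise ValueError("saccade duration must be positive")
    if time < trace.time[0] - 1e-12 or time + duration > trace.time[-1] + 1e-12:
        raise ValueError("saccade interval outside trace")
    u = (trace.time - time) / duration
    profile = amplitude * minimum_jerk_position(u)
    dx, dy = direction
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("direction vector must be nonzero")
    return RawTrace(
        time=trace.time,
        x=trace.x + profile * dx / norm,
        y=trace.y + profile * dy / norm,
        rate=trace.rate,
        mask=trace.mask.copy(),
    )


def _integrate_velocity(v: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid integration, position starting at 0."""
    out = np.empty_like(v)
    out[0] = 0.0
    np.cumsum((v[1:] + v[:-1]) * (dt / 2.0), out=out[1:])
    return out


def _eye_velocity_profile(t: np.ndarray, config: SimulationConfig,
                          v_true: float, direction: int) -> np.ndarray:
    onset = config.onset_time
    ramp_start = onset - config.anticipation_window
    ramp_end = onset - config.ramp_end_margin
    pursuit_start = onset + config.pursuit_latency
    target_v = direction * config.target_speed

    v = np.zeros_like(t)
    ramp = (t >= ramp_start) & (t < ramp_end)
    v[ramp] = v_true * _smoothstep((t[ramp] - ramp_start) / (ramp_end - ramp_start))
    plateau = (t >= ramp_end) & (t < pursuit_start)
    v[plateau] = v_true
    pursuit = t >= pursuit_start
    tau = config.pursuit_time_constant
    v[pursuit] = target_v + (v_true - target_v) * np.exp(
        -(t[pursuit] - pursuit_start) / tau)
    return v


def _sample_event_time(rng: np.random.Generator, windows: List[Tuple[float, float]]
                       ) -> Optional[float]:
    widths = np.array([max(0.0, hi - lo) for lo, hi in windows])
    total = widths.sum()
    if total <= 0:
        return None
    w = rng.random() * total
    for (lo, hi), width in zip(windows, widths):
        if w < width:
            return lo + w
        w -= width
    return None


def _render_eye(config: SimulationConfig, rng: np.random.Generator,
                v_true: float, direction: int, violation: str
                ) -> Tuple[RawTrace, List[Interval], List[Interval]]:
    dt = 1.0 / config.eye_rate
    n = int(round(config.trial_duration * config.eye_rate)) + 1
    t = np.arange(n) * dt
    v = _eye_velocity_profile(t, config, v_true, direction)
    if config.noise_sd_eye > 0:
        v = v + rng.normal(0.0, config.noise_sd_eye, n)
        vy = rng.normal(0.0, config.noise_sd_eye, n)
    else:
        vy = np.zeros(n)
    trace = RawTrace(time=t, x=_integrate_velocity(v, dt),
                     y=_integrate_velocity(vy, dt), rate=config.eye_rate)

    onset, end = config.onset_time, config.trial_duration
    epoch_margin = 0.09  # keeps padded detections clear of the +-50 ms epoch
    saccades: List[Interval] = []
    n_sacc = rng.poisson(config.saccade_rate * config.trial_duration)
    for _ in range(n_sacc):
        amp = rng.uniform(0.4, 1.0)
        dur = 0.02 + 0.006 * amp
        windows = [(0.05, onset - epoch_margin - dur),
                   (onset + epoch_margin, end - 0.05 - dur)]
        start = _sample_event_time(rng, windows)
        if start is None:
            continue
        sign = rng.choice([-1.0, 1.0])
        trace = inject_saccade(trace, start, sign * amp, dur)
        saccades.append(Interval(start, start + dur))

    blinks: List[Interval] = []
    blink_dur = 0.15
    if violation == "blink":
        start = float(rng.uniform(onset + 0.1, end - blink_dur - 0.05))
        blinks.append(Interval(start, start + blink_dur))
    elif config.blink_prob > 0 and rng.random() < config.blink_prob:
        hi = onset - 0.45 - blink_dur
        if hi > 0.05:
            start = float(rng.uniform(0.05, hi))
            blinks.append(Interval(start, start + blink_dur))
    if violation == "saccade":
        dur = 0.032
        start = onset - dur / 2.0
        trace = inject_saccade(trace, start, float(rng.choice([-2.0, 2.0])), dur)
        saccades.append(Interval(start, start + dur))

    for iv in blinks:
        trace.mask |= (t >= iv.start) & (t <= iv.end)
    return trace, saccades, blinks


def _render_cursor(config: SimulationConfig, rng: np.random.Generator,
                   true_latency: float, direction: int) -> RawTrace:
    dt = 1.0 / config.cursor_rate
    n = int(round(config.trial_duration * config.cursor_rate)) + 1
    t = np.arange(n) * dt
    x0, y0 = config.start_position
    move_start = config.onset_time + true_latency
    mt = config.reach_duration
    x_aim = direction * config.target_speed * (true_latency + mt)
    if config.aim_error_sd > 0:
        x_aim += rng.normal(0.0, config.aim_error_sd)
    u = (t - move_start) / mt
    profile = minimum_jerk_position(u)
    x = x0 + (x_aim - x0) * profile
    y = y0 + (0.0 - y0) * profile
    if config.noise_sd_cursor > 0:
        x = x + rng.normal(0.0, config.noise_sd_cursor, n)
        y = y + rng.normal(0.0, config.noise_sd_cursor, n)
    return RawTrace(time=t, x=x, y=y, rate=config.cursor_rate)


# ---------------------------------------------------------------------------
# cohort assembly

def simulate_cohort(config: SimulationConfig
                    ) -> Tuple[CohortData, GroundTruth]:
    """Generate a full cohort of trial records with ground truth.

    Deterministic given ``config.seed``: identical configs yield bit-identical
    traces and tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants, trials = simulate_trial_table(config, rng)

    records: List[TrialRecord] = []
    saccade_map, blink_map = {}, {}
    for row in trials.itertuples(index=False):
        eye, saccades, blinks = _render_eye(
            config, rng, row.true_asem, row.direction, row.violation)
        cursor = _render_cursor(config, rng, row.true_latency, row.direction)
        meta = TrialMeta(
            participant=row.participant, trial=int(row.trial),
            condition=row.condition, coherence=float(row.coherence),
            direction=int(row.direction), onset_time=config.onset_time,
            target_speed=config.target_speed,
        )
        records.append(TrialRecord(meta=meta, eye=eye, cursor=cursor))
        key = (row.participant, int(row.trial))
        saccade_map[key] = saccades
        blink_map[key] = blinks

    metadata = trials[["participant", "trial", "condition", "coherence",
                       "direction", "onset_time"]].copy()
    metadata["target_speed"] = config.target_speed
    cohort = CohortData(trials=records, metadata=metadata,
                        provenance={"seed": config.seed})
    truth = GroundTruth(participants=participants, trials=trials,
                        saccades=saccade_map, blinks=blink_map)
    return cohort, truth


# ---------------------------------------------------------------------------
# random-dot motion stimulus

@dataclass
class RDMFrame:
    """Dot coordinates for one display frame (aperture-centered, deg)."""

    positions: np.ndarray  # (n_dots, 2)
    set_index: int  # which of the three interleaved sets was redrawn
    signal: np.ndarray  # True where the redraw was a coherent displacement
    wrapped: np.ndarray  # True where the displacement wrapped at the aperture


@dataclass
class RDMFrameSet:
    frames: List[RDMFrame]
    aperture_diameter: float  # deg
    coherence: float  # signed fraction
    displacement: float  # deg per 3-frame redraw
    refresh: float  # Hz

    def signal_fraction(self) -> float:
        """Fraction of redraws carrying the coherent displacement."""
        flags = np.concatenate([f.signal for f in self.frames[3:]])
        return float(flags.mean()) if len(flags) else 0.0


def _uniform_in_circle(rng: np.random.Generator, n: int, radius: float
                       ) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_rdm_frames(coherence: float, duration: float, refresh: float = 60.0,
                        aperture: float = 15.0, density: float = 16.7,
                        speed: float = 8.0, seed: int = 0) -> RDMFrameSet:
    """Random-dot kinematogram with three interleaved dot sets.

    Each set is redrawn three frames after it was last shown: with
    probability |coherence| a dot is displaced by ``speed * 3 / refresh`` deg
    in the direction of the coherence sign (horizontal); otherwise it is
    redrawn at a uniform-random location in the circular aperture. Dot count
    per frame follows the density convention dots/deg^2/s aggregated over
    frames. Displacements that would exit the aperture wrap across the
    horizontal chord and are flagged ``wrapped``.
    """
    if abs(coherence) > 1.0:
        raise ValueError("|coherence| must be <= 1")
    if refresh <= 0 or duration <= 0 or aperture <= 0:
        raise ValueError("refresh, duration and aperture must be positive")
    rng = np.random.default_rng(seed)
    radius = aperture / 2.0
    area = math.pi * radius ** 2
    n_dots = max(1, int(round(density * area / refresh)))
    n_frames = int(round(duration * refresh))
    dx = math.copysign(speed * 3.0 / refresh, coherence) if coherence != 0 else 0.0
    p_signal = abs(coherence)

    frames: List[RDMFrame] = []
    for f in range(n_frames):
        set_index = f % 3
        if f < 3:
            pos = _uniform_in_circle(rng, n_dots, radius)
            signal = np.zeros(n_dots, dtype=bool)
            wrapped = np.zeros(n_dots, dtype=bool)
        else:
            prev = frames[f - 3].positions
            signal = rng.random(n_dots) < p_signal
            pos = _uniform_in_circle(rng, n_dots, radius)
            wrapped = np.zeros(n_dots, dtype=bool)
            if signal.any():
                moved = prev[signal].copy()
                moved[:, 0] += dx
                y = moved[:, 1]
                half_chord = np.sqrt(np.maximum(radius ** 2 - y ** 2, 0.0))
                outside = np.abs(moved[:, 0]) > half_chord
                if outside.any():
                    w = half_chord[outside]
                    safe = w > 1e-9
                    xw = moved[outside, 0]
                    xw[safe] = np.mod(xw[safe] + w[safe], 2.0 * w[safe]) - w[safe]
                    xw[~safe] = 0.0
                    moved[outside, 0] = xw
                pos[signal] = moved
                wrapped[signal] = outside
        frames.append(RDMFrame(positions=pos, set_index=set_index,
                               signal=signal, wrapped=wrapped))
    return RDMFrameSet(frames=frames, aperture_diameter=aperture,
                       coherence=coherence, displacement=abs(dx), refresh=refresh)
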