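"""Core data containers shared across the pipeline.

Units throughout: degrees of visual angle (deg), seconds (s), Hz.
Motion coherence is a signed fraction in [-1, 1]; target direction is +-1
(rightward positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd


class ExclusionReason(str, Enum):
    """Why a trial is dropped before the headline analyses."""

    BLINK_DURING_MOTION = "blink_during_motion"
    SACCADE_IN_ASEM_EPOCH = "saccade_in_asem_epoch"
    PRE_ONSET_MOVEMENT = "pre_onset_movement"
    LATENCY_OVER_500MS = "latency_over_500ms"


@dataclass
class RawTrace:
    """A uniformly sampled 2-D position trace.

    ``mask`` marks missing samples (pupil loss / blinks); positions at masked
    samples are not meaningful.
    """

    time: np.ndarray  # s, strictly increasing, uniform
    x: np.ndarray  # deg
    y: np.ndarray  # deg
    rate: float  # Hz
    mask: np.ndarray = None  # True where the sample is missing

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.time.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.time)
        if not (len(self.x) == len(self.y) == len(self.mask) == n):
            raise ValueError("trace arrays must share one length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time base must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time base must be uniform")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TrialMeta:
    participant: str
    trial: int
    condition: str  # "control" | "gap"
    coherence: float  # signed fraction
    direction: int  # +-1
    onset_time: float  # target-motion onset on the trial clock, s
    target_speed: float = 8.0  # deg/s


@dataclass
class TrialRecord:
    """One trial's raw traces plus metadata."""

    meta: TrialMeta
    eye: RawTrace
    cursor: RawTrace


@dataclass
class KinematicSeries:
    """Filtered position with velocity/acceleration on the same time base."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    rate: float
    desaccaded: bool = False

    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def accel_magnitude(self) -> np.ndarray:
        return np.hypot(self.ax, self.ay)


@dataclass(frozen=True)
class SaccadeInterval:
    start: float  # s
    end: float  # s
    peak_velocity: float  # deg/s
    peak_acceleration: float  # deg/s^2

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("saccade interval must have start < end")

    def overlaps(self, t0: float, t1: float) -> bool:
        return self.start <= t1 and self.end >= t0


@dataclass(frozen=True)
class Interval:
    """A plain time interval (blinks, planted events)."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("interval must have start < end")

    def overlaps(self, t0: float, t1: float) -> bool:
        return self.start <= t1 and self.end >= t0


@dataclass
class TrialFeatures:
    """Per-trial scalar measures feeding the statistics layer.

    ``asem_velocity`` is the raw horizontal value; ``asem_velocity_signed`` is
    re-signed so that the target-motion direction is positive. Hand fields are
    NaN when undefined (no interception onset / no target-line crossing).
    """

    participant: str
    trial: int
    condition: str
    coherence: float
    direction: int
    asem_velocity: float
    asem_velocity_signed: float
    interception_onset: float  # s on the trial clock; NaN if none
    latency: float  # s; NaN if no onset
    movement_time: float
    initial_direction: float  # deg from the +y midline, rightward positive
    endpoint_error: float  # deg, absolute x distance at target-y crossing
    peak_velocity_x: float
    peak_velocity_y: float
    initial_accel_x: float
    initial_accel_y: float


@dataclass
class ExclusionOutcome:
    retained: bool
    reasons: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.reasons = frozenset(ExclusionReason(r) for r in self.reasons)
        if self.retained != (len(self.reasons) == 0):
            raise ValueError("retained must mirror an empty reason set")


@dataclass
class CumulativeGaussianFit:
    """Sigmoid (cumulative Gaussian) fit of ASEM velocity vs signed coherence.

    v(x) = a/2 * (1 + erf((x - mu) / (sigma * sqrt(2)))) + b
    """

    a: float  # height, deg/s
    mu: float  # coherence
    sigma: float  # coherence
    b: float  # baseline (lower asymptote), deg/s
    r_squared: float
    converged: bool


@dataclass
class GaussianLatencyFit:
    """Gaussian fit of interception latency vs signed coherence.

    L(x) = c * exp(-(x - mu)^2 / (2 sigma^2)) + d
    """

    c: float  # peak amplitude, s
    mu: float
    sigma: float
    d: float  # constant offset, s
    r_squared: float
    converged: bool


@dataclass
class LMEFitResult:
    formula_id: str  # "random_slope_intercept" | "random_intercept" | "fixed_only"
    fixed_intercept: float
    fixed_slope: float
    fixed_intercept_se: float
    fixed_slope_se: float
    slope_t: float
    slope_df: int
    slope_p: float
    random_effect_variances: dict
    loglik: float
    n_params: int
    bic: float
    n_obs: int
    singular: bool
    participant_intercepts: dict
    participant_slopes: dict
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")


@dataclass
class LMEComparison:
    fits: dict  # formula_id -> LMEFitResult
    selected: str  # formula_id with minimum BIC

    @property
    def selected_fit(self) -> LMEFitResult:
        return self.fits[self.selected]


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float  # mean(diff)/sd(diff) convention
    cohens_d_av: float  # mean(diff)/mean(sd(x), sd(y)) convention
    mean_diff: float
    n: int


@dataclass
class CohortData:
    """A simulated or imported cohort: trial records plus a metadata table.

    ``metadata`` has one row per trial (participant, trial, condition,
    coherence, direction, onset_time, target_speed) matching ``trials``.
    """

    trials: List[TrialRecord]
    metadata: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class GroundTruth:
    """Generative truth for recovery tests.

    ``participants`` holds the per-participant sigmoid/latency/coupling
    parameters; ``trials`` the per-trial true ASEM velocity (deg/s), true
    latency (s), direction and any planted violation; ``saccades``/``blinks``
    map (participant, trial) to planted event intervals.
    """

    participants: pd.DataFrame
    trials: pd.DataFrame
    saccades: Dict[Tuple[str, int], List[Interval]] = field(default_factory=dict)
    blinks: Dict[Tuple[str, int], List[Interval]] = field(default_factory=dict)


@dataclass
class ParticipantRegression:
    participant: str
    slope: float  # s per deg/s
    intercept: float  # s
    r_squared: float
    mean_latency: float  # s
    n_trials: int
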