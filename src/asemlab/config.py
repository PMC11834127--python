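"""Simulation and analysis configuration.

Analysis defaults are the constants of the measurement protocol this package
implements: 15/30/20 Hz Butterworth passbands, the 30 deg/s + 1000 deg/s^2
saccade criterion, the +-50 ms ASEM window, the 1.0 deg/s interception-onset
threshold, the 100 ms initial-acceleration window, the 500 ms latency cutoff
and the 20% extreme-trial fraction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import yaml

#: The nine signed coherence levels of the study design.
STUDY_COHERENCES: Tuple[float, ...] = (
    -0.64, -0.32, -0.16, -0.08, 0.0, 0.08, 0.16, 0.32, 0.64,
)

MeanSD = Tuple[float, float]


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


def _check_mean_sd(name: str, value: MeanSD) -> None:
    if len(value) != 2:
        raise ConfigurationError(f"{name} must be a (mean, sd) pair")
    if value[1] < 0:
        raise ConfigurationError(f"{name} SD must be >= 0")


@dataclass
class SigmoidPopulation:
    """Population distribution of per-participant sigmoid parameters.

    Each entry is (mean, sd) of a normal draw per participant. Defaults put
    the condition means of direction-signed ASEM velocity near 0.28 deg/s
    (control) and 0.52 deg/s (gap) when averaged over the nine study
    coherence levels.
    """

    a_control: MeanSD = (1.0, 0.2)
    a_gap: MeanSD = (1.86, 0.25)
    mu: MeanSD = (0.0, 0.02)
    sigma: MeanSD = (0.25, 0.05)
    b: MeanSD = (-0.5, 0.1)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check_mean_sd(f.name, getattr(self, f.name))


@dataclass
class LatencyPopulation:
    """Population distribution of latency-model parameters.

    True latency per trial is
        d_i + c_i * exp(-(x - mu_i)^2 / (2 sigma_i^2))
            + beta0_i + beta1_i * (direction-signed ASEM velocity) + eps,
    eps ~ N(0, residual_sd). ``beta0`` is the participant intercept
    *deviation* (population mean 0); ``d`` carries the condition-independent
    offset so the two intercept-like terms are not doubled.
    """

    c: MeanSD = (0.12, 0.03)  # s
    mu: MeanSD = (0.0, 0.02)
    sigma: MeanSD = (0.30, 0.05)
    d: MeanSD = (0.25, 0.04)  # s
    beta0: MeanSD = (0.0, 0.03)  # s
    beta1: MeanSD = (-0.03, 0.01)  # s per deg/s
    residual_sd: float = 0.05  # s

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "residual_sd":
                if v < 0:
                    raise ConfigurationError("residual_sd must be >= 0")
            else:
                _check_mean_sd(f.name, v)


@dataclass
class SimulationConfig:
    """Everything the synthetic-cohort generator needs.

    Defaults emulate the study design: 10 participants x 2 conditions x 9
    coherence levels x 20 trials, target speed 8.0 deg/s, eye at 1 kHz and
    cursor at 60 Hz.
    """

    n_participants: int = 10
    trials_per_cell: int = 20
    coherence_levels: Sequence[float] = STUDY_COHERENCES
    conditions: Sequence[str] = ("control", "gap")
    eye_rate: float = 1000.0  # Hz
    cursor_rate: float = 60.0  # Hz
    target_speed: float = 8.0  # deg/s
    sigmoid_population: SigmoidPopulation = field(default_factory=SigmoidPopulation)
    latency_population: LatencyPopulation = field(default_factory=LatencyPopulation)
    asem_trial_sd: float = 0.3  # deg/s, trial-to-trial ASEM variability
    pursuit_latency: float = 0.1  # s after target onset
    pursuit_time_constant: float = 0.12  # s, first-order approach to 8 deg/s
    anticipation_window: float = 0.3  # s before onset where the ASEM ramp starts
    ramp_end_margin: float = 0.08  # s before onset where the ramp plateaus
    saccade_rate: float = 0.4  # spontaneous events/s
    blink_prob: float = 0.1  # per-trial probability
    noise_sd_eye: float = 0.2  # deg/s white velocity noise on the eye
    noise_sd_cursor: float = 0.005  # deg white position noise on the cursor
    reach_duration: float = 0.4  # s, bell-velocity reach
    aim_error_sd: float = 0.5  # deg, horizontal scatter of the reach endpoint
    start_position: Tuple[float, float] = (0.0, -15.0)  # deg
    onset_time: float = 0.8  # s on the trial clock
    trial_duration: float = 2.0  # s
    latency_floor: float = 0.05  # s, clip for non-violation trials
    latency_ceiling: float = 0.45  # s, keeps non-violation trials retainable
    violation_fraction: float = 0.0  # planted excludable-trial fraction
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.trials_per_cell < 1:
            raise ConfigurationError("participant and trial counts must be >= 1")
        if len(self.coherence_levels) == 0:
            raise ConfigurationError("coherence_levels must not be empty")
        levels = sorted(self.coherence_levels)
        if any(abs(lo + hi) > 1e-12 for lo, hi in zip(levels, reversed(levels))):
            raise ConfigurationError("coherence levels must be symmetric about 0")
        for name in ("eye_rate", "cursor_rate", "target_speed"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.violation_fraction <= 1:
            raise ConfigurationError("violation_fraction must be in [0, 1]")
        if not 0 <= self.blink_prob <= 1:
            raise ConfigurationError("blink_prob must be in [0, 1]")
        for name in ("asem_trial_sd", "noise_sd_eye", "noise_sd_cursor",
                     "aim_error_sd", "saccade_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.onset_time - self.anticipation_window <= 0:
            raise ConfigurationError("anticipation window precedes the trial")
        if self.trial_duration <= self.onset_time:
            raise ConfigurationError("trial must extend beyond target onset")
        self.sigmoid_population.validate()
        self.latency_population.validate()


@dataclass
class AnalysisConfig:
    """Measurement-protocol constants plus the genuinely open choices."""

    eye_position_cutoff: float = 15.0  # Hz
    eye_velocity_cutoff: float = 30.0  # Hz (also acceleration)
    cursor_cutoff: float = 20.0  # Hz
    saccade_velocity_threshold: float = 30.0  # deg/s
    saccade_accel_threshold: float = 1000.0  # deg/s^2
    saccade_pad: float = 0.010  # s each side of a detected interval
    saccade_axis: str = "x"  # "x" or "magnitude" for the joint criterion
    blink_pad: float = 0.050  # s each side of a missing-sample run
    asem_halfwindow: float = 0.050  # s each side of target onset
    onset_speed_threshold: float = 1.0  # deg/s, 2-D cursor speed
    initial_accel_window: float = 0.100  # s after target onset
    max_latency: float = 0.500  # s, exclusion cutoff
    pre_onset_guard: float = 0.050  # s skipped at trace start (filter warm-up)
    extreme_fraction: float = 0.20  # upper/lower stratum fraction
    min_cell_trials: int = 5  # for the extreme-stratum analysis
    fit_sigma_bounds: Tuple[float, float] = (1e-3, 2.0)
    fit_mu_bound: float = 1.0
    inverse_variance_weighting: bool = False
    greenhouse_geisser: bool = False
    lme_min_trials: int = 10  # per participant

    def validate(self) -> None:
        for name in ("eye_position_cutoff", "eye_velocity_cutoff", "cursor_cutoff",
                     "saccade_velocity_threshold", "saccade_accel_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.saccade_axis not in ("x", "magnitude"):
            raise ConfigurationError("saccade_axis must be 'x' or 'magnitude'")
        if not 0 < self.extreme_fraction <= 0.5:
            raise ConfigurationError("extreme_fraction must be in (0, 0.5]")
        if self.max_latency < 0:
            raise ConfigurationError("max_latency must be >= 0")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_hash(*configs) -> str:
    """Stable hash identifying a configuration set; stamped on outputs."""
    payload = json.dumps([_to_plain(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _from_dict(cls, data: dict):
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise ConfigurationError(f"unknown {cls.__name__} key: {key!r}")
        ftype = fields[key].type
        if key == "sigmoid_population":
            value = SigmoidPopulation(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in value.items()})
        elif key == "latency_population":
            value = LatencyPopulation(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in value.items()})
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> Tuple[SimulationConfig, AnalysisConfig]:
    """Read a YAML config file with optional ``simulation:``/``analysis:`` blocks."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = _from_dict(SimulationConfig, data.get("simulation", {}))
    ana = _from_dict(AnalysisConfig, data.get("analysis", {}))
    sim.validate()
    ana.validate()
    return sim, ana


def dump_config(sim: SimulationConfig, ana: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"simulation": _to_plain(sim), "analysis": _to_plain(ana)}, fh)
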