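"""Psychometric curve fitting and pooled ASEM-velocity distributions.

Two response curves are fitted to condition x coherence cell means:

* a cumulative Gaussian (sigmoid) for ASEM velocity,
      v(x) = a/2 (1 + erf((x - mu)/(sigma sqrt(2)))) + b,
  where ``a`` is the height (the amplitude measure contrasted between
  conditions) and ``b`` the baseline;
* a Gaussian for interception latency,
      L(x) = c exp(-(x - mu)^2 / (2 sigma^2)) + d,
  where ``c`` is the peak amplitude and ``d`` the offset contrasted between
  conditions.

Fits are nonlinear least squares with multi-start initialization (nine-point
coherence designs are initialization-sensitive) and bounds sigma in
(1e-3, 2], |mu| <= 1. r^2 is 1 - SS_res/SS_tot on the fitted points and is
reported as computed (it can be negative for pathological fits; summary
display clips at 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synth import cumulative_gaussian, gaussian_latency
from .types import CumulativeGaussianFit, GaussianLatencyFit


class InsufficientDataError(ValueError):
    """Too few coherence points (or trials) for the requested fit."""


_MULTISTART = ((0.0, 0.1), (0.0, 0.3), (-0.2, 0.2), (0.2, 0.2), (0.0, 0.2))


def _fit_curve(model, x, y, p0_amp, p0_off, sigma_bounds=(1e-3, 2.0),
               mu_bound=1.0, weights=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("coherences and means must have equal lengths")
    if len(x) < 5:
        raise InsufficientDataError("need >= 5 coherence points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-20:
        # flat data: amplitude ~ 0, spread unidentifiable
        return ((0.0, 0.0, math.nan, float(y.mean())), 0.0, False)

    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))
    lo = [-np.inf, -mu_bound, sigma_bounds[0], -np.inf]
    hi = [np.inf, mu_bound, sigma_bounds[1], np.inf]

    best = None
    for mu0, sig0 in _MULTISTART:
        p0 = np.array([p0_amp, mu0, sig0, p0_off])

        def residuals(p):
            return w * (model(x, *p) - y)

        try:
            res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return ((p0_amp, 0.0, math.nan, p0_off), 0.0, False)

    amp, mu, sigma, off = best.x
    ss_res = float(np.sum((model(x, amp, mu, sigma, off) - y) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    interior = (sigma_bounds[0] * (1 + 1e-6) < sigma < sigma_bounds[1] * (1 - 1e-6))
    converged = bool(best.success and interior)
    return ((float(amp), float(mu), float(sigma), float(off)), float(r2), converged)


def fit_cumulative_gaussian(means: Sequence[float], coherences: Sequence[float],
                            weights=None) -> CumulativeGaussianFit:
    """Least-squares sigmoid fit of per-coherence ASEM-velocity means."""
    y = np.asarray(means, dtype=float)
    amp0 = float(y.max() - y.min()) or 1.0
    (a, mu, sigma, b), r2, converged = _fit_curve(
        cumulative_gaussian, coherences, y, amp0, float(y.min()), weights=weights)
    return CumulativeGaussianFit(a=a, mu=mu, sigma=sigma, b=b,
                                 r_squared=r2, converged=converged)


def fit_latency_gaussian(means: Sequence[float], coherences: Sequence[float],
                         weights=None) -> GaussianLatencyFit:
    """Least-squares Gaussian fit of per-coherence latency means."""
    y = np.asarray(means, dtype=float)
    amp0 = float(y.max() - y.min()) or 0.1
    (c, mu, sigma, d), r2, converged = _fit_curve(
        gaussian_latency, coherences, y, amp0, float(y.min()), weights=weights)
    return GaussianLatencyFit(c=c, mu=mu, sigma=sigma, d=d,
                              r_squared=r2, converged=converged)


def cell_means(features: pd.DataFrame, value: str,
               retained_only: bool = True) -> pd.DataFrame:
    """Participant x condition x coherence mean of ``value``."""
    df = features
    if retained_only and "retained" in df.columns:
        df = df[df["retained"]]
    return (df.groupby(["participant", "condition", "coherence"], sort=True)
            [value].mean().reset_index())


def fit_participant_curves(features: pd.DataFrame) -> pd.DataFrame:
    """Fit Eq-type curves per participant x condition.

    Returns one row per (participant, condition) with the sigmoid parameters
    for ASEM velocity (a, mu, sigma, b, r2_asem) and the Gaussian parameters
    for latency (c, lat_mu, lat_sigma, d, r2_latency).
    """
    asem = cell_means(features, "asem_velocity")
    lat = cell_means(features, "latency")
    rows = []
    for (pid, cond), grp in asem.groupby(["participant", "condition"]):
        grp = grp.sort_values("coherence")
        sig = fit_cumulative_gaussian(grp["asem_velocity"], grp["coherence"])
        lgrp = lat[(lat["participant"] == pid) & (lat["condition"] == cond)]
        lgrp = lgrp.sort_values("coherence")
        gau = fit_latency_gaussian(lgrp["latency"], lgrp["coherence"])
        rows.append({
            "participant": pid, "condition": cond,
            "a": sig.a, "mu": sig.mu, "sigma": sig.sigma, "b": sig.b,
            "r2_asem": sig.r_squared, "asem_converged": sig.converged,
            "c": gau.c, "lat_mu": gau.mu, "lat_sigma": gau.sigma, "d": gau.d,
            "r2_latency": gau.r_squared, "latency_converged": gau.converged,
        })
    return pd.DataFrame(rows)


def condition_contrast(fits: pd.DataFrame, parameter: str,
                       conditions: Tuple[str, str] = ("control", "gap")
                       ) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Paired per-participant values of ``parameter`` for the two conditions.

    Returns (control values, gap values, participant order); raises when a
    participant is missing a condition fit.
    """
    first, second = conditions
    pivot = fits.pivot(index="participant", columns="condition", values=parameter)
    for cond in conditions:
        missing = pivot.index[pivot[cond].isna()] if cond in pivot else pivot.index
        if cond not in pivot.columns or len(missing):
            who = list(missing) if cond in pivot.columns else list(pivot.index)
            raise ValueError(f"missing {cond} fit for participants: {who}")
    participants = list(pivot.index)
    return (pivot[first].to_numpy(), pivot[second].to_numpy(), participants)


# ---------------------------------------------------------------------------
# pooled z-normalized distributions

@dataclass
class NormalizedDistribution:
    """Within-participant z-scores pooled across the cohort.

    ``scores`` carries one row per trial with its z-score; ``groups`` maps
    (condition, coherence) to (sorted support, cumulative frequency 0..1).
    """

    scores: pd.DataFrame
    groups: Dict[Tuple[str, float], Tuple[np.ndarray, np.ndarray]]


def znormalize_and_pool(features: pd.DataFrame,
                        value: str = "asem_velocity",
                        retained_only: bool = True) -> NormalizedDistribution:
    """Z-normalize per participant across ALL that participant's trials, pool,
    and build cumulative frequency curves per condition x coherence group."""
    df = features
    if retained_only and "retained" in df.columns:
        df = df[df["retained"]]
    df = df.copy()

    def _z(group):
        if len(group) < 2:
            raise InsufficientDataError(
                f"participant {group.name} has fewer than 2 trials")
        sd = group[value].std(ddof=0)
        if sd == 0:
            raise ValueError(
                f"participant {group.name} has zero within-participant variance")
        return (group[value] - group[value].mean()) / sd

    df["z"] = df.groupby("participant", group_keys=False).apply(
        _z, include_groups=False)

    groups = {}
    for (cond, coh), grp in df.groupby(["condition", "coherence"]):
        support = np.sort(grp["z"].to_numpy())
        cumfreq = (np.linspace(0.0, 1.0, len(support)) if len(support) > 1
                   else np.array([1.0]))
        groups[(cond, float(coh))] = (support, cumfreq)
    return NormalizedDistribution(scores=df, groups=groups)


# ---------------------------------------------------------------------------
# unimodality (dip-type) statistic

def _convex_minorant_gap(x: np.ndarray, f: np.ndarray) -> float:
    """Max gap between f and its greatest convex minorant on (x, f)."""
    hull_x: List[float] = []
    hull_f: List[float] = []
    for xi, fi in zip(x, f):
        hull_x.append(xi)
        hull_f.append(fi)
        while len(hull_x) >= 3:
            x0, x1, x2 = hull_x[-3], hull_x[-2], hull_x[-1]
            f0, f1, f2 = hull_f[-3], hull_f[-2], hull_f[-1]
            if (f1 - f0) * (x2 - x1) <= (f2 - f1) * (x1 - x0) + 1e-15:
                break
            del hull_x[-2], hull_f[-2]
    gcm = np.interp(x, hull_x, hull_f)
    return float(np.max(f - gcm))


def dip_statistic(samples: np.ndarray) -> float:
    """Sup-norm distance from the empirical CDF to the nearest unimodal CDF.

    Computed by scanning candidate modes: left of the mode the CDF must be
    convex (distance = half the greatest-convex-minorant gap), right of it
    concave (mirror image). The minimum over modes is the statistic. Its null
    distribution depends on sample size, so tests compare against a
    critical value simulated with the same function.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 4:
        return 0.0
    f = (np.arange(1, n + 1) - 0.5) / n
    best = math.inf
    for m in range(n):
        left = _convex_minorant_gap(x[: m + 1], f[: m + 1]) if m >= 2 else 0.0
        right = (_convex_minorant_gap(-x[m:][::-1], -f[m:][::-1])
                 if n - m >= 3 else 0.0)
        best = min(best, max(left, right))
    return 0.5 * best
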