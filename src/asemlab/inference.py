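"""Statistical layer: paired tests, repeated-measures ANOVA with Holm post
hocs, the three-candidate mixed-model comparison by BIC, per-participant
regressions, and the extreme-stratum control analysis.

Mixed models are fitted by maximum likelihood (not REML) because the three
candidates differ in random-effects structure and the fixed-only candidate
has no REML analogue; BIC is computed as -2 logLik + k ln(n_obs) with k the
number of estimated parameters (fixed effects + unique random-effect
covariance entries + residual variance). The fixed-slope test uses the
residual-df convention df = n_obs - rank(fixed design).

The two-way repeated-measures ANOVA is computed from balanced within-subject
sums of squares directly (each effect tested against its effect-by-subject
interaction), which keeps the degenerate cases well-defined: a zero effect
sum of squares yields F = 0, p = 1, and a non-zero effect with zero error
yields p = 0. A Greenhouse-Geisser correction is available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .types import (LMEComparison, LMEFitResult, PairedTestResult,
                    ParticipantRegression)

MODEL_RANDOM_SLOPE = "random_slope_intercept"
MODEL_RANDOM_INTERCEPT = "random_intercept"
MODEL_FIXED_ONLY = "fixed_only"


class DegenerateDataError(ValueError):
    """The requested statistic is undefined for this input."""


# ---------------------------------------------------------------------------
# paired comparisons

def paired_t_cohens_d(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t test with both Cohen's d conventions.

    ``cohens_d`` is mean(diff)/sd(diff) (d_z); ``cohens_d_av`` divides by the
    average of the two level SDs instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal lengths")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, cohens_d=0.0,
                                    cohens_d_av=0.0, mean_diff=0.0, n=n)
        raise DegenerateDataError("zero variance of paired differences")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    sd_av = 0.5 * (x.std(ddof=1) + y.std(ddof=1))
    d_av = mean / sd_av if sd_av > 0 else math.nan
    return PairedTestResult(t=float(t), df=n - 1, p=float(p),
                            cohens_d=float(mean / sd), cohens_d_av=float(d_av),
                            mean_diff=float(mean), n=n)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, never below raw)."""
    return multipletests(np.asarray(p_values, float), method="holm")[1]


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA

@dataclass
class AnovaResult:
    table: pd.DataFrame  # effect, F, df1, df2, p (and p_gg if requested)
    posthoc: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _f_and_p(ss_effect, df_effect, ss_error, df_error):
    if ss_effect <= 1e-14 * max(1.0, ss_error):
        return 0.0, 1.0
    if ss_error <= 1e-14 * ss_effect:
        return math.inf, 0.0
    f = (ss_effect / df_effect) / (ss_error / df_error)
    return float(f), float(stats.f.sf(f, df_effect, df_error))


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x level scores."""
    k = scores.shape[1]
    if k < 3:
        return 1.0
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1].T  # orthonormal contrasts
    v = c @ np.cov(scores, rowvar=False) @ c.T
    tr = np.trace(v)
    denom = (k - 1) * np.trace(v @ v)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), tr ** 2 / denom)))


def rm_anova_holm(features: pd.DataFrame, dv: str,
                  factors: Tuple[str, str] = ("condition", "coherence"),
                  subject: str = "participant",
                  config: AnalysisConfig = None,
                  alpha: float = 0.05) -> AnovaResult:
    """Two-way within-subject ANOVA on per-cell participant means of ``dv``.

    Requires a complete subject x cell design (an error lists any missing
    cells); significant main effects are followed by Holm-corrected pairwise
    paired t tests on the marginal means.
    """
    cfg = config or AnalysisConfig()
    fa, fb = factors
    df = features
    if "retained" in df.columns:
        df = df[df["retained"]]
    cells = (df.dropna(subset=[dv])
             .groupby([subject, fa, fb])[dv].mean().reset_index())

    subjects = sorted(cells[subject].unique())
    a_levels = sorted(cells[fa].unique())
    b_levels = sorted(cells[fb].unique())
    pivot = cells.set_index([subject, fa, fb])[dv]
    missing = [
        (s, a, b) for s in subjects for a in a_levels for b in b_levels
        if (s, a, b) not in pivot.index
    ]
    if missing:
        raise DegenerateDataError(f"missing design cells: {missing[:10]}"
                                  + ("..." if len(missing) > 10 else ""))
    y = np.array([[[pivot[(s, a, b)] for b in b_levels] for a in a_levels]
                  for s in subjects])  # (n, A, B)
    n, na, nb = y.shape

    grand = y.mean()
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    s_m = y.mean(axis=(1, 2))
    as_m = y.mean(axis=2)
    bs_m = y.mean(axis=1)
    ab_m = y.mean(axis=0)

    ss_a = nb * n * np.sum((a_m - grand) ** 2)
    ss_b = na * n * np.sum((b_m - grand) ** 2)
    ss_ab = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_as = nb * np.sum((as_m - a_m[None, :] - s_m[:, None] + grand) ** 2)
    ss_bs = na * np.sum((bs_m - b_m[None, :] - s_m[:, None] + grand) ** 2)
    resid = (y - ab_m[None, :, :] - as_m[:, :, None] - bs_m[:, None, :]
             + a_m[None, :, None] + b_m[None, None, :] + s_m[:, None, None]
             - grand)
    ss_abs = np.sum(resid ** 2)

    rows = []
    specs = [
        (fa, ss_a, na - 1, ss_as, (na - 1) * (n - 1), as_m),
        (fb, ss_b, nb - 1, ss_bs, (nb - 1) * (n - 1), bs_m),
        (f"{fa}:{fb}", ss_ab, (na - 1) * (nb - 1), ss_abs,
         (na - 1) * (nb - 1) * (n - 1), y.reshape(n, na * nb)),
    ]
    for name, ss_e, df_e, ss_err, df_err, scores in specs:
        f, p = _f_and_p(ss_e, df_e, ss_err, df_err)
        row = {"effect": name, "F": f, "df1": df_e, "df2": df_err, "p": p}
        if cfg.greenhouse_geisser and np.isfinite(f):
            eps = _gg_epsilon(np.asarray(scores, float))
            row["epsilon_gg"] = eps
            row["p_gg"] = (float(stats.f.sf(f, df_e * eps, df_err * eps))
                           if 0 < f < math.inf else p)
        rows.append(row)
    table = pd.DataFrame(rows)

    posthoc: Dict[str, pd.DataFrame] = {}
    for name, levels, marginal in ((fa, a_levels, as_m), (fb, b_levels, bs_m)):
        p_eff = float(table.loc[table["effect"] == name, "p"].iloc[0])
        if p_eff >= alpha or len(levels) < 2:
            continue
        pairs, raw = [], []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                try:
                    res = paired_t_cohens_d(marginal[:, i], marginal[:, j])
                    t_ij, p_ij = res.t, res.p
                except DegenerateDataError:
                    # identical nonzero difference in every subject
                    diff = float(np.mean(marginal[:, i] - marginal[:, j]))
                    t_ij, p_ij = math.copysign(math.inf, diff), 0.0
                pairs.append((levels[i], levels[j], t_ij, p_ij))
                raw.append(p_ij)
        adj = holm_adjust(raw)
        posthoc[name] = pd.DataFrame(
            [{"level_a": a, "level_b": b, "t": t, "p_raw": p, "p_holm": ph}
             for (a, b, t, p), ph in zip(pairs, adj)])
    return AnovaResult(table=table, posthoc=posthoc)


# ---------------------------------------------------------------------------
# mixed-effects comparison

def _ols_ml_fit(x: np.ndarray, y: np.ndarray) -> LMEFitResult:
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sigma2_ml = ssr / n
    llf = -0.5 * n * (math.log(2.0 * math.pi * sigma2_ml) + 1.0)
    k = 3  # intercept, slope, residual variance
    bic = -2.0 * llf + k * math.log(n)
    cov = ssr / (n - 2) * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta[1] / se[1]
    df = n - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    var_fixed = float(np.var(X @ beta))
    r2 = var_fixed / (var_fixed + sigma2_ml) if var_fixed + sigma2_ml > 0 else 0.0
    return LMEFitResult(
        formula_id=MODEL_FIXED_ONLY,
        fixed_intercept=float(beta[0]), fixed_slope=float(beta[1]),
        fixed_intercept_se=float(se[0]), fixed_slope_se=float(se[1]),
        slope_t=float(t), slope_df=df, slope_p=float(p),
        random_effect_variances={}, loglik=float(llf), n_params=k,
        bic=float(bic), n_obs=n, singular=False,
        participant_intercepts={}, participant_slopes={},
        r2_marginal=r2, r2_conditional=r2,
    )


def _mixed_fit(x: np.ndarray, y: np.ndarray, groups: np.ndarray,
               random_slope: bool) -> LMEFitResult:
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    exog_re = X if random_slope else np.ones((n, 1))
    model = MixedLM(y, X, groups=groups, exog_re=exog_re)

    def _ok(res):
        try:
            return (np.isfinite(res.llf)
                    and np.all(np.isfinite(np.asarray(res.fe_params, float)))
                    and np.all(np.isfinite(np.asarray(res.bse_fe, float))))
        except Exception:
            return False

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = None
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                candidate = model.fit(reml=False, method=method)
            except Exception:
                continue
            if not np.isfinite(candidate.llf):
                continue
            if result is None or candidate.llf > result.llf + 1e-8:
                result = candidate
            if _ok(result):
                break
        if result is None:
            raise DegenerateDataError("mixed-model likelihood did not converge")
        fe = np.asarray(result.fe_params, dtype=float)
        se = np.asarray(result.bse_fe, dtype=float)
        if not np.all(np.isfinite(se)):
            # fall back to the OLS standard errors; flagged singular below
            n_ = len(y)
            resid_ = y - X @ fe
            cov_ = float(resid_ @ resid_) / (n_ - 2) * np.linalg.inv(X.T @ X)
            se = np.sqrt(np.diag(cov_))
    cov_re = np.atleast_2d(np.asarray(result.cov_re, dtype=float))
    sigma2 = float(result.scale)
    k = 2 + (3 if random_slope else 1) + 1
    llf = float(result.llf)
    bic = -2.0 * llf + k * math.log(n)
    df = n - 2
    t = fe[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), df)

    eig = np.linalg.eigvalsh(cov_re)
    singular = bool(eig.min() < 1e-10 * max(eig.max(), 1e-12))

    intercepts, slopes = {}, {}
    try:
        blups = result.random_effects
    except (ValueError, np.linalg.LinAlgError):
        blups = {gid: np.zeros(exog_re.shape[1]) for gid in np.unique(groups)}
    for gid, re in blups.items():
        re = np.asarray(re, dtype=float)
        intercepts[gid] = float(fe[0] + re[0])
        slopes[gid] = float(fe[1] + (re[1] if random_slope else 0.0))

    var_fixed = float(np.var(X @ fe))
    if random_slope:
        z = X
        var_re = float(np.mean(np.einsum("ij,jk,ik->i", z, cov_re, z)))
        variances = {"intercept": float(cov_re[0, 0]),
                     "slope": float(cov_re[1, 1]),
                     "intercept_slope_cov": float(cov_re[0, 1]),
                     "residual": sigma2}
    else:
        var_re = float(cov_re[0, 0])
        variances = {"intercept": float(cov_re[0, 0]), "residual": sigma2}
    total = var_fixed + var_re + sigma2
    r2m = var_fixed / total if total > 0 else math.nan
    r2c = (var_fixed + var_re) / total if total > 0 else math.nan

    return LMEFitResult(
        formula_id=MODEL_RANDOM_SLOPE if random_slope else MODEL_RANDOM_INTERCEPT,
        fixed_intercept=float(fe[0]), fixed_slope=float(fe[1]),
        fixed_intercept_se=float(se[0]), fixed_slope_se=float(se[1]),
        slope_t=float(t), slope_df=df, slope_p=float(p),
        random_effect_variances=variances, loglik=llf, n_params=k,
        bic=float(bic), n_obs=n, singular=singular,
        participant_intercepts=intercepts, participant_slopes=slopes,
        r2_marginal=r2m, r2_conditional=r2c,
    )


def fit_lme_candidates(trials: pd.DataFrame,
                       asem_col: str = "asem_velocity_signed",
                       latency_col: str = "latency",
                       participant_col: str = "participant",
                       min_trials: int = 10) -> LMEComparison:
    """Fit the three candidate latency ~ ASEM-velocity models and compare BIC.

    Candidates: correlated random intercept + slope per participant, random
    intercept only, and fixed effects only. The minimum-BIC model is
    selected (ties break toward the simpler model).
    """
    df = trials.dropna(subset=[asem_col, latency_col])
    counts = df.groupby(participant_col).size()
    if len(counts) < 2:
        raise DegenerateDataError("need >= 2 participants")
    if (counts < min_trials).any():
        low = list(counts[counts < min_trials].index)
        raise DegenerateDataError(f"participants below {min_trials} trials: {low}")
    x = df[asem_col].to_numpy(dtype=float)
    y = df[latency_col].to_numpy(dtype=float)
    groups = df[participant_col].to_numpy()
    if np.ptp(x) < 1e-12:
        raise DegenerateDataError("ASEM velocity is constant; slope unidentifiable")

    fits = {
        MODEL_RANDOM_SLOPE: _mixed_fit(x, y, groups, random_slope=True),
        MODEL_RANDOM_INTERCEPT: _mixed_fit(x, y, groups, random_slope=False),
        MODEL_FIXED_ONLY: _ols_ml_fit(x, y),
    }
    selected = min(fits, key=lambda name: (fits[name].bic, fits[name].n_params))
    return LMEComparison(fits=fits, selected=selected)


# ---------------------------------------------------------------------------
# per-participant effects and correlations

def participant_effects(trials: pd.DataFrame,
                        asem_col: str = "asem_velocity_signed",
                        latency_col: str = "latency",
                        participant_col: str = "participant",
                        min_trials: int = 10) -> List[ParticipantRegression]:
    """Simple per-participant regressions of latency on signed ASEM velocity."""
    df = trials.dropna(subset=[asem_col, latency_col])
    out = []
    for pid, grp in df.groupby(participant_col):
        if len(grp) < min_trials:
            continue
        res = stats.linregress(grp[asem_col], grp[latency_col])
        out.append(ParticipantRegression(
            participant=pid, slope=float(res.slope),
            intercept=float(res.intercept), r_squared=float(res.rvalue ** 2),
            mean_latency=float(grp[latency_col].mean()), n_trials=len(grp)))
    return out


def correlate(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with two-sided p across participants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateDataError("need >= 3 paired values")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# extreme-stratum control analysis

def extreme_quintile_contrast(trials: pd.DataFrame,
                              fraction: float = 0.20,
                              min_cell_trials: int = 5,
                              asem_col: str = "asem_velocity_signed",
                              latency_col: str = "latency",
                              condition: Optional[str] = "control"
                              ) -> Tuple[PairedTestResult, int]:
    """Upper- vs lower-ASEM-stratum latency contrast within coherence cells.

    Within each participant x coherence cell (control condition by default),
    trials are ranked by signed ASEM velocity (stable sort, ties broken by
    trial order) and the top and bottom floor(fraction * n) trials (minimum
    1) are selected; cells with fewer than ``min_cell_trials`` usable trials
    are skipped and counted. Latencies are averaged per participant per
    stratum and contrasted with a paired t test (upper minus lower).

    Returns the test result and the number of skipped cells.
    """
    df = trials
    if condition is not None:
        df = df[df["condition"] == condition]
    if "retained" in df.columns:
        df = df[df["retained"]]
    df = df.dropna(subset=[asem_col, latency_col])

    upper: Dict[str, List[float]] = {}
    lower: Dict[str, List[float]] = {}
    skipped = 0
    for (pid, _coh), grp in df.groupby(["participant", "coherence"]):
        n = len(grp)
        if n < min_cell_trials:
            skipped += 1
            continue
        k = max(1, int(math.floor(fraction * n)))
        ordered = grp.sort_values(asem_col, kind="stable")
        lower.setdefault(pid, []).extend(ordered[latency_col].iloc[:k])
        upper.setdefault(pid, []).extend(ordered[latency_col].iloc[-k:])

    participants = sorted(set(upper) & set(lower))
    if len(participants) < 3:
        raise DegenerateDataError("too few participants with usable cells")
    up = np.array([np.mean(upper[p]) for p in participants])
    lo = np.array([np.mean(lower[p]) for p in participants])
    return paired_t_cohens_d(up, lo), skipped
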