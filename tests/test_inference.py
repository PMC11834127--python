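"""Statistics-layer tests: paired t, Holm, rmANOVA, LME comparison,
per-participant regressions, and the extreme-stratum contrast."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import asemlab as al
from asemlab.config import LatencyPopulation, SimulationConfig
from asemlab.inference import (DegenerateDataError, MODEL_FIXED_ONLY,
                               MODEL_RANDOM_INTERCEPT, MODEL_RANDOM_SLOPE,
                               extreme_quintile_contrast, holm_adjust,
                               paired_t_cohens_d, rm_anova_holm)
from asemlab.synth import simulate_trial_table


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t_cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.cohens_d == 0.0

    def test_hand_computed_example(self):
        # differences (-1, -2, -3): mean -2, sd 1 -> t = -2/(1/sqrt(3))
        res = paired_t_cohens_d([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(-3.4641, abs=1e-4)
        assert res.df == 2
        assert res.cohens_d == pytest.approx(-2.0)
        assert res.mean_diff == pytest.approx(-2.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        fwd = paired_t_cohens_d(x, y)
        rev = paired_t_cohens_d(y, x)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.cohens_d == pytest.approx(-rev.cohens_d)
        assert fwd.p == pytest.approx(rev.p)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_ttest_rel(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1.0, 12)
        y = rng.normal(0.0, 1.0, 12)
        res = paired_t_cohens_d(x, y)
        t_ref, p_ref = stats.ttest_rel(x, y)
        assert res.t == pytest.approx(t_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            paired_t_cohens_d([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestHolm:
    def test_worked_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_stepwise_definition_oracle(self, rng):
        p = rng.uniform(0, 1, 7)
        # direct stepwise Holm: sort, multiply by (m - rank), cummax, cap at 1
        order = np.argsort(p)
        m = len(p)
        adj_sorted = np.minimum(1.0, np.maximum.accumulate(
            (m - np.arange(m)) * p[order]))
        expected = np.empty(m)
        expected[order] = adj_sorted
        assert np.allclose(holm_adjust(p), expected)

    def test_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 9)
        assert np.all(holm_adjust(p) >= p - 1e-15)


class TestRmAnova:
    COHS = [-0.32, 0.0, 0.32]

    def _df(self, fn, n_sub=6):
        rows = []
        for s in range(n_sub):
            for cond in ("control", "gap"):
                for coh in self.COHS:
                    rows.append({"participant": f"p{s}", "condition": cond,
                                 "coherence": coh, "dv": fn(s, cond, coh),
                                 "retained": True})
        return pd.DataFrame(rows)

    def test_constant_dv_gives_zero_f(self):
        res = rm_anova_holm(self._df(lambda s, c, x: 1.0), "dv")
        assert (res.table.F == 0.0).all()
        assert (res.table.p == 1.0).all()

    def test_participant_offsets_only(self):
        res = rm_anova_holm(self._df(lambda s, c, x: float(s)), "dv")
        assert (res.table.F == 0.0).all()

    def test_planted_condition_effect_zero_noise(self):
        res = rm_anova_holm(
            self._df(lambda s, c, x: float(s) + (0.5 if c == "gap" else 0.0)),
            "dv")
        tab = res.table.set_index("effect")
        assert tab.loc["condition", "p"] == 0.0
        assert tab.loc["coherence", "F"] == 0.0
        assert tab.loc["condition:coherence", "F"] == 0.0

    def test_matches_anovarm_oracle(self, rng):
        df = self._df(lambda s, c, x:
                      rng.normal() + (0.4 if c == "gap" else 0) + x)
        res = rm_anova_holm(df, "dv")
        from statsmodels.stats.anova import AnovaRM
        oracle = AnovaRM(df, "dv", "participant",
                         within=["condition", "coherence"]).fit().anova_table
        ours = res.table.set_index("effect")
        for effect, key in (("condition", "condition"),
                            ("coherence", "coherence"),
                            ("condition:coherence", "condition:coherence")):
            assert ours.loc[effect, "F"] == pytest.approx(
                oracle.loc[key, "F Value"], abs=1e-9)
            assert ours.loc[effect, "p"] == pytest.approx(
                oracle.loc[key, "Pr > F"], abs=1e-9)

    def test_posthoc_holm_on_significant_effects(self, rng):
        df = self._df(lambda s, c, x: rng.normal(0, 0.05) + x)
        res = rm_anova_holm(df, "dv")
        assert "coherence" in res.posthoc
        ph = res.posthoc["coherence"]
        assert len(ph) == 3  # 3 coherence levels -> 3 pairs
        assert np.all(ph.p_holm >= ph.p_raw - 1e-15)

    def test_missing_cell_rejected(self):
        df = self._df(lambda s, c, x: 1.0)
        df = df[~((df.participant == "p0") & (df.condition == "gap")
                  & (df.coherence == 0.0))]
        with pytest.raises(DegenerateDataError, match="missing"):
            rm_anova_holm(df, "dv")


def _trial_df(seed=0, beta1=(-0.03, 0.01), n_participants=6, trials_per_cell=5,
              residual_sd=0.05):
    lp = LatencyPopulation(c=(0.0, 0.0), beta1=beta1, residual_sd=residual_sd)
    cfg = SimulationConfig(n_participants=n_participants,
                           trials_per_cell=trials_per_cell, seed=seed,
                           latency_population=lp)
    _, trials = simulate_trial_table(cfg)
    trials["asem_velocity_signed"] = trials.true_asem * trials.direction
    trials["latency"] = trials.true_latency
    return trials


class TestLMECandidates:
    def test_noise_free_recovery_random_intercept(self):
        # distinct participant intercepts, one common slope, no noise:
        # the random-intercept fixed slope is exact and the fuller model's
        # slope variance collapses
        rng = np.random.default_rng(4)
        rows = []
        for i in range(5):
            b0 = 0.25 + 0.03 * i
            x = rng.uniform(-1, 1, 40)
            for xi in x:
                rows.append({"participant": f"p{i}",
                             "asem_velocity_signed": xi,
                             "latency": b0 - 0.03 * xi})
        df = pd.DataFrame(rows)
        cmp_ = al.fit_lme_candidates(df)
        ri = cmp_.fits[MODEL_RANDOM_INTERCEPT]
        assert ri.fixed_slope == pytest.approx(-0.03, abs=1e-8)
        rs = cmp_.fits[MODEL_RANDOM_SLOPE]
        assert rs.random_effect_variances["slope"] == pytest.approx(0.0, abs=1e-6)

    def test_random_slope_model_wins_with_slope_heterogeneity(self):
        trials = _trial_df(seed=21, beta1=(-0.03, 0.03),
                           n_participants=10, trials_per_cell=5)
        cmp_ = al.fit_lme_candidates(trials)
        assert cmp_.selected == MODEL_RANDOM_SLOPE
        # OLS oracle: average per-participant slope agrees within 2 SE
        ols = [stats.linregress(g.asem_velocity_signed, g.latency).slope
               for _, g in trials.groupby("participant")]
        sel = cmp_.selected_fit
        assert abs(sel.fixed_slope - np.mean(ols)) < 2 * sel.fixed_slope_se

    def test_fixed_only_bic_matches_closed_form_ols(self):
        trials = _trial_df(seed=5)
        cmp_ = al.fit_lme_candidates(trials)
        fo = cmp_.fits[MODEL_FIXED_ONLY]
        x = trials.asem_velocity_signed.to_numpy()
        y = trials.latency.to_numpy()
        n = len(y)
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = float(np.sum((y - X @ beta) ** 2)) / n
        llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
        bic = -2 * llf + 3 * math.log(n)
        assert fo.bic == pytest.approx(bic, abs=1e-8)
        assert fo.loglik == pytest.approx(llf, abs=1e-8)

    def test_bic_formula_invariant(self):
        trials = _trial_df(seed=6)
        cmp_ = al.fit_lme_candidates(trials)
        for fit in cmp_.fits.values():
            expected = -2 * fit.loglik + fit.n_params * math.log(fit.n_obs)
            assert fit.bic == pytest.approx(expected, abs=1e-9)
            for v in fit.random_effect_variances.values():
                if not v == fit.random_effect_variances.get("intercept_slope_cov"):
                    assert v >= -1e-12

    def test_constant_asem_rejected(self):
        trials = _trial_df(seed=7)
        trials["asem_velocity_signed"] = 0.5
        with pytest.raises(DegenerateDataError, match="unidentifiable"):
            al.fit_lme_candidates(trials)

    def test_too_few_trials_rejected(self):
        trials = _trial_df(seed=8).groupby("participant").head(5)
        with pytest.raises(DegenerateDataError):
            al.fit_lme_candidates(trials)


class TestParticipantEffects:
    def test_collinear_correlation(self):
        r, p = al.correlate([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # x=(1,2,3,4), y=(2,1,4,3): cov = 1, sd_x sd_y -> r = 0.6
        r, _ = al.correlate([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_covariance(self):
        r, _ = al.correlate([-1, 1, -1, 1], [-1, -1, 1, 1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_regressions_match_linregress(self):
        trials = _trial_df(seed=9)
        effects = al.participant_effects(trials)
        assert len(effects) == trials.participant.nunique()
        for eff in effects:
            grp = trials[trials.participant == eff.participant]
            ref = stats.linregress(grp.asem_velocity_signed, grp.latency)
            assert eff.slope == pytest.approx(ref.slope)
            assert eff.r_squared == pytest.approx(ref.rvalue ** 2)


class TestExtremeQuintile:
    def test_selection_count_20pct_of_10(self):
        # 10 trials per cell -> exactly 2 upper + 2 lower per cell
        rows = []
        rng = np.random.default_rng(3)
        for s in range(4):
            for k in range(10):
                rows.append({"participant": f"p{s}", "condition": "control",
                             "coherence": 0.0, "retained": True,
                             "asem_velocity_signed": float(k),
                             "latency": 0.3 - 0.01 * k + rng.normal(0, 1e-6)})
        df = pd.DataFrame(rows)
        res, skipped = extreme_quintile_contrast(df)
        assert skipped == 0
        # upper trials are k in {8,9}, lower k in {0,1}; latency gap 0.08
        assert res.mean_diff == pytest.approx(-0.08, abs=1e-4)

    def test_negative_coupling_orders_strata_per_participant(self):
        trials = _trial_df(seed=10, beta1=(-0.05, 0.0), residual_sd=0.0,
                           n_participants=5, trials_per_cell=8)
        res, _ = extreme_quintile_contrast(trials)
        assert res.t < 0 and res.mean_diff < 0

    def test_small_cells_skipped_with_count(self):
        trials = _trial_df(seed=12, trials_per_cell=2)  # cells of ~2 < 5
        with pytest.raises(DegenerateDataError):
            extreme_quintile_contrast(trials)
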