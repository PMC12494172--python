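"""ST/GT slope, group split, association models and behavioral statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from scipy.linalg import helmert

from gazecpm.phenotype import (
    adiposity_model,
    assign_groups,
    rm_anova,
    stgt_coefficient,
    trend_over_trials,
    welch_t,
)
from gazecpm.synthetic import GroundTruth, StudyConfig, gen_covariates

from _oracles import ols_slope, welch_formula


class TestStgtCoefficient:
    def test_saturated_design_closed_form(self):
        """Gaze pinned to the CS on every rewarding trial and to the UCS on
        every zero-value trial: 12 trials each of values 2/1/0/0 gives an
        OLS slope of exactly 12/11."""
        vals = np.array([2.0] * 12 + [1.0] * 12 + [0.0] * 24)
        idx = np.array([1.0] * 24 + [-1.0] * 24)
        res = stgt_coefficient(vals, idx)
        assert res.stgt_slope == pytest.approx(12 / 11)
        assert res.stgt_slope == pytest.approx(ols_slope(vals, idx))

    def test_four_trial_worked_example(self):
        vals = np.array([2.0, 1.0, 0.0, 0.0])
        idx = np.array([0.5, 0.1, -0.2, -0.4])
        res = stgt_coefficient(vals, idx, min_trials=1)
        assert res.stgt_slope == pytest.approx(0.4)
        assert res.stgt_slope == pytest.approx(ols_slope(vals, idx))

    def test_constant_index_gives_zero_slope(self):
        res = stgt_coefficient(np.array([2.0, 1, 0, 0]), np.full(4, 0.3), min_trials=1)
        assert res.stgt_slope == pytest.approx(0.0)

    def test_missing_indices_dropped(self):
        vals = np.array([2.0, 1.0, 0.0, 0.0, 2.0])
        idx = np.array([0.5, 0.1, -0.2, -0.4, np.nan])
        res = stgt_coefficient(vals, idx, min_trials=1)
        assert res.n_trials_used == 4
        assert res.stgt_slope == pytest.approx(0.4)

    def test_single_cs_value_is_error(self):
        with pytest.raises(ValueError):
            stgt_coefficient(np.array([1.0, 1.0, 1.0]), np.array([0.1, 0.2, 0.3]))

    def test_order_invariance_and_affine_equivariance(self):
        rng = np.random.default_rng(0)
        vals = np.repeat([2.0, 1.0, 0.0, 0.0], 12)
        idx = rng.uniform(-1, 1, 48)
        base = stgt_coefficient(vals, idx).stgt_slope
        perm = rng.permutation(48)
        assert stgt_coefficient(vals[perm], idx[perm]).stgt_slope == pytest.approx(base)
        scaled = stgt_coefficient(vals, 3.0 * idx - 0.5).stgt_slope
        assert scaled == pytest.approx(3.0 * base)

    def test_too_few_trials_marks_excluded(self):
        res = stgt_coefficient(np.array([2.0, 0.0, 1.0]), np.array([0.5, -0.5, 0.2]))
        assert res.group == "excluded"


class TestGroupSplit:
    @pytest.mark.parametrize("n,sizes", [(47, (19, 9, 19)), (5, (2, 1, 2)), (10, (4, 2, 4))])
    def test_split_sizes(self, n, sizes):
        rng = np.random.default_rng(n)
        labels = assign_groups(rng.normal(size=n))
        counts = (
            int(np.sum(labels == "ST")),
            int(np.sum(labels == "intermediate")),
            int(np.sum(labels == "GT")),
        )
        assert counts == sizes

    def test_ranking_direction(self):
        labels = assign_groups(np.array([5.0, -5.0, 0.0, 1.0, -1.0]))
        assert labels[0] == "ST" and labels[1] == "GT" and labels[2] == "intermediate"

    def test_sizes_near_fractions_for_any_n(self):
        for n in range(5, 60):
            labels = assign_groups(np.random.default_rng(n).normal(size=n))
            assert len(labels) == n
            assert abs(np.sum(labels == "ST") - 0.4 * n) <= 0.5
            assert abs(np.sum(labels == "GT") - 0.4 * n) <= 0.5

    def test_too_small_sample_is_error(self):
        with pytest.raises(ValueError):
            assign_groups(np.array([1.0, 2.0, 3.0, 4.0]))


class TestAdiposityModel:
    def _noiseless(self, n=40, seed=1):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "whr": rng.uniform(0.75, 0.99, n),
                "age": rng.uniform(18, 41, n),
                "sex": rng.integers(0, 2, n),
                "hunger": rng.uniform(0, 100, n),
            }
        )
        df["stgt_slope"] = -1.64 + 1.48 * df["whr"] + 0.01 * df["age"] + 0.07 * df["sex"]
        return df

    def test_exact_recovery_on_noiseless_data(self):
        fit = adiposity_model(self._noiseless(), predictor="whr")
        est = dict(zip(fit.terms, fit.estimates))
        assert est["const"] == pytest.approx(-1.64)
        assert est["whr"] == pytest.approx(1.48)
        assert est["age"] == pytest.approx(0.01)
        assert est["sex"] == pytest.approx(0.07)
        assert est["hunger"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert np.all(fit.conf_int[:, 0] <= fit.estimates)
        assert np.all(fit.estimates <= fit.conf_int[:, 1])

    def test_null_predictor_has_small_coefficient(self):
        rng = np.random.default_rng(3)
        df = self._noiseless(n=500)
        df["stgt_slope"] = rng.normal(0, 1, len(df))  # outcome independent of all
        fit = adiposity_model(df, predictor="whr")
        assert abs(dict(zip(fit.terms, fit.std_estimates))["whr"]) < 0.2

    def test_duplicated_rows_leave_coefficients_unchanged(self):
        df = self._noiseless(n=30)
        df["stgt_slope"] += np.random.default_rng(0).normal(0, 0.1, 30)
        a = adiposity_model(df, predictor="whr")
        b = adiposity_model(pd.concat([df, df], ignore_index=True), predictor="whr")
        assert np.allclose(a.estimates, b.estimates)

    def test_rank_deficient_design_is_error(self):
        df = self._noiseless()
        df["age"] = 2.0 * df["hunger"]
        with pytest.raises(ValueError):
            adiposity_model(df, predictor="whr")

    def test_planted_whr_coupling_recovered_across_replicates(self):
        """With a positive WHR-propensity coupling, the adjusted WHR model
        finds a positive coefficient whose CI excludes 0 in >=90% of
        replicate studies."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = StudyConfig(n_participants=200, whr_slope=0.05, seed=rep)
            rng = np.random.default_rng(rep)
            theta = rng.normal(0, 1, 200)
            truth = GroundTruth(theta=theta, true_edges=cfg.planted_edges, true_whr_slope=0.05)
            df = gen_covariates(cfg, truth, rep + 100)
            # behavioral slope tracks theta with realistic trial noise
            df["stgt_slope"] = 0.3 * theta + rng.normal(0, 0.15, 200)
            fit = adiposity_model(df, predictor="whr")
            k = fit.terms.index("whr")
            if fit.estimates[k] > 0 and fit.conf_int[k, 0] > 0:
                hits += 1
        assert hits >= 9


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 10.0]
        t, df, p = welch_t(a, b)
        t0, df0, p0 = welch_formula(a, b)
        assert t == pytest.approx(t0)
        assert df == pytest.approx(df0)
        assert p == pytest.approx(p0)

    def test_antisymmetry(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 8.0, 7.0, 3.0]
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_small_group_is_error(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestRMAnova:
    def test_all_equal_cells_give_zero_F(self):
        out = rm_anova(np.full((6, 3, 4), 7.0))
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_exact_sphericity_gives_epsilon_one(self):
        """Interaction contrasts whitened to an identity sample covariance
        have epsilon exactly 1 and uncorrected df."""
        rng = np.random.default_rng(5)
        n, p, q = 10, 3, 4
        d = (p - 1) * (q - 1)
        Z = rng.normal(0, 1, (n, d))
        Zc = Z - Z.mean(axis=0)
        S = Zc.T @ Zc / (n - 1)
        w, V = np.linalg.eigh(S)
        Zw = Zc @ V @ np.diag(w**-0.5) @ V.T  # exact identity covariance
        C = np.kron(helmert(p), helmert(q))
        Y = (Zw @ C).reshape(n, p, q)
        out = rm_anova(Y)
        assert out["epsilon"] == pytest.approx(1.0)
        assert out["df1"] == pytest.approx(d)
        assert out["df2"] == pytest.approx((n - 1) * d)

    def test_matches_independent_anova_oracle(self):
        """Frozen reference values computed with R's car::Anova (type-3
        repeated-measures with Greenhouse-Geisser correction) on the same
        generated table."""
        rng = np.random.default_rng(0)
        Y = rng.normal(0, 1, (8, 3, 4)) + rng.normal(0, 1, (8, 1, 1))
        out = rm_anova(Y)
        assert out["F"] == pytest.approx(3.063253661, rel=1e-8)
        assert out["epsilon"] == pytest.approx(0.5577649, rel=1e-6)
        assert out["p"] == pytest.approx(0.04333735, rel=1e-6)

    def test_missing_cells_rejected(self):
        Y = np.random.default_rng(1).normal(size=(5, 3, 4))
        Y[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(Y)


class TestTrendOverTrials:
    def test_constant_values(self):
        mean_slope, p = trend_over_trials(np.full((8, 12), 4.0))
        assert mean_slope == 0.0 and p == 1.0

    def test_unit_trend(self):
        V = np.tile(np.arange(1.0, 13.0), (6, 1))
        mean_slope, p = trend_over_trials(V)
        assert mean_slope == pytest.approx(1.0)
        assert p == 0.0  # zero-variance slopes, all exactly 1

    def test_power_at_planted_slope(self):
        """A planted mean slope of 0.2 against noise sd 0.1 is detected in
        at least 95% of simulated cohorts of 30 participants."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 40
        tn = np.arange(1, 13, dtype=float)
        for _ in range(n_rep):
            slopes = 0.2 + rng.normal(0, 0.05, 30)
            V = slopes[:, None] * tn[None, :] + rng.normal(0, 0.1, (30, 12))
            _, p = trend_over_trials(V)
            rejections += p < 0.05
        assert rejections >= 0.95 * n_rep

    def test_too_few_trials_is_error(self):
        with pytest.raises(ValueError):
            trend_over_trials(np.ones((5, 2)))
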