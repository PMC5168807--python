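"""Unit tests of the survival-statistics engine against independent oracles
(hand tabulation, brute-force pair enumeration, and lifelines)."""

import numpy as np
import pandas as pd
import pytest

from survscreen.stats import (CoxPH, concordance_index,
                              cox_fit_raw, cox_null_loglik, fit_cox,
                              logrank_many, logrank_test, survival_array,
                              welch_many, welch_t_test)

from conftest import random_censored


def brute_force_concordance(risk, y):
    """O(n^2) pair enumeration, written independently of the production path."""
    conc = disc = tied = 0
    for i in range(len(y)):
        if not y["event"][i]:
            continue
        for j in range(len(y)):
            if y["time"][i] < y["time"][j]:
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] < risk[j]:
                    disc += 1
                else:
                    tied += 1
    return conc, disc, tied


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

class TestConcordance:
    def test_perfect_ranking_gives_one(self):
        t = np.arange(1.0, 11.0)
        y = survival_array(t, np.ones(10, bool))
        assert concordance_index(-t, y).cindex == 1.0

    def test_constant_risk_gives_half(self):
        y = survival_array([1, 2, 3, 4], [1, 1, 0, 1])
        rec = concordance_index(np.zeros(4), y)
        assert rec.cindex == 0.5
        assert rec.concordant == 0 and rec.discordant == 0

    def test_four_patient_hand_enumeration(self):
        # events at t=1 and t=3, censored at 2 and 4; risks anti-ordered
        # with time -> comparable pairs (1,2),(1,3),(1,4),(3,4), all concordant
        y = survival_array([1, 2, 3, 4], [1, 0, 1, 0])
        rec = concordance_index([4.0, 3.0, 2.0, 1.0], y)
        assert rec.n_comparable == 4
        assert rec.concordant == 4
        assert rec.cindex == 1.0

    def test_zero_comparable_pairs_errors(self):
        y = survival_array([5.0, 5.0], [1, 1])  # tied event times
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], y)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        y = random_censored(rng, 80, tie_grid=4)
        risk = rng.integers(-3, 4, 80).astype(float)
        rec = concordance_index(risk, y)
        assert (rec.concordant, rec.discordant, rec.tied_risk) == \
            brute_force_concordance(risk, y)

    def test_matches_lifelines_without_risk_ties(self):
        from lifelines.utils import concordance_index as lifelines_c
        rng = np.random.default_rng(3)
        y = random_censored(rng, 150)
        risk = rng.normal(size=150)
        mine = concordance_index(risk, y).cindex
        theirs = lifelines_c(y["time"], -risk, y["event"])
        assert mine == pytest.approx(theirs, abs=1e-12)

    def test_random_risk_centers_at_half(self):
        rng = np.random.default_rng(4)
        y = random_censored(rng, 500)
        cs = [concordance_index(rng.uniform(size=500), y).cindex
              for _ in range(100)]
        assert np.mean(cs) == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups_give_null(self):
        y = survival_array([1, 2, 3, 4], [1, 0, 1, 1])
        res = logrank_test(y, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_tabulated_toy_example(self):
        # all-event groups (1,2,3) vs (4,5,6); O-E and V summed by hand over
        # event times 1..3 give (3-1.15)^2 / 0.6775
        a = survival_array([1, 2, 3], [1, 1, 1])
        b = survival_array([4, 5, 6], [1, 1, 1])
        res = logrank_test(a, b)
        assert res.statistic == pytest.approx(5.051660516605167, rel=1e-12)
        assert res.p_value == pytest.approx(0.024602349953641744, rel=1e-10)

    def test_no_events_warns_and_degenerates(self):
        a = survival_array([1, 2], [0, 0])
        b = survival_array([3, 4], [0, 0])
        with pytest.warns(UserWarning, match="zero events"):
            res = logrank_test(a, b)
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_lifelines(self, seed):
        from lifelines.statistics import logrank_test as lifelines_lr
        rng = np.random.default_rng(seed)
        a = random_censored(rng, 60, tie_grid=3 if seed % 2 else None)
        b = random_censored(rng, 45, tie_grid=3 if seed % 2 else None)
        mine = logrank_test(a, b)
        theirs = lifelines_lr(a["time"], b["time"], a["event"], b["event"])
        assert mine.statistic == pytest.approx(theirs.test_statistic, rel=1e-8)
        assert mine.p_value == pytest.approx(theirs.p_value, rel=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = random_censored(rng, 40)
        b = random_censored(rng, 50)
        assert logrank_test(a, b).statistic == pytest.approx(
            logrank_test(b, a).statistic, rel=1e-12)

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(8)
        a = random_censored(rng, 40)
        b = random_censored(rng, 40)
        s1 = logrank_test(a, b).statistic
        a2 = survival_array(a["time"] ** 1.5 * 2 + 3, a["event"])
        b2 = survival_array(b["time"] ** 1.5 * 2 + 3, b["event"])
        assert logrank_test(a2, b2).statistic == pytest.approx(s1, rel=1e-10)

    def test_power_under_planted_hazard_ratio(self):
        """HR = 5 between two groups of 50 is detected in >= 95% of sims."""
        rng = np.random.default_rng(9)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            ta = rng.exponential(1.0 / 5.0, 50)
            tb = rng.exponential(1.0, 50)
            a = survival_array(ta, np.ones(50, bool))
            b = survival_array(tb, np.ones(50, bool))
            hits += logrank_test(a, b).p_value < 0.05
        assert hits / n_sim >= 0.95

    def test_many_features_consistent_with_pairwise(self):
        rng = np.random.default_rng(10)
        y = random_censored(rng, 70, tie_grid=5)
        groups = rng.integers(-1, 2, size=(12, 70)).astype(np.int8)
        stat, p, oe = logrank_many(y["time"], y["event"], groups)
        for f in range(12):
            g = groups[f]
            if (g == 1).sum() == 0 or (g == 0).sum() == 0:
                continue
            a = y[g == 1]
            b = y[g == 0]
            if not (a["event"].any() or b["event"].any()):
                continue
            ref = logrank_test(a, b)
            assert stat[f] == pytest.approx(ref.statistic, rel=1e-10, abs=1e-12)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_formula_toy_example(self):
        # means 2 vs 3, variances 1, n=3 -> t = -1/sqrt(2/3), df = 4
        res = welch_t_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.224744871391589, rel=1e-12)
        assert res.p_value == pytest.approx(0.28786413472669053, rel=1e-10)

    def test_separated_samples(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = rng.normal(3, 1, 50)
        assert welch_t_test(x, y).p_value < 1e-6

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match=">=2"):
            welch_t_test([1.0], [1.0, 2.0, 3.0])

    def test_vectorised_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(1)
        values = rng.normal(size=(8, 60))
        values[rng.random((8, 60)) < 0.1] = np.nan
        mask_a = np.zeros(60, bool)
        mask_a[:25] = True
        mask_b = ~mask_a
        t, p = welch_many(values, mask_a, mask_b)
        for f in range(8):
            xa = values[f, mask_a]
            xb = values[f, mask_b]
            ref = sps.ttest_ind(xa[np.isfinite(xa)], xb[np.isfinite(xb)],
                                equal_var=False)
            assert t[f] == pytest.approx(ref.statistic, rel=1e-10)
            assert p[f] == pytest.approx(ref.pvalue, rel=1e-10)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _sim_cox(rng, n, beta):
    x = rng.normal(size=(n, len(beta)))
    t_event = rng.exponential(1.0, n) / np.exp(x @ np.asarray(beta))
    t_cens = rng.exponential(2.0, n)
    t = np.minimum(t_event, t_cens)
    e = t_event <= t_cens
    return x, t, e


class TestCoxPH:
    @pytest.mark.parametrize("tie_grid", [None, 8])
    def test_matches_lifelines(self, tie_grid):
        import lifelines
        rng = np.random.default_rng(0)
        x, t, e = _sim_cox(rng, 250, [0.8, -0.4, 0.0])
        if tie_grid:
            t = np.ceil(t * tie_grid) / tie_grid
        raw = cox_fit_raw(x, t, e)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["t"], df["e"] = t, e.astype(int)
        ref = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert raw["converged"]
        # agreement is limited by lifelines' own stopping rule (its gradient
        # at the reported optimum is ~1e-3)
        np.testing.assert_allclose(raw["beta"], ref.params_.to_numpy(),
                                   rtol=2e-4, atol=1e-6)
        assert raw["loglik"] == pytest.approx(ref.log_likelihood_, rel=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        x, t, e = _sim_cox(rng, 1000, [1.0])
        raw = cox_fit_raw(x, t, e)
        assert abs(raw["beta"][0] - 1.0) < 0.15

    def test_null_covariate_lr_calibration(self):
        """-2 (ll - ll0) for a pure-noise covariate stays below the chi2(1)
        95% critical value in >= 90% of simulations."""
        from scipy import stats as sps
        rng = np.random.default_rng(2)
        crit = sps.chi2.ppf(0.95, 1)
        below = 0
        n_sim = 40
        for _ in range(n_sim):
            x, t, e = _sim_cox(rng, 200, [0.0])
            raw = cox_fit_raw(x, t, e)
            below += -2 * (raw["null_loglik"] - raw["loglik"]) < crit
        assert below / n_sim >= 0.90

    def test_nested_model_loglik_monotone(self):
        rng = np.random.default_rng(3)
        x, t, e = _sim_cox(rng, 200, [0.5, -0.5])
        full = cox_fit_raw(x, t, e)
        sub = cox_fit_raw(x[:, :1], t, e)
        assert full["loglik"] >= sub["loglik"] - 1e-9

    def test_perfect_separation_is_flagged(self):
        t = np.arange(1.0, 31.0)
        e = np.ones(30, bool)
        x = -t[:, None]  # risk perfectly anti-ordered with time
        raw = cox_fit_raw(x, t, e)
        assert not raw["converged"]

    def test_estimator_interface_and_aic(self):
        rng = np.random.default_rng(4)
        x, t, e = _sim_cox(rng, 150, [0.7, 0.0])
        X = pd.DataFrame(x, columns=["m1", "m2"])
        y = survival_array(t, e)
        model = fit_cox(X, y)
        assert list(model.coef_.index) == ["m1", "m2"]
        assert model.aic_ == pytest.approx(-2 * model.log_likelihood_ + 4)
        assert model.n_used_ == 150
        risk = model.predict(X)
        np.testing.assert_allclose(risk, x @ model.coef_.to_numpy())
        assert 0.5 < model.score(X, y) <= 1.0

    def test_complete_case_handling(self):
        rng = np.random.default_rng(5)
        x, t, e = _sim_cox(rng, 120, [0.8])
        X = pd.DataFrame(x, columns=["m"])
        X.iloc[:20, 0] = np.nan
        model = fit_cox(X, survival_array(t, e))
        assert model.n_used_ == 100
        risk = model.predict(X)
        assert np.isnan(risk[:20]).all() and np.isfinite(risk[20:]).all()

    def test_too_few_complete_cases_raises(self):
        X = pd.DataFrame({"m": [1.0, np.nan, 2.0]})
        y = survival_array([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="complete cases"):
            fit_cox(X, y)

    def test_coefficient_serialisation_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        x, t, e = _sim_cox(rng, 100, [0.5])
        model = fit_cox(pd.DataFrame(x, columns=["m"]), survival_array(t, e))
        path = tmp_path / "coef.tsv"
        model.to_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert back.loc[0, "covariate"] == "m"
        assert back.loc[0, "coefficient"] == pytest.approx(model.coef_["m"])

    def test_null_loglik_consistent(self):
        rng = np.random.default_rng(7)
        x, t, e = _sim_cox(rng, 80, [0.0])
        raw = cox_fit_raw(x, t, e)
        assert raw["null_loglik"] == pytest.approx(cox_null_loglik(t, e), rel=1e-12)
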