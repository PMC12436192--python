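"""Association designs against brute-force and closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ewaskit as ek
from ewaskit.association import (
    longitudinal_delta_test,
    overlap_test,
    posthoc_depression_adjust,
    predict_response_logistic,
    response_continuous,
    smoking_ewas_robust,
    welch_case_control,
)
from ewaskit.data import EffectSpec
from ewaskit.preprocess import AdjustedMatrix, MValueMatrix, beta_to_m
from ewaskit.qc import label_response


def welch_bruteforce(x, y):
    """Direct evaluation of the Welch t and Welch-Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    t = (x.mean() - y.mean()) / math.sqrt(v1 / n1 + v2 / n2)
    df = (v1 / n1 + v2 / n2) ** 2 / ((v1 / n1) ** 2 / (n1 - 1)
                                     + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def _as_adjusted(values, sample_ids):
    frame = pd.DataFrame(values, index=sample_ids)
    frame.columns = [f"cg{j}" for j in range(frame.shape[1])]
    return AdjustedMatrix(frame, ["none"])


class TestWelch:
    def test_matches_bruteforce_formula(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0]
        vals = np.array(x + y)[:, None]
        ids = [f"s{i}" for i in range(7)]
        adj = _as_adjusted(vals, ids)
        group = pd.Series([True] * 4 + [False] * 3, index=ids)
        betas = pd.DataFrame(np.full((7, 1), 0.5), index=ids,
                             columns=adj.residuals.columns)
        res = welch_case_control(adj, group, betas)
        t_ref, df_ref = welch_bruteforce(x, y)
        assert res["statistic"].iloc[0] == pytest.approx(t_ref, abs=1e-12)
        assert res["df"].iloc[0] == pytest.approx(df_ref, abs=1e-12)
        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        assert res["p_value"].iloc[0] == pytest.approx(p_ref, abs=1e-12)

    def test_identical_groups_give_t_zero_p_one(self):
        vals = np.array([1.0, 2.0, 3.0] * 2)[:, None]
        ids = [f"s{i}" for i in range(6)]
        adj = _as_adjusted(vals, ids)
        group = pd.Series([True] * 3 + [False] * 3, index=ids)
        betas = pd.DataFrame(np.full((6, 1), 0.5), index=ids,
                             columns=adj.residuals.columns)
        res = welch_case_control(adj, group, betas)
        assert res["statistic"].iloc[0] == 0
        assert res["p_value"].iloc[0] == 1

    def test_zero_variance_probe_flagged(self):
        vals = np.ones((8, 1))
        ids = [f"s{i}" for i in range(8)]
        adj = _as_adjusted(vals, ids)
        group = pd.Series([True] * 4 + [False] * 4, index=ids)
        betas = pd.DataFrame(np.full((8, 1), 0.5), index=ids,
                             columns=adj.residuals.columns)
        res = welch_case_control(adj, group, betas)
        assert res["flag"].iloc[0] == "degenerate"
        assert np.isnan(res["p_value"].iloc[0])

    def test_affine_invariance_of_t(self, rng):
        vals = rng.normal(size=(30, 4))
        ids = [f"s{i}" for i in range(30)]
        group = pd.Series(rng.integers(0, 2, 30).astype(bool), index=ids)
        betas = pd.DataFrame(rng.uniform(0.2, 0.8, (30, 4)), index=ids,
                             columns=[f"cg{j}" for j in range(4)])
        a = welch_case_control(_as_adjusted(vals, ids), group, betas)
        b = welch_case_control(_as_adjusted(vals * 3.7 - 1.2, ids), group, betas)
        assert np.allclose(a["statistic"], b["statistic"], atol=1e-10)

    def test_delta_beta_from_raw_betas_not_residuals(self, rng):
        vals = rng.normal(size=(20, 1))
        ids = [f"s{i}" for i in range(20)]
        group = pd.Series([True] * 10 + [False] * 10, index=ids)
        betas = pd.DataFrame(
            np.concatenate([np.full(10, 0.7), np.full(10, 0.5)])[:, None],
            index=ids, columns=["cg0"])
        res = welch_case_control(_as_adjusted(vals, ids), group, betas)
        assert res["effect"].iloc[0] == pytest.approx(0.2)
        assert res["effect_pct"].iloc[0] == pytest.approx(100 * 0.2 / 0.5)

    def test_p_recomputable_from_statistic_and_df(self, clean_cohort, manifest):
        from ewaskit.preprocess import impute_probe_means
        m = beta_to_m(clean_cohort.t0.betas.iloc[:, :200])
        adj = AdjustedMatrix(impute_probe_means(m.m), ["none"])
        group = (clean_cohort.sheet.table["group"] == "patient")
        res = welch_case_control(adj, group, clean_cohort.t0.betas.iloc[:, :200])
        ok = res["flag"] == ""
        p2 = 2 * stats.t.sf(res.loc[ok, "statistic"].abs(), res.loc[ok, "df"])
        assert np.abs(res.loc[ok, "p_value"] - p2).max() < 1e-10


class TestPosthocDepression:
    def test_all_zero_depression_equals_pooled_t(self, rng):
        n = 40
        vals = rng.normal(size=(n, 3))
        ids = [f"s{i}" for i in range(n)]
        group = pd.Series(rng.integers(0, 2, n).astype(bool), index=ids)
        dep = pd.Series(False, index=ids)
        adj = _as_adjusted(vals, ids)
        res = posthoc_depression_adjust(adj, group, dep,
                                        list(adj.residuals.columns))
        for j, pid in enumerate(adj.residuals.columns):
            t_ref, p_ref = stats.ttest_ind(vals[group.to_numpy(), j],
                                           vals[~group.to_numpy(), j],
                                           equal_var=True)
            assert res.loc[pid, "statistic"] == pytest.approx(t_ref, abs=1e-10)
            assert res.loc[pid, "p_value"] == pytest.approx(p_ref, abs=1e-10)

    def test_group_and_depression_separated(self, rng):
        n = 60
        ids = [f"s{i}" for i in range(n)]
        group = pd.Series([True] * 30 + [False] * 30, index=ids)
        dep = pd.Series(rng.random(n) < 0.3, index=ids) & group  # patients only
        dep.iloc[0] = True  # ensure contrast
        # probe 0: effect purely through depression; probe 1: pure group effect
        y = rng.normal(size=(n, 2))
        y[:, 0] += 2.0 * dep.to_numpy()
        y[:, 1] += 2.0 * group.to_numpy()
        adj = _as_adjusted(y, ids)
        res = posthoc_depression_adjust(adj, group, dep, ["cg0", "cg1"],
                                        sig=1e-4, suggestive=1e-2)
        assert abs(res.loc["cg0", "effect"]) < 0.8       # mediated -> shrinks
        assert res.loc["cg1", "p_value"] < 1e-4          # survives adjustment
        assert res.loc["cg1", "status"] == "significant"

    def test_collinear_predictors_raise(self, rng):
        n = 20
        ids = [f"s{i}" for i in range(n)]
        group = pd.Series([True] * 10 + [False] * 10, index=ids)
        adj = _as_adjusted(rng.normal(size=(n, 1)), ids)
        with pytest.raises(ValueError):
            posthoc_depression_adjust(adj, group, group.copy(), ["cg0"])


class TestLogistic:
    def test_matches_closed_form_2x2_log_odds(self):
        # binary predictor with cell counts a=12, b=8, c=6, d=14
        a, b, c, d = 12, 8, 6, 14
        x = np.array([1.0] * (a + b) + [0.0] * (c + d))
        y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
        ids = [f"s{i}" for i in range(len(x))]
        m = MValueMatrix(pd.DataFrame({"cg0": x}, index=ids), 0.001)
        res = predict_response_logistic(m, pd.Series(y, index=ids),
                                        pd.DataFrame(index=ids))
        log_or = math.log(a * d / (b * c))
        assert res.loc["cg0", "effect"] == pytest.approx(log_or, abs=1e-8)
        assert np.sign(res.loc["cg0", "statistic"]) == np.sign(log_or)

    def test_null_probes_have_moderate_z(self, rng):
        n, p = 200, 400
        y = pd.Series((rng.random(n) < 0.5).astype(float),
                      index=[f"s{i}" for i in range(n)])
        m = MValueMatrix(pd.DataFrame(
            rng.normal(size=(n, p)), index=y.index,
            columns=[f"cg{j}" for j in range(p)]), 0.001)
        res = predict_response_logistic(m, y, pd.DataFrame(index=y.index))
        z = res["statistic"].dropna()
        assert np.abs(z).max() < 5.0
        assert stats.kstest(res["p_value"].dropna(), "uniform").pvalue > 0.01

    def test_perfect_separation_flagged(self):
        n = 30
        ids = [f"s{i}" for i in range(n)]
        x = np.linspace(-2, 2, n)
        y = (x > 0).astype(float)
        m = MValueMatrix(pd.DataFrame({"cg0": x}, index=ids), 0.001)
        res = predict_response_logistic(m, pd.Series(y, index=ids),
                                        pd.DataFrame(index=ids))
        assert res.loc["cg0", "flag"] in ("separation", "no_convergence")
        assert np.isnan(res.loc["cg0", "p_value"])

    def test_planted_slope_recovered(self, rng):
        """Generator-planted log-odds slope of 1 per unit M, n = 300."""
        man = ek.generate_manifest(300, 50, 100, 0.0, 0.0, seed=3)
        ref = ek.generate_reference(100, 1.5, seed=4)
        target = ek.spikeable_probes(man, 1)[0]
        coefs = []
        for r in range(40):
            co = ek.generate_cohort(
                man, ref, 300, 0, EffectSpec(pred_spiked=[(target, 1.0)]),
                seed=100 + r, hama_dropout=(0.0, 0.0), meth_dropout=(0.0, 0.0))
            labels = label_response(co.sheet, "T0", "T1")
            m = beta_to_m(co.t0.betas[[target]])
            res = predict_response_logistic(
                m, labels, pd.DataFrame(index=co.sheet.table.index))
            coefs.append(res.loc[target, "effect"])
        coefs = np.array(coefs)
        assert abs(coefs.mean() - 1.0) < 0.15
        assert (np.abs(coefs - 1.0) <= 0.3).mean() >= 0.8

    def test_response_with_no_contrast_raises(self, rng):
        ids = [f"s{i}" for i in range(30)]
        m = MValueMatrix(pd.DataFrame(rng.normal(size=(30, 2)), index=ids), 0.001)
        with pytest.raises(ValueError):
            predict_response_logistic(m, pd.Series(1.0, index=ids),
                                      pd.DataFrame(index=ids))


class TestResponseContinuous:
    def test_constant_outcome_flagged(self, rng):
        ids = [f"s{i}" for i in range(30)]
        m = MValueMatrix(pd.DataFrame(rng.normal(size=(30, 3)), index=ids), 0.001)
        res = response_continuous(m, pd.Series(50.0, index=ids),
                                  pd.DataFrame(index=ids))
        assert (res["flag"] == "zero_variance_outcome").all()

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm
        n = 60
        ids = [f"s{i}" for i in range(n)]
        covs = pd.DataFrame(rng.normal(size=(n, 2)), index=ids, columns=["a", "b"])
        mvals = pd.DataFrame(rng.normal(size=(n, 4)), index=ids,
                             columns=[f"cg{j}" for j in range(4)])
        y = pd.Series(rng.normal(size=n) * 10 + 40, index=ids)
        res = response_continuous(MValueMatrix(mvals, 0.001), y, covs)
        for pid in mvals.columns:
            x = sm.add_constant(np.column_stack([mvals[pid], covs]))
            fit = sm.OLS(y.to_numpy(), x).fit()
            assert res.loc[pid, "effect"] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.loc[pid, "statistic"] == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert res.loc[pid, "p_value"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_planted_slope_recovered(self, rng):
        n = 300
        ids = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        y = pd.Series(40 + 5.0 * x + rng.normal(0, 10, n), index=ids)
        m = MValueMatrix(pd.DataFrame({"cg0": x}, index=ids), 0.001)
        res = response_continuous(m, y, pd.DataFrame(index=ids))
        assert abs(res.loc["cg0", "effect"] - 5.0) <= 2 * res.loc["cg0", "se"]

    def test_strong_binary_hit_is_continuous_hit(self, rng):
        """A probe that predicts binary response at p < 1e-5 must also be
        associated with the continuous improvement score at p <= 0.05."""
        n = 300
        ids = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        pct = pd.Series(50 + 25 * x + rng.normal(0, 15, n), index=ids)
        resp = (pct >= 50).astype(float)
        m = MValueMatrix(pd.DataFrame({"cg0": x}, index=ids), 0.001)
        logi = predict_response_logistic(m, resp, pd.DataFrame(index=ids))
        cont = response_continuous(m, pct, pd.DataFrame(index=ids))
        assert logi.loc["cg0", "p_value"] < 1e-5
        assert cont.loc["cg0", "p_value"] <= 0.05


class TestLongitudinal:
    def _adj(self, vals, ids):
        return _as_adjusted(vals, ids)

    def test_identical_timepoints_flagged_degenerate(self, rng):
        ids = [f"p{i}" for i in range(10)]
        vals = rng.normal(size=(10, 3))
        mask = pd.Series([True] * 5 + [False] * 5, index=ids)
        out = longitudinal_delta_test(self._adj(vals, ids), self._adj(vals, ids), mask)
        for tab in out.values():
            assert (tab["flag"] == "degenerate").all()

    def test_analytic_one_sample_t(self, rng):
        # d ~ Normal(0.5, 1), n = 100 -> t concentrates near sqrt(n)*mu/sigma = 5
        ids = [f"p{i}" for i in range(200)]
        d = rng.normal(0.5, 1.0, size=(200, 1))
        t0 = np.zeros((200, 1))
        mask = pd.Series([True] * 100 + [False] * 100, index=ids)
        base = self._adj(t0, ids)
        tk = self._adj(d, ids)
        out = longitudinal_delta_test(base, tk, mask)
        t_resp = out["responder"]["statistic"].iloc[0]
        assert abs(t_resp - 5.0) < 4.0
        # p recomputable from t and df
        tab = out["responder"]
        p2 = 2 * stats.t.sf(abs(t_resp), tab["df"].iloc[0])
        assert tab["p_value"].iloc[0] == pytest.approx(p2, abs=1e-12)

    def test_small_stratum_skipped_with_warning(self, rng):
        ids = [f"p{i}" for i in range(6)]
        vals = rng.normal(size=(6, 2))
        mask = pd.Series([True] * 5 + [False], index=ids)
        with pytest.warns(UserWarning, match="skipped"):
            out = longitudinal_delta_test(self._adj(np.zeros((6, 2)), ids),
                                          self._adj(vals, ids), mask)
        assert "non-responder" not in out

    def test_responder_only_drift_detected_in_right_stratum(self, manifest, reference):
        target = ek.spikeable_probes(manifest, 1)[0]
        eff = EffectSpec(long_spiked=[(target, (0.0, 0.05))])
        co = ek.generate_cohort(manifest, reference, 120, 0, eff, seed=31)
        from ewaskit.pipeline import joint_adjust
        from ewaskit.qc import filter_probes
        keep = filter_probes(manifest).kept_probe_ids
        subs = {tp: ds.subset_probes([p for p in keep if p in ds.betas.columns])
                for tp, ds in co.datasets.items()}
        labels = label_response(co.sheet, "T0", "T2")
        resp = labels[labels != "missing"] == "responder"
        import ewaskit.preprocess as prep
        from ewaskit.pipeline import RunConfig
        adj, m_st, covs = joint_adjust(subs, manifest, reference, keep, 10)
        arr_person = pd.Series({a: a.rsplit(":", 1)[0] for a in m_st.m.index})
        multi = arr_person.map(arr_person.value_counts()) > 1
        m_long = prep.MValueMatrix(m_st.m.loc[multi[multi].index], m_st.offset_used)
        aw = prep.residualize_within(m_long, covs.loc[m_long.m.index],
                                     arr_person.loc[m_long.m.index])
        sl = {}
        for tp in ("T0", "T2"):
            aid = [a for a in aw.residuals.index if a.endswith(f":{tp}")]
            sl[tp] = AdjustedMatrix(
                aw.residuals.loc[aid].set_axis(
                    [a.rsplit(":", 1)[0] for a in aid], axis=0), ["w"])
        out = longitudinal_delta_test(sl["T0"], sl["T2"], resp)
        assert out["responder"].loc[target, "p_value"] < 1e-4
        assert out["non-responder"].loc[target, "p_value"] > 1e-3


class TestSmokingRobust:
    def test_clean_data_matches_ols(self, rng):
        import statsmodels.api as sm
        n = 80
        ids = [f"s{i}" for i in range(n)]
        smoke = pd.Series(rng.integers(0, 2, n).astype(bool), index=ids)
        betas = pd.DataFrame(
            np.clip(0.5 + 0.05 * smoke.to_numpy() + rng.normal(0, 0.03, n), 0, 1)[:, None],
            index=ids, columns=["cg0"])
        res = smoking_ewas_robust(betas, smoke, pd.DataFrame(index=ids))
        x = sm.add_constant(smoke.astype(float).to_numpy())
        ols = sm.OLS(betas["cg0"].to_numpy(), x).fit()
        assert res.loc["cg0", "effect"] == pytest.approx(ols.params[1], rel=0.05)

    def test_robust_beats_ols_under_contamination(self, rng):
        import statsmodels.api as sm
        wins = 0
        reps = 12
        n = 100
        for r in range(reps):
            g = np.random.default_rng(r)
            smoke = g.integers(0, 2, n).astype(float)
            y = 0.4 + 0.05 * smoke + g.normal(0, 0.02, n)
            bad = g.choice(n, size=5, replace=False)
            y[bad] += g.choice([-0.4, 0.4], size=5)
            y = np.clip(y, 0, 1)
            ids = [f"s{i}" for i in range(n)]
            betas = pd.DataFrame(y[:, None], index=ids, columns=["cg0"])
            res = smoking_ewas_robust(betas, pd.Series(smoke.astype(bool), index=ids),
                                      pd.DataFrame(index=ids))
            ols = sm.OLS(y, sm.add_constant(smoke)).fit()
            if abs(res.loc["cg0", "effect"] - 0.05) < abs(ols.params[1] - 0.05):
                wins += 1
        assert wins >= reps * 0.7

    def test_constant_smoking_raises(self, rng):
        ids = [f"s{i}" for i in range(20)]
        betas = pd.DataFrame(rng.uniform(0, 1, (20, 2)), index=ids,
                             columns=["cg0", "cg1"])
        with pytest.raises(ValueError):
            smoking_ewas_robust(betas, pd.Series(True, index=ids),
                                pd.DataFrame(index=ids))


class TestOverlap:
    def test_disjoint_sets_tail_at_zero_is_one(self):
        count, p = overlap_test({"a", "b"}, {"c", "d"}, 100)
        assert count == 0 and p == 1.0

    def test_identical_small_sets_exact_combinatorics(self):
        count, p = overlap_test(set("abcde"), set("abcde"), 10)
        assert count == 5
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_large_sparse_case_stable_in_log_space(self):
        # zero overlap of 495- and 88-element sets in a 780,145 universe
        a = {f"x{i}" for i in range(495)}
        b = {f"y{i}" for i in range(88)}
        count, p = overlap_test(a, b, 780145)
        assert count == 0
        # closed form: P(X >= 0) = 1
        assert p == 1.0
        # and the complementary exact probability of the observed zero
        from scipy.stats import hypergeom
        p_zero = hypergeom.pmf(0, 780145, 495, 88)
        from math import lgamma
        def logc(n, k):
            return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)
        log_ref = logc(780145 - 495, 88) - logc(780145, 88)
        assert math.log(p_zero) == pytest.approx(log_ref, abs=1e-6)

    def test_universe_smaller_than_set_raises(self):
        with pytest.raises(ValueError):
            overlap_test(set(range(10)), set(), 5)
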