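"""Tests for cohort statistics: normalization, effect sizes, FDR, ROC, NB-CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pdspeech as pk
from pdspeech import cohort
from pdspeech.errors import (
    ArgumentError,
    CollinearityError,
    NormalizationError,
    StratificationError,
)


def _toy_cohort(n_hc=6, n_pd=6):
    rng = np.random.default_rng(3)
    n = n_hc + n_pd
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["HC"] * n_hc + ["PD"] * n_pd,
            "sex": (["M", "F"] * n)[:n],
            "feat": rng.normal(5.0, 2.0, n),
        }
    )


class TestZnormalize:
    def test_self_normalization_of_controls(self, cohort_table):
        z = pk.znormalize(cohort_table)
        hc = z[z["group"] == "HC"]
        for sex in ("M", "F"):
            sub = hc[hc["sex"] == sex][cohort.FEATURE_COLUMNS]
            np.testing.assert_allclose(sub.mean(), 0.0, atol=1e-9)
            np.testing.assert_allclose(sub.std(ddof=1), 1.0, atol=1e-9)

    def test_patient_at_control_mean_maps_to_zero(self):
        df = _toy_cohort()
        hc_f = df[(df["group"] == "HC") & (df["sex"] == "F")]
        df.loc[df.index[-1], "sex"] = "F"
        df.loc[df.index[-1], "feat"] = hc_f["feat"].mean()
        z = pk.znormalize(df, features=["feat"])
        assert z.loc[df.index[-1], "feat"] == pytest.approx(0.0, abs=1e-9)

    def test_arithmetic_example(self):
        df = pd.DataFrame(
            {
                "subject_id": list("abcde"),
                "group": ["HC", "HC", "HC", "HC", "PD"],
                "sex": ["F"] * 5,
                "feat": [3.0, 5.0, 5.0, 7.0, 9.0],  # HC mean 5, SD ~1.633
            }
        )
        sd = np.std([3, 5, 5, 7], ddof=1)
        z = pk.znormalize(df, features=["feat"])
        assert z.loc[4, "feat"] == pytest.approx((9.0 - 5.0) / sd)

    def test_small_stratum_rejected(self):
        df = _toy_cohort()
        df.loc[df["group"] == "HC", "sex"] = "M"
        df.loc[df["group"] == "PD", "sex"] = "F"
        with pytest.raises(NormalizationError):
            pk.znormalize(df, features=["feat"])

    def test_zero_variance_rejected(self):
        df = _toy_cohort()
        df.loc[df["group"] == "HC", "feat"] = 1.0
        with pytest.raises(NormalizationError):
            pk.znormalize(df, features=["feat"])


class TestCompareGroupsAndHedgesG:
    def test_identical_groups(self):
        df = _toy_cohort()
        df["feat"] = [1, 2, 3, 4, 5, 6] * 2
        res = pk.compare_groups(df, features=["feat"])
        assert res.loc["feat", "t_statistic"] == pytest.approx(0.0)
        assert res.loc["feat", "p_value"] == pytest.approx(1.0)
        assert res.loc["feat", "hedges_g"] == pytest.approx(0.0)

    def test_hand_pooled_t(self):
        df = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "group": ["HC"] * 3 + ["PD"] * 3,
                "sex": ["M"] * 6,
                "feat": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        res = pk.compare_groups(df, features=["feat"])
        assert res.loc["feat", "t_statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert res.loc["feat", "p_value"] == pytest.approx(0.0214, abs=1e-3)

    def test_equal_means_zero_g(self):
        assert pk.hedges_g(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0

    def test_degenerate_pooled_sd_rejected(self):
        with pytest.raises(ArgumentError):
            pk.hedges_g(5.0, 0.0, 10, 6.0, 0.0, 10)

    def test_simulation_recovers_known_effect(self):
        # standardized difference 0.8 at n = 40/80: estimator bias < 0.05
        rng = np.random.default_rng(12)
        gs = []
        for _ in range(300):
            x = rng.normal(0.8, 1.0, 40)
            y = rng.normal(0.0, 1.0, 80)
            gs.append(pk.hedges_g(x.mean(), x.std(ddof=1), 40, y.mean(), y.std(ddof=1), 80))
        assert abs(np.mean(gs) - 0.8) < 0.05

    def test_separated_cohort_detected(self, cohort_table):
        res = pk.compare_groups(cohort_table, features=["DDKavr"])
        assert res.loc["DDKavr", "p_value"] < 0.001


class TestRankFeatures:
    def test_pure_g_ordering_when_uncorrelated(self):
        comp = pd.DataFrame({"hedges_g": [0.3, 0.9, -0.6]}, index=["a", "b", "c"])
        assert pk.rank_features(comp) == ["b", "c", "a"]

    def test_correlated_weaker_feature_demoted(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=200)
        mat = pd.DataFrame(
            {
                "a": base,
                "b": base + 0.01 * rng.normal(size=200),  # near-duplicate of a
                "c": rng.normal(size=200),
            }
        )
        comp = pd.DataFrame({"hedges_g": [0.9, 0.8, 0.1]}, index=["a", "b", "c"])
        ranked = pk.rank_features(comp, mat, max_abs_corr=0.9)
        assert ranked == ["a", "c", "b"]

    def test_reference_cohort_recovers_implied_ordering(self):
        # the generator's population effect sizes follow from its (mean, SD)
        # parameters: NSR ~1.06 then VowelArea ~0.94; at 10x the study size
        # the sample ordering of the leading effects must match
        tab = pk.synth_cohort(n_hc=400, n_pd=800, seed=77)
        comp = pk.compare_groups(tab)
        order = comp["hedges_g"].abs().sort_values(ascending=False)
        params = pk.reference_feature_params().set_index("feature")
        implied = {
            f: abs(pk.hedges_g(r["hc_mean"], r["hc_sd"], 40, r["pd_mean"], r["pd_sd"], 80))
            for f, r in params.iterrows()
        }
        implied_top2 = sorted(implied, key=implied.get, reverse=True)[:2]
        assert list(order.index[:2]) == implied_top2
        assert "VowelArea" in implied_top2


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r, _ = pk.partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_identity_gives_r_one(self):
        x = np.arange(10.0)
        r, p = pk.partial_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_shared_covariate_explains_both(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=200)
        x = 2.0 * z + 0.3 * rng.normal(size=200)
        y = -1.5 * z + 0.3 * rng.normal(size=200)
        r, _ = pk.partial_correlation(x, y, z)
        assert abs(r) < 0.2

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=50)
        cov = np.column_stack([z, 2 * z])
        with pytest.raises(CollinearityError):
            pk.partial_correlation(rng.normal(size=50), rng.normal(size=50), cov)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(pk.fdr_adjust([0.03]), [0.03])

    def test_hand_bh_example(self):
        np.testing.assert_allclose(pk.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ArgumentError):
            pk.fdr_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
    def test_matches_brute_force_bh(self, pvals):
        p = np.asarray(pvals)
        n = p.size
        order = np.argsort(p, kind="stable")
        scaled = p[order] * n / (np.arange(n) + 1)
        adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(pk.fdr_adjust(p), expected, atol=1e-12)
        assert np.all(pk.fdr_adjust(p) >= p - 1e-12)


class TestStageComparison:
    def _staged(self, rng, shift_by_stage=0.0, n_per=12):
        stages = [np.nan, 1.5, 2.5, 3.0, 4.0]
        rows = []
        for j, stage in enumerate(stages):
            for i in range(n_per):
                rows.append(
                    {
                        "group": "HC" if j == 0 else "PD",
                        "sex": "M",
                        "HY_stage": stage,
                        "feat": rng.normal(j * shift_by_stage, 1.0),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_values_f_zero(self):
        df = self._staged(np.random.default_rng(0))
        df["feat"] = 1.0
        res = pk.stage_comparison(df, "feat")
        assert res["F"] == pytest.approx(0.0)

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(1)
        df = self._staged(rng, shift_by_stage=2.0, n_per=20)
        res = pk.stage_comparison(df, "feat")
        assert res["p_value"] < 0.001
        assert (res["vs_hc"]["p_bonferroni"] < 0.05).any()

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            df = self._staged(rng)
            if pk.stage_comparison(df, "feat")["p_value"] < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07

    def test_small_stage_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        df = self._staged(rng)
        df = df[~((df["HY_stage"] == 4.0) & (df.index % 12 != 0))]
        with pytest.warns(UserWarning):
            res = pk.stage_comparison(df, "feat")
        assert "HY4-5" not in res["group_sizes"]


class TestLinearModel:
    def test_exact_linear_target(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        y = X @ [1.0, -2.0, 0.5] + 3.0
        res = pk.linear_updrs_model(X, y)
        assert res["r_squared"] == pytest.approx(1.0)
        np.testing.assert_allclose(res["coefficients"], [3.0, 1.0, -2.0, 0.5], atol=1e-9)

    def test_null_r2_small(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(500, 6))
        y = rng.normal(size=500)
        assert pk.linear_updrs_model(X, y)["r_squared"] < 0.05

    def test_single_feature_slope(self):
        x = np.arange(20.0)
        res = pk.linear_updrs_model(x[:, None], 2.0 * x)
        assert res["coefficients"][1] == pytest.approx(2.0, abs=1e-9)

    def test_collinear_design_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(CollinearityError):
            pk.linear_updrs_model(np.column_stack([x, 2 * x]), x)


class TestRocAuc:
    def test_worked_example(self):
        assert pk.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert pk.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert pk.roc_auc([0.5] * 10, [0, 1] * 5) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ArgumentError):
            pk.roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = wins / (pos.size * neg.size)
        assert pk.roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestNbClassifyCv:
    def test_perfect_separation_auc_one(self):
        rng = np.random.default_rng(20)
        X = np.concatenate([rng.normal(0, 1, (40, 1)), rng.normal(10, 1, (40, 1))])
        y = np.array([0] * 40 + [1] * 40)
        assert pk.nb_classify_cv(X, y, seed=0).auc == 1.0

    def test_chance_level_on_independent_labels(self):
        # a single pooled-CV AUC under the null has SD ~0.036 at n = 400, so
        # check the mean over replicates against the chance band
        aucs = []
        for rep in range(10):
            rng = np.random.default_rng(21 + rep)
            X = rng.normal(size=(400, 4))
            y = rng.integers(0, 2, 400)
            aucs.append(pk.nb_classify_cv(X, y, seed=rep).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)
        assert np.all(np.abs(np.array(aucs) - 0.5) < 0.15)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(60, 3))
        y = np.array([0, 1] * 30)
        a = pk.nb_classify_cv(X, y, seed=5)
        b = pk.nb_classify_cv(X, y, seed=5)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)
        assert a.auc == b.auc

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ArgumentError):
            pk.nb_classify_cv(X, np.ones(10), seed=0)

    def test_folds_partition_subjects(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(57, 3))
        y = rng.integers(0, 2, 57)
        y[:5] = 0
        y[5:10] = 1
        report = pk.nb_classify_cv(X, y, k=5, seed=1)
        assert sorted(np.unique(report.fold_assignments)) == [0, 1, 2, 3, 4]
        assert report.fold_assignments.size == 57
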