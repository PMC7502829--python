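"""SVM-RFE selection, cross-validation, permutation, SVR, domains,
external validation, importance filtering and group statistics."""

import numpy as np
import pandas as pd
import pytest

import lesionload as ll
from lesionload.prognosis import RFEResult


def noisy_features(rng, n, p, informative=0, gap=4.0):
    y = np.r_[np.ones(n // 2), -np.ones(n - n // 2)].astype(int)
    y = rng.permutation(y)
    X = pd.DataFrame(
        rng.standard_normal((n, p)),
        columns=[f"f{i:02d}" for i in range(p)],
        index=[f"s{i:02d}" for i in range(n)],
    )
    for j in range(informative):
        X.iloc[:, j] += gap * y / 2.0
    return X, pd.Series(y, index=X.index)


class TestRFESelect:
    def test_top_weight_is_one(self, separable_features):
        X, y = separable_features
        rfe = ll.rfe_select(X, y)
        assert rfe.weights.max() == 1.0

    def test_elimination_order_is_permutation(self, separable_features):
        X, y = separable_features
        rfe = ll.rfe_select(X, y)
        assert sorted(rfe.elimination_order) == sorted(X.columns)

    def test_separating_feature_survives(self):
        """One perfectly separating feature among 20 noise features stays
        in the optimal subset almost always."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            X, y = noisy_features(rng, 40, 21, informative=1, gap=6.0)
            rfe = ll.rfe_select(X, y, seed=seed)
            hits += "f00" in rfe.subset
        assert hits >= 19

    def test_single_class_rejected(self, separable_features):
        X, _ = separable_features
        with pytest.raises(ValueError, match="class"):
            ll.rfe_select(X, np.ones(len(X), dtype=int))

    def test_needs_two_features(self, separable_features):
        X, y = separable_features
        with pytest.raises(ValueError, match="2 features"):
            ll.rfe_select(X.iloc[:, :1], y)


class TestLOOCV:
    def test_wide_margin_perfect_accuracy(self, separable_features):
        X, y = separable_features
        report = ll.loocv_classify(X, y, subset=list(X.columns))
        assert report.accuracy == 100.0
        assert report.sensitivity == 100.0 and report.specificity == 100.0

    def test_confusion_counts_consistent(self, separable_features):
        X, y = separable_features
        r = ll.loocv_classify(X, y, subset=["f0"])
        c = r.confusion
        assert r.accuracy == pytest.approx(100 * (c["tp"] + c["tn"]) / sum(c.values()))

    def test_pure_noise_near_chance(self):
        """With an a-priori fixed subset, null-data LOOCV is centred at
        (or pessimistically below) chance: no optimism bias.  Single-run
        LOOCV accuracies disperse widely (fold predictions share the
        training data), so the check is on the distribution, not on every
        seed."""
        accs = []
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(400 + seed)
            X, y = noisy_features(rng, 40, 4)
            accs.append(ll.loocv_classify(X, y, subset=list(X.columns)).accuracy)
        assert 38.0 <= np.mean(accs) <= 55.0
        assert np.sum((np.asarray(accs) >= 35) & (np.asarray(accs) <= 65)) >= 0.7 * n_seeds

    def test_column_order_invariance(self, separable_features):
        X, y = separable_features
        a = ll.loocv_classify(X, y, subset=["f0", "f2"]).predictions
        shuffled = X[["f3", "f1", "f2", "f0"]]
        b = ll.loocv_classify(shuffled, y, subset=["f0", "f2"]).predictions
        assert a.equals(b)

    def test_sensitivity_targets_not_recovered_class(self):
        """All errors on the -1 class must hit sensitivity, not specificity."""
        rng = np.random.default_rng(5)
        X, y = noisy_features(rng, 20, 3, informative=1, gap=6.0)
        # move one -1 subject deep into +1 territory
        i = int(np.flatnonzero(y.values == -1)[0])
        X.iloc[i, 0] = X.values[y.values == 1, 0].mean()
        r = ll.loocv_classify(X, y, subset=list(X.columns))
        assert r.sensitivity < 100.0 and r.specificity == 100.0


class TestRepeatedSubsampling:
    def test_exhaustive_single_holdout_equals_loocv(self, separable_features):
        X, y = separable_features
        dist, _ = ll.repeated_subsampling(X, y, list(X.columns), 1, exhaustive=True)
        loocv = ll.loocv_classify(X, y, subset=list(X.columns))
        assert dist["accuracy"].mean() == pytest.approx(loocv.accuracy)

    def test_all_correct_gives_degenerate_ci(self, separable_features):
        X, y = separable_features
        _, ci = ll.repeated_subsampling(X, y, list(X.columns), 3, reps=150, seed=0)
        assert ci == (100.0, 100.0)

    def test_deterministic_given_seed(self, separable_features):
        X, y = separable_features
        d1, c1 = ll.repeated_subsampling(X, y, ["f0"], 4, reps=120, seed=9)
        d2, c2 = ll.repeated_subsampling(X, y, ["f0"], 4, reps=120, seed=9)
        assert d1.equals(d2) and c1 == c2

    def test_oversized_test_set_rejected(self, separable_features):
        X, y = separable_features
        with pytest.raises(ValueError, match="n_test"):
            ll.repeated_subsampling(X, y, ["f0"], len(X), reps=100)


class TestPermutationTest:
    def test_minimal_p_when_observed_beats_all(self, separable_features):
        X, y = separable_features
        p, observed, perm = ll.permutation_test(
            X, y, subset=["f0"], n_perm=100, seed=0
        )
        assert observed == 100.0
        assert p == pytest.approx(1 / 101)

    def test_null_data_p_not_significant(self):
        """On label-independent features the test must not fire; LOOCV's
        pessimistic bias pushes null p-values high, never low."""
        ps = []
        for seed in range(10):
            rng = np.random.default_rng(600 + seed)
            X, y = noisy_features(rng, 30, 2)
            p, _, _ = ll.permutation_test(X, y, subset=list(X.columns),
                                          n_perm=99, seed=seed)
            ps.append(p)
        assert sum(p < 0.05 for p in ps) <= 1
        assert np.median(ps) >= 0.2

    def test_full_mode_refits_selection(self):
        rng = np.random.default_rng(7)
        X, y = noisy_features(rng, 16, 3, informative=1, gap=6.0)
        p, observed, _ = ll.permutation_test(
            X, y, n_perm=20, seed=0, mode="full", inner_cv=4
        )
        assert observed >= 90.0 and p <= 0.1


class TestSVR:
    def test_linear_score_recovered(self):
        rng = np.random.default_rng(8)
        n = 60
        X = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(n)],
        )
        score = 30 + 8 * X["a"] + 0.5 * rng.standard_normal(n)
        rep = ll.svr_predict(X, score, ["a", "b", "c"])
        assert rep.rho >= 0.9
        assert rep.rho_ci[0] <= rep.rho <= rep.rho_ci[1]

    def test_constant_scores_rejected(self, separable_features):
        X, _ = separable_features
        with pytest.raises(ValueError, match="constant"):
            ll.svr_predict(X, np.full(len(X), 3.0), ["f0"])


class TestCombineDomains:
    def make(self, n=10, p_fa=53, p_cyt=3):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(n)]
        fa = pd.DataFrame(rng.random((n, p_fa)),
                          columns=[f"c{i:02d}" for i in range(p_fa)], index=idx)
        cyt = pd.DataFrame(rng.random((n, p_cyt)),
                           columns=["il1b", "il6", "ccl2"], index=idx)
        return fa, cyt

    def test_column_count_adds_up(self):
        fa, cyt = self.make()
        combined = ll.combine_domains(fa, cyt)
        assert combined.shape[1] == 56
        assert set(combined.attrs["domain"].values()) == {"fa", "cytokine"}

    def test_empty_cytokines_passthrough(self):
        fa, cyt = self.make()
        out = ll.combine_domains(fa, cyt.iloc[:, :0])
        assert out.equals(fa)

    def test_domains_standardized_separately(self):
        fa, cyt = self.make()
        combined = ll.combine_domains(fa, cyt)
        assert np.allclose(combined.mean(), 0, atol=1e-12)
        assert np.allclose(combined.std(ddof=0), 1, atol=1e-12)

    def test_subject_mismatch_lists_ids(self):
        fa, cyt = self.make()
        cyt = cyt.rename(index={"s0": "zz"})
        with pytest.raises(ValueError, match="zz"):
            ll.combine_domains(fa, cyt)


class TestExternalValidate:
    def test_flipped_labels_mirror_accuracy(self, separable_features):
        X, y = separable_features
        est = ll.SVMRFEClassifier().fit(X, y)
        straight = ll.external_validate(est, X, y)
        flipped = ll.external_validate(est, X, -y)
        assert flipped.accuracy == pytest.approx(100.0 - straight.accuracy)

    def test_resubstitution_bounds_loocv(self):
        rng = np.random.default_rng(11)
        X, y = noisy_features(rng, 30, 5, informative=2, gap=2.0)
        rfe = ll.rfe_select(X, y)
        loocv = ll.loocv_classify(X, y, subset=rfe.subset)
        resub = ll.external_validate(rfe.estimator, X, y)
        assert resub.accuracy >= loocv.accuracy

    def test_bit_identical_reports(self, separable_features):
        X, y = separable_features
        est = ll.SVMRFEClassifier().fit(X, y)
        a = ll.external_validate(est, X, y)
        b = ll.external_validate(est, X, y)
        assert a.to_dict() == b.to_dict()
        assert a.predictions.equals(b.predictions)

    def test_missing_catalogue_feature_rejected(self, separable_features):
        X, y = separable_features
        est = ll.SVMRFEClassifier().fit(X, y)
        with pytest.raises(ValueError, match="missing"):
            ll.external_validate(est, X.drop(columns=["f1"]), y)


def make_rfe_result(n_fibers, rng):
    """One cluster per fiber with descending normalized weights."""
    names = [f"tract_{i:02d}_low_0" for i in range(n_fibers)]
    w = np.linspace(1.0, 0.1, n_fibers)
    weights = pd.Series(w, index=names)
    est = ll.SVMRFEClassifier()  # placeholder, not used by the filter
    return RFEResult(
        elimination_order=list(reversed(names)),
        step_accuracies=pd.DataFrame({"n_features": [n_fibers], "cv_accuracy": [1.0]}),
        subset=names,
        weights=weights,
        estimator=est,
    )


class TestImportanceFilter:
    def groups(self, n_non, n_rec, n_con):
        return pd.Series(
            ["nonrecovered"] * n_non + ["recovered"] * n_rec + ["control"] * n_con,
            index=[f"s{i}" for i in range(n_non + n_rec + n_con)],
        )

    def features(self, rng, groups, cols, shifted=()):
        X = pd.DataFrame(
            rng.standard_normal((len(groups), len(cols))), columns=cols,
            index=groups.index,
        )
        for c in shifted:
            X.loc[groups == "nonrecovered", c] += 3.0
        return X

    def test_top_quarter_of_27_fibers_is_6(self):
        rng = np.random.default_rng(12)
        rfe = make_rfe_result(27, rng)
        groups = self.groups(8, 12, 10)
        X = self.features(rng, groups, rfe.subset, shifted=rfe.subset[:3])
        res = ll.importance_filter(rfe, X, groups)
        assert res.n_fibers == 27
        assert res.n_top == 6
        assert res.p_threshold == pytest.approx(0.05 / 6)
        assert round(res.p_threshold, 3) == 0.008  # the printed adjusted level

    def test_survivors_require_both_group_differences(self):
        rng = np.random.default_rng(13)
        rfe = make_rfe_result(8, rng)
        groups = self.groups(10, 14, 12)
        X = self.features(rng, groups, rfe.subset, shifted=[rfe.subset[0]])
        res = ll.importance_filter(rfe, X, groups)
        assert res.selected == [rfe.subset[0]]

    def test_null_features_rarely_survive(self):
        empties = 0
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            rfe = make_rfe_result(12, rng)
            groups = self.groups(8, 10, 10)
            X = self.features(rng, groups, rfe.subset)
            empties += len(ll.importance_filter(rfe, X, groups).selected) == 0
        assert empties >= 18

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(14)
        rfe = make_rfe_result(5, rng)
        groups = self.groups(5, 5, 0)
        X = self.features(rng, groups, rfe.subset)
        with pytest.raises(ValueError, match="control"):
            ll.importance_filter(rfe, X, groups)


class TestGroupStats:
    def test_identical_groups_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = ll.group_stats(x, x.copy())
        assert res.cohens_d == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_unit_effect_recovered(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        res = ll.group_stats(x, y)
        assert abs(res.cohens_d - (-1.0)) <= 0.35
        assert res.p_value < 0.001
        assert res.mean_diff_ci[0] < -1 + 0.35

    def test_swap_flips_sign_not_p(self):
        rng = np.random.default_rng(16)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 30)
        a = ll.group_stats(x, y)
        b = ll.group_stats(y, x)
        assert a.cohens_d == pytest.approx(-b.cohens_d)
        assert a.p_value == pytest.approx(b.p_value)

    def test_nonnormal_data_uses_ranksum(self):
        rng = np.random.default_rng(17)
        x = rng.exponential(1.0, 40) ** 3
        y = rng.exponential(1.5, 40) ** 3
        assert ll.group_stats(x, y).test == "ranksum"

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ll.group_stats(np.ones(5), np.ones(5))
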