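"""Grouped SVM decoding, chance tests, ROC, Friedman/Durbin-Conover."""

import numpy as np
import pandas as pd
import pytest

import vocalstm as v
from vocalstm import DataError, ParameterError
from vocalstm.decode import (
    DecodeResult,
    durbin_conover,
    friedman_test,
    group_cv_svm,
    select_lambda,
)


def _blobs(rng, n_per_group=20, n_groups=6, p=10, sep=4.0):
    """Two Gaussian classes per group, separated by `sep` along feature 0."""
    X, y, g = [], [], []
    for gi in range(n_groups):
        for cls in (1, -1):
            Xi = rng.standard_normal((n_per_group // 2, p))
            Xi[:, 0] += cls * sep / 2
            X.append(Xi)
            y += ["song" if cls == 1 else "speech"] * (n_per_group // 2)
            g += [f"g{gi}"] * (n_per_group // 2)
    return np.vstack(X), np.array(y), np.array(g)


class TestGroupCvSvm:
    def test_separable_classes_decode_perfectly(self):
        X, y, g = _blobs(np.random.default_rng(0), sep=8.0)
        res = group_cv_svm(X, y, g, lam=0.01)
        assert np.all(res.fold_accuracy == 100.0)
        assert np.all(res.fold_sensitivity == 100.0)
        assert np.all(res.fold_specificity == 100.0)

    def test_pure_noise_decodes_at_chance(self):
        rng = np.random.default_rng(1)
        X, y, g = _blobs(rng, n_per_group=30, n_groups=21, sep=0.0)
        res = group_cv_svm(X, y, g, lam=0.01)
        # 630 pooled predictions: 3-sigma binomial band around 50%
        assert 44.0 < res.pooled_prediction_accuracy < 56.0

    def test_fold_structure_is_leave_one_group_out(self):
        X, y, g = _blobs(np.random.default_rng(2), n_groups=5)
        res = group_cv_svm(X, y, g, lam=0.01)
        assert res.fold_groups == sorted(set(g))
        assert sum(len(t) for t in res.fold_y_true) == len(y)

    def test_no_leakage_from_test_rows(self):
        """Corrupting held-out rows must leave the fitted weights unchanged:
        standardization and training never see test-fold data."""
        X, y, g = _blobs(np.random.default_rng(3), n_groups=4)
        r1 = group_cv_svm(X, y, g, lam=0.01)
        held_out = sorted(set(g))[0]
        X2 = X.copy()
        X2[np.asarray(g) == held_out] *= 1e3  # wreck the held-out rows
        r2 = group_cv_svm(X2, y, g, lam=0.01)
        k = r1.fold_groups.index(held_out)
        np.testing.assert_allclose(r1.fold_weights_z[k], r2.fold_weights_z[k], rtol=1e-6)

    def test_pooled_accuracy_is_fold_mean(self):
        X, y, g = _blobs(np.random.default_rng(4), sep=1.0)
        res = group_cv_svm(X, y, g, lam=0.01)
        assert res.accuracy_mean == pytest.approx(np.mean(res.fold_accuracy))
        assert 0 <= res.pooled_prediction_accuracy <= 100

    def test_single_class_training_fold_rejected(self):
        X = np.random.default_rng(5).standard_normal((8, 3))
        y = ["song"] * 4 + ["speech"] * 4
        g = ["a"] * 4 + ["b"] * 4  # holding out b leaves only songs
        with pytest.raises(DataError):
            group_cv_svm(X, y, g, lam=0.01)

    def test_decode_stm_weight_map_on_grid(self, small_stm):
        res = v.decode_stm(small_stm, lam=0.01)
        assert res.weight_map.shape == small_stm.shape2d
        i, j = np.unravel_index(small_stm.origin_index, small_stm.shape2d)
        assert res.weight_map[i, j] == 0.0  # origin excluded from features
        top = res.top_weight_cells(fraction=0.05)
        assert top.sum() == pytest.approx(0.05 * small_stm.n_cells, abs=2)


class TestSelectLambda:
    def test_strong_signal_tie_breaks_to_largest(self):
        X, y, g = _blobs(np.random.default_rng(0), sep=10.0)
        val_X, val_y, _ = _blobs(np.random.default_rng(1), sep=10.0)
        assert select_lambda(X, y, val_X, val_y) == 0.1

    def test_single_value_grid(self):
        X, y, _ = _blobs(np.random.default_rng(2))
        assert select_lambda(X, y, X, y, grid=(0.005,)) == 0.005

    def test_empty_validation_rejected_and_deterministic(self):
        X, y, _ = _blobs(np.random.default_rng(3), sep=0.5)
        with pytest.raises(ParameterError):
            select_lambda(X, y, X[:0], y[:0])
        val_X, val_y, _ = _blobs(np.random.default_rng(4), sep=0.5)
        assert select_lambda(X, y, val_X, val_y) == select_lambda(X, y, val_X, val_y)


class TestWilcoxonVsChance:
    def test_all_above_chance_gives_maximal_statistic(self):
        accs = np.linspace(60, 100, 21)
        res = v.wilcoxon_vs_chance(accs)
        assert res.w == 21 * 22 / 2 == 231
        assert res.rank_biserial == 1.0
        assert res.p < 0.001
        assert res.ci[0] > 0

    def test_symmetric_accuracies_give_null_effect(self):
        accs = 50 + np.array([-8, 8, -6, 6, -4, 4, -2, 2, -1, 1])
        res = v.wilcoxon_vs_chance(accs)
        assert abs(res.rank_biserial) < 1e-12
        assert res.p > 0.5

    def test_p_matches_exact_enumeration_at_n6(self):
        """scipy uses the exact null at small n; verify against brute-force
        enumeration of all 2^6 sign assignments of the ranks."""
        import itertools

        d = np.array([3.0, -1.0, 7.0, 2.5, -4.0, 6.0])
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        null_w = [
            np.sum(np.where(signs, ranks, 0))
            for signs in itertools.product((False, True), repeat=6)
        ]
        mean_w = 6 * 7 / 4
        p_exact = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in null_w])
        res = v.wilcoxon_vs_chance(50 + d, chance=50)
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            v.wilcoxon_vs_chance([60, 70])
        with pytest.raises(DataError):
            v.wilcoxon_vs_chance([50.0] * 8)


class TestRoc:
    def _result(self, y, dec):
        r = DecodeResult(
            grouping="g", lam=0.01, fold_groups=["a"],
            fold_accuracy=np.array([0.0]), fold_sensitivity=np.array([0.0]),
            fold_specificity=np.array([0.0]),
        )
        r.fold_y_true = [np.asarray(y)]
        r.fold_decision = [np.asarray(dec)]
        r.fold_pred = [np.sign(dec).astype(int)]
        return r

    def test_hand_enumerated_auc(self):
        """decisions {0.9, 0.8, 0.3, 0.1}, labels {+,-,+,-}: 3 of 4
        positive/negative pairs concordant -> AUC = 0.75."""
        rocs = v.roc_per_group(self._result([1, -1, 1, -1], [0.9, 0.8, 0.3, 0.1]))
        assert rocs["a"]["auc"] == pytest.approx(0.75)

    def test_perfect_and_single_class(self):
        rocs = v.roc_per_group(self._result([1, 1, -1, -1], [2.0, 1.0, -1.0, -2.0]))
        assert rocs["a"]["auc"] == 1.0
        assert v.roc_per_group(self._result([1, 1], [0.1, 0.2])) == {}


class TestFriedmanAndPosthoc:
    def test_friedman_matches_hand_computation(self):
        """4 blocks ranking 3 treatments identically: chi2 = 12/(4*3*4) *
        (16+64+144) - 3*4*4 = 8, Kendall's W = 1."""
        table = pd.DataFrame({"a": [1, 1, 1, 1], "b": [2, 2, 2, 2], "c": [3, 3, 3, 3]},
                             dtype=float)
        chi2, p, w = friedman_test(table)
        assert chi2 == pytest.approx(8.0)
        assert w == pytest.approx(1.0)

    def test_identical_treatments_are_null(self):
        table = pd.DataFrame({c: [80.0, 85.0, 90.0, 75.0] for c in "abcd"})
        chi2, p, w = friedman_test(table)
        assert chi2 == 0.0 and p == 1.0
        with pytest.raises(DataError):
            durbin_conover(table)

    def test_durbin_conover_matches_hand_worked_ranks(self):
        """Rank sums R = (4, 9, 11), A=56, C=48, T1=6.5, denom=sqrt(2):
        pairwise t = -3.5355, -4.9497, -1.4142 on 6 df."""
        table = pd.DataFrame(
            {"a": [80.0, 82, 75, 70], "b": [85.0, 88, 80, 78], "c": [90.0, 86, 85, 88]}
        )
        ph = durbin_conover(table, bonferroni=False)
        t = {(r["a"], r["b"]): r["t"] for _, r in ph.iterrows()}
        assert t[("a", "b")] == pytest.approx(-5 / np.sqrt(2), abs=1e-6)
        assert t[("a", "c")] == pytest.approx(-7 / np.sqrt(2), abs=1e-6)
        assert t[("b", "c")] == pytest.approx(-2 / np.sqrt(2), abs=1e-6)
        ph_b = durbin_conover(table, bonferroni=True)
        assert np.all(ph_b["p"].to_numpy() >= ph["p"].to_numpy())

    def test_compare_feature_sets_runs_on_shared_folds(self, small_stm):
        features, labels = v.synth_acoustic_table(small_stm, n_features=20, seed=0)
        cmp = v.compare_feature_sets(small_stm, features, vip_excluded=["pitch_f0_median"])
        assert list(cmp.accuracy_table.columns) == ["stm", "stm+acoustic", "acoustic", "acoustic_novip"]
        assert len(cmp.accuracy_table) == small_stm.meta["fieldsite"].nunique()
        assert cmp.accuracy_table.to_numpy().min() >= 0
        with pytest.raises(ParameterError):
            v.compare_feature_sets(small_stm, features, vip_excluded=["no_such_feature"])


class TestPearsonCovariate:
    def test_identity_and_negation(self):
        acc = np.array([60.0, 70, 80, 90, 85])
        assert v.correlate_accuracy_with_covariate(acc, acc)[0] == pytest.approx(1.0)
        assert v.correlate_accuracy_with_covariate(acc, -acc)[0] == pytest.approx(-1.0)

    def test_matches_hand_computed_covariance_ratio(self):
        a = np.array([55.0, 62, 71, 80, 92])
        c = np.array([2.0, 3.5, 3.0, 5.0, 6.0])
        r_hand = np.sum((a - a.mean()) * (c - c.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((c - c.mean()) ** 2)
        )
        assert v.correlate_accuracy_with_covariate(a, c)[0] == pytest.approx(r_hand, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            v.correlate_accuracy_with_covariate([1, 2, 3], [1, 2])
        with pytest.raises(DataError):
            v.correlate_accuracy_with_covariate([1.0, 1, 1, 1], [1.0, 2, 3, 4])
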