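"""Normalization, Fisher selection, linear SVM, fusion, CV and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neurofuse.errors import NeurofuseError
from neurofuse.ml import (
    CVScheme,
    FisherScoreSelector,
    OmicsFusionClassifier,
    PipelineConfig,
    classification_metrics,
    confusion_from_rates,
    cv_evaluate,
    fisher_score,
    fuse_modalities,
    minmax_normalize,
    select_top_k,
    top_contributors,
    train_linear_svm,
    tune_C,
)
from neurofuse.synthetic import CohortConfig, gen_cohort_features


class TestMinMax:
    def test_affine_map(self):
        out = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        out = minmax_normalize(np.full((5, 2), 7.0))
        assert (out == 0).all()

    def test_train_fold_scope_clips_test_rows(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        out = minmax_normalize(X, scope="train_fold", train_idx=np.array([0, 1, 2]))
        assert np.allclose(out.ravel(), [0.0, 0.5, 1.0, 1.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_range_property(self, seed):
        X = np.random.default_rng(seed).normal(0, 100, (7, 4))
        out = minmax_normalize(X)
        assert (out >= 0).all() and (out <= 1).all()


class TestFisherScore:
    def test_identical_classes_score_zero(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 3))
        y = np.repeat([0, 1], 3)
        X = np.vstack([X[:3], X[:3]])
        scores, _ = fisher_score(X, y)
        assert np.allclose(scores, 0.0)

    def test_hand_computed_example(self):
        # class A: 1,2,3; class B: 5,6,7
        X = np.array([[1.0], [2.0], [3.0], [5.0], [6.0], [7.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        scores, _ = fisher_score(X, y)
        mu, mu1, mu2 = 4.0, 2.0, 6.0
        var1 = var2 = np.var([1, 2, 3])  # population variance = 2/3
        expect = (3 * (mu1 - mu) ** 2 + 3 * (mu2 - mu) ** 2) / (3 * var1 + 3 * var2)
        assert np.isclose(scores[0], expect)

    def test_zero_within_variance_hits_floor(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        scores, _ = fisher_score(X, y)
        assert scores[0] > 1e10  # capped by the variance floor, finite
        assert np.isfinite(scores[0])

    def test_single_class_rejected(self):
        with pytest.raises(NeurofuseError):
            fisher_score(np.ones((4, 2)), np.zeros(4))

    def test_selector_estimator_keeps_top_k(self, rng):
        X = rng.standard_normal((30, 20))
        y = np.repeat([0, 1], 15)
        X[y == 1, 5] += 3.0
        sel = FisherScoreSelector(k=4).fit(X, y)
        assert 5 in sel.selected_
        assert sel.transform(X).shape == (30, 4)


class TestSelectTopK:
    def test_identity_when_k_equals_count(self):
        order = np.array([3, 1, 2, 0])
        assert np.array_equal(select_top_k(order, 4), order)

    def test_k_too_large_rejected(self):
        with pytest.raises(NeurofuseError):
            select_top_k(np.arange(3), 4)

    def test_ties_break_by_ascending_feature_id(self):
        scores = np.array([1.0, 2.0, 2.0, 0.5])
        _, order = fisher_score(
            np.array([[0, 0, 0, 0], [1, 2, 2, 0.5], [0, 0, 0, 0], [1, 2, 2, 0.5]],
                     dtype=float),
            np.array([0, 1, 0, 1]))
        # equal scores for features 1 and 2 -> feature 1 first
        assert list(order).index(1) < list(order).index(2)


class TestLinearSVM:
    def test_analytic_max_margin_solution(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
        y = np.array([-1, -1, 1, 1])
        m = train_linear_svm(X, y, C=1e6)
        # max-margin hyperplane: x1 = 1, w proportional to (1, 0)
        assert abs(m.weights[1] / m.weights[0]) < 1e-3
        boundary = -m.bias / m.weights[0]
        assert abs(boundary - 1.0) < 1e-3

    def test_separable_training_accuracy_one(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1, -1)
        m = train_linear_svm(X, y, C=1e4)
        assert (m.predict(X) == y).all()

    def test_duplicated_dataset_same_solution(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        X[y == 1, 0] += 1.0
        m1 = train_linear_svm(X, y, C=1e5)
        m2 = train_linear_svm(np.vstack([X, X]), np.concatenate([y, y]), C=1e5)
        assert np.allclose(m1.weights, m2.weights, atol=1e-4)
        assert np.isclose(m1.bias, m2.bias, atol=1e-4)

    def test_single_class_rejected(self, rng):
        with pytest.raises(NeurofuseError):
            train_linear_svm(rng.standard_normal((5, 2)), np.ones(5))

    def test_nonpositive_c_rejected(self, rng):
        with pytest.raises(NeurofuseError):
            train_linear_svm(rng.standard_normal((4, 2)),
                             np.array([0, 0, 1, 1]), C=0.0)


class TestTopContributors:
    def test_single_nonzero_weight_first(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.where(X[:, 2] > 0, 1, -1)
        X[:, [0, 1, 3]] = 0.0
        m = train_linear_svm(X, y, C=10.0)
        assert top_contributors(m, 1)[0] == 2

    def test_k_all_is_permutation(self, rng):
        X = rng.standard_normal((20, 6))
        y = np.repeat([0, 1], 10)
        m = train_linear_svm(X, y)
        assert sorted(top_contributors(m, 6)) == list(range(6))

    def test_planted_features_recovered(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = CohortConfig(n_features_per_modality={"m": 200},
                               n_discriminative={"m": 10},
                               effect_size=2.0, seed=seed)
            table, truth = gen_cohort_features(cfg)
            X = minmax_normalize(table.data.to_numpy())
            y = table.groups.to_numpy()
            _, order = fisher_score(X, y)
            m = train_linear_svm(X, y, feature_idx=select_top_k(order, 100))
            top10 = set(top_contributors(m, 10))
            planted = {table.data.columns.get_loc(c)
                       for c in truth.discriminative_feature_ids["m"]}
            hits += len(top10 & planted) >= 8
        assert hits >= int(0.90 * n_seeds)


class TestTuneC:
    def test_single_element_grid(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.repeat([0, 1], 6)
        best, scores = tune_C(X, y, grid=[0.5])
        assert best == 0.5 and set(scores) == {0.5}

    def test_separable_ties_resolve_to_smallest_c(self, rng):
        X = np.vstack([rng.normal(-5, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        y = np.repeat([0, 1], 10)
        best, scores = tune_C(X, y, grid=[0.25, 1.0, 4.0])
        perfect = [c for c, s in scores.items() if s == 1.0]
        assert best == min(perfect)

    def test_matches_independent_inner_loop(self, rng):
        from sklearn.svm import SVC

        X = rng.standard_normal((16, 4))
        y = np.repeat([0, 1], 8)
        X[y == 1] += 0.8
        grid = [0.1, 1.0, 10.0]
        best, scores = tune_C(X, y, grid=grid)
        for C in grid:
            correct = 0
            for i in range(16):
                tr = np.setdiff1d(np.arange(16), [i])
                clf = SVC(kernel="linear", C=C).fit(X[tr], np.where(y[tr] == 1, 1, -1))
                correct += clf.predict(X[[i]])[0] == (1 if y[i] == 1 else -1)
            assert np.isclose(scores[C], correct / 16)


class TestFusion:
    def test_disjoint_lists_union(self, rng):
        X = rng.standard_normal((20, 30))
        y = np.repeat([0, 1], 10)
        cand, final = fuse_modalities([np.arange(10), np.arange(10, 20)], X, y)
        assert len(cand) == 20 and len(final) == 10

    def test_identical_lists_deduplicate(self, rng):
        X = rng.standard_normal((20, 30))
        y = np.repeat([0, 1], 10)
        cand, final = fuse_modalities([np.arange(10), np.arange(10)], X, y)
        assert len(cand) == 10

    def test_empty_union_rejected(self, rng):
        with pytest.raises(NeurofuseError):
            fuse_modalities([[], []], rng.standard_normal((6, 3)),
                            np.repeat([0, 1], 3))

    def test_informative_modality_dominates_fused_set(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = CohortConfig(
                n_features_per_modality={"a": 100, "b": 100, "c": 100},
                n_discriminative={"a": 10, "b": 0, "c": 0},
                effect_size=2.0, seed=seed)
            table, _ = gen_cohort_features(cfg)
            X = minmax_normalize(table.data.to_numpy())
            y = table.groups.to_numpy()
            tops = []
            for mod in ("a", "b", "c"):
                idx = np.array([i for i, c in enumerate(table.data.columns)
                                if c.startswith(mod)])
                _, order = fisher_score(X[:, idx], y)
                m = train_linear_svm(X[:, idx], y,
                                     feature_idx=select_top_k(order, 50))
                tops.append(idx[top_contributors(m, 10)])
            _, final = fuse_modalities(tops, X, y)
            n_from_a = sum(1 for i in final if i < 100)
            wins += n_from_a >= 7
        assert wins >= int(0.90 * n_seeds)


class TestCVEvaluate:
    def test_constant_features_give_majority_baseline(self):
        # leave out an NA subject: training majority is NCD -> wrong;
        # leave out an NCD: majority NCD -> right. Accuracy = 22/41.
        y = np.array(["NA"] * 19 + ["NCD"] * 22)
        X = np.zeros((41, 5))
        res = cv_evaluate(X, y, PipelineConfig(top_k=5, final_k=5, tune_grid=None,
                                               positive_label="NA"))
        assert np.isclose(res["report"].accuracy, 22 / 41)

    def test_null_accuracy_within_binomial_chance_band(self):
        # d=0 cohort, fold-honest pipeline: accuracy should sit inside the
        # 95% binomial interval around the majority-class proportion
        accs = []
        for seed in range(10):
            cfg = CohortConfig(effect_size=0.0, seed=100 + seed,
                               n_features_per_modality={"m": 200},
                               n_discriminative={"m": 0})
            table, _ = gen_cohort_features(cfg)
            res = cv_evaluate(table.data.to_numpy(), table.groups.to_numpy(),
                              PipelineConfig(scope="train_fold", tune_grid=None,
                                             positive_label="NA"))
            accs.append(res["report"].accuracy)
        p0 = 22 / 41
        half = 1.96 * np.sqrt(p0 * (1 - p0) / 41)
        assert p0 - half <= np.mean(accs) <= p0 + half

    def test_fixed_seed_reproduces_folds_and_metrics(self, planted_cohort):
        table, _ = planted_cohort
        X, y = table.data.to_numpy(), table.groups.to_numpy()
        scheme = CVScheme("kfold", k=5, seed=3)
        a = cv_evaluate(X, y, PipelineConfig(tune_grid=None, positive_label="NA"),
                        scheme)
        b = cv_evaluate(X, y, PipelineConfig(tune_grid=None, positive_label="NA"),
                        scheme)
        assert np.array_equal(a["decision_values"], b["decision_values"])
        assert a["report"].as_dict() == b["report"].as_dict()

    def test_kfold_partitions_subjects(self):
        y = np.array(["NA"] * 19 + ["NCD"] * 22)
        folds = CVScheme("kfold", k=10, seed=1).folds(y)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(41))

    def test_estimator_follows_sklearn_conventions(self, planted_cohort):
        from sklearn.base import clone

        table, _ = planted_cohort
        est = OmicsFusionClassifier(top_k=50, final_k=5, tune_grid=None)
        cloned = clone(est)
        cloned.fit(table.data.to_numpy(), table.groups.to_numpy())
        assert hasattr(cloned, "final_features_")
        assert cloned.predict(table.data.to_numpy()).shape == (41,)


class TestMetrics:
    def test_published_eeg_row_reconstructed(self):
        # precision 85.71%, recall 63.16% at N=41 -> unique confusion matrix
        matches, _ = confusion_from_rates(41, 0.8571, 0.6316)
        assert len(matches) == 1
        m = matches[0]
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (12, 2, 7, 20)
        assert round(m["accuracy"] * 100, 2) == 78.05
        # and the metrics report on an equivalent prediction vector gives
        # the published F1 = 0.7273
        y = np.array([1] * 19 + [0] * 22)
        pred = np.array([1] * 12 + [0] * 7 + [1] * 2 + [0] * 20)
        rep = classification_metrics(y, pred, positive_label=1)
        assert round(rep.f1, 4) == 0.7273

    def test_trivial_rates(self):
        matches, _ = confusion_from_rates(10, 1.0, 1.0, n_positive=4)
        assert matches[0] == {"tp": 4, "fp": 0, "fn": 0, "tn": 6,
                              "precision": 1.0, "recall": 1.0, "accuracy": 1.0}

    def test_inconsistent_rates_return_nearest(self):
        # the published gut-microbiota row (prec 66.67%, rec 89.47%) admits
        # no exact integer table at N=41 with 19 positives
        matches, nearest = confusion_from_rates(41, 0.6667, 0.8947, n_positive=19)
        assert matches == []
        assert len(nearest) >= 1

    def test_perfect_scores(self, rng):
        y = np.repeat([0, 1], 10)
        d = y + rng.normal(0, 0.01, 20)
        rep = classification_metrics(y, y, d, positive_label=1)
        assert rep.roc_auc == 1.0 and np.isclose(rep.pr_auc, 1.0) and rep.f1 == 1.0

    def test_auc_equals_mann_whitney_identity(self, rng):
        y = np.repeat([0, 1], [12, 9])
        d = rng.standard_normal(21) + 0.7 * y
        rep = classification_metrics(y, (d > 0).astype(int), d, positive_label=1)
        u = stats.mannwhitneyu(d[y == 1], d[y == 0], alternative="two-sided")[0]
        assert np.isclose(rep.roc_auc, u / (12 * 9))

    def test_metric_identities_hold_exactly(self, rng):
        y = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        rep = classification_metrics(y, pred, positive_label=1)
        tp, fp, fn, tn = rep.tp, rep.fp, rep.fn, rep.tn
        assert rep.accuracy == (tp + tn) / 50
        if tp + fp and tp + fn:
            p_, r_ = tp / (tp + fp), tp / (tp + fn)
            if p_ + r_:
                assert abs(rep.f1 - 2 * p_ * r_ / (p_ + r_)) < 1e-12

    def test_one_class_labels_rejected(self):
        with pytest.raises(NeurofuseError):
            classification_metrics(np.ones(5), np.ones(5))
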