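"""AUC selection, classifiers, CV protocol, voting, reports, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenotrack.learn import (AUCQuantileSelector, DiagonalLDA,
                              TrackClassifier, cluster_vote,
                              confusion_matrix_df, expected_cluster_accuracy,
                              feature_auc, half_experiment_out_cv, half_split,
                              pca_scores, select_features,
                              unbalanced_accuracy)


def auc_pair_counting(values, labels):
    """Exhaustive Mann-Whitney pair oracle, ties counted half."""
    classes = np.unique(labels)
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    wins = sum(1.0 if vb > va else 0.5 if vb == va else 0.0
               for va, vb in itertools.product(a, b))
    return wins / (len(a) * len(b))


class TestFeatureAuc:
    def test_worked_example(self):
        vals = np.array([1.0, 2.0, 1.5, 3.0])
        labs = np.array([0, 0, 1, 1])
        assert feature_auc(vals, labs) == pytest.approx(0.75)

    def test_perfect_separation_and_negation_symmetry(self, rng):
        vals = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(2, 3, 10)])
        labs = np.repeat([0, 1], 10)
        assert feature_auc(vals, labs) == 1.0
        assert feature_auc(-vals, labs) == 0.0
        v = rng.normal(size=20)
        assert feature_auc(-v, labs) == pytest.approx(
            1.0 - feature_auc(v, labs))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 31)
        n_pos = int(rng.integers(1, n))
        vals = rng.integers(0, 6, size=n).astype(float)  # many ties
        labs = np.zeros(n, dtype=int)
        labs[rng.choice(n, size=n_pos, replace=False)] = 1
        assert feature_auc(vals, labs) == pytest.approx(
            auc_pair_counting(vals, labs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            feature_auc(np.arange(4.0), np.zeros(4))


class TestSelection:
    def test_evenly_spaced_quantile_rule(self):
        aucs = np.round(np.arange(0.30, 0.50, 0.01), 10)
        idx, th_min, th_max = select_features(aucs)
        assert th_min == pytest.approx(np.quantile(aucs, 0.1))
        assert th_max == pytest.approx(np.quantile(aucs, 0.9))
        # linear-interpolation quantiles: th_min 0.319, th_max 0.471
        assert list(idx) == [0, 1, 18, 19]

    def test_strong_feature_always_selected(self, rng):
        for _ in range(100):
            aucs = rng.uniform(0.45, 0.55, size=100)
            aucs[37] = 0.95
            idx, _, _ = select_features(aucs)
            assert 37 in idx

    def test_degenerate_aucs_hit_fallback(self):
        X = np.ones((10, 20))
        X += np.arange(20)[None, :] * 0.0
        y = np.repeat([0, 1], 5)
        sel = AUCQuantileSelector().fit(X + 0.0, y)
        assert sel.used_fallback_
        assert sel.get_support().sum() == 10

    def test_saturated_upper_tail_keeps_informative_features(self, rng):
        """Many perfectly separating features (AUC 1.0) must stay selected
        even though the 0.9-quantile equals the maximum."""
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = np.hstack([np.tile(y[:, None], (1, 30)) + rng.normal(0, .01, (n, 30)),
                       rng.normal(size=(n, 10))])
        sel = AUCQuantileSelector().fit(X, y)
        assert sel.get_support()[:30].all()

    def test_transform_uses_training_support(self, rng):
        X = rng.normal(size=(20, 15))
        y = np.repeat([0, 1], 10)
        sel = AUCQuantileSelector().fit(X, y)
        Xt = sel.transform(rng.normal(size=(5, 15)))
        assert Xt.shape == (5, sel.get_support().sum())


class TestClassifiers:
    @staticmethod
    def _separable(rng, n=40, p=30):
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, p))
        X[:, :5] += 4.0 * y[:, None]
        return X, y

    def test_linear_svm_fits_separable_data(self, rng):
        X, y = self._separable(rng)
        clf = TrackClassifier(kind="svm").fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    @pytest.mark.parametrize("kind", ["svm", "rf", "lda", "knn"])
    def test_deterministic_given_seed(self, kind, rng):
        X, y = self._separable(rng, n=30, p=45)
        Xt = rng.normal(size=(10, 45))
        p1 = TrackClassifier(kind=kind, seed=3, inner_cv=2).fit(X, y).predict(Xt)
        p2 = TrackClassifier(kind=kind, seed=3, inner_cv=2).fit(X, y).predict(Xt)
        assert np.array_equal(p1, p2)

    def test_knn_uses_reduced_feature_subset(self, rng):
        X, y = self._separable(rng, n=40, p=200)
        clf = TrackClassifier(kind="knn").fit(X, y)
        assert clf.support_.sum() == 5  # 2.5% of 200
        assert clf.support_[:5].any()

    def test_diagonal_lda_separates_gaussians(self, rng):
        X, y = self._separable(rng)
        clf = DiagonalLDA().fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95
        assert clf.decision_function(X).shape == (40,)


class TestReports:
    def test_unbalanced_accuracy_cluster_arithmetic(self):
        # 35 clusters of one class (28 recognized), 63 of the other (51)
        conf = np.array([[28, 7], [12, 51]])
        assert unbalanced_accuracy(conf) == pytest.approx(79 / 98, abs=1e-4)
        assert unbalanced_accuracy(np.diag([5, 9])) == 1.0
        assert unbalanced_accuracy(np.array([[0, 3], [4, 0]])) == 0.0
        with pytest.raises(ValueError):
            unbalanced_accuracy(np.zeros((2, 2)))

    def test_confusion_row_sums_are_instance_counts(self):
        df = confusion_matrix_df([0, 0, 1, 1, 1], [0, 1, 1, 1, 0], [0, 1])
        assert df.sum(axis=1).tolist() == [2, 3]
        assert df.to_numpy().sum() == 5


def _meta(n_videos=2, clusters_per_side=2, tracks_per_cluster=5):
    rows = []
    tid = 0
    for v in range(n_videos):
        cid = 0
        for side, x in (("left", 100.0), ("right", 400.0)):
            for _ in range(clusters_per_side):
                label = cid % 2
                for _ in range(tracks_per_cluster):
                    rows.append((tid, v, cid, label, x, 512))
                    tid += 1
                cid += 1
    return pd.DataFrame(rows, columns=["track_id", "video_id", "cluster_id",
                                       "label", "centroid_x", "frame_width"])


class TestCrossValidation:
    def test_two_folds_and_no_cluster_leakage(self, rng):
        meta = _meta()
        X = rng.normal(size=(len(meta), 20))
        X[:, 0] += 3.0 * meta.label.to_numpy()
        rep, pred = half_experiment_out_cv(X, meta, TrackClassifier("svm"))
        assert len(rep.fold_accuracies) == 2
        for fold, g in pred.groupby("fold"):
            test_clusters = set(zip(g.video_id, g.cluster_id))
            train_clusters = set(zip(meta.video_id, meta.cluster_id)) \
                - test_clusters
            assert not test_clusters & train_clusters
        assert len(pred) == len(meta)

    def test_one_sided_video_rejected(self):
        meta = _meta()
        meta.loc[meta.video_id == 1, "centroid_x"] = 50.0
        with pytest.raises(ValueError, match="side"):
            half_split(meta)

    def test_null_data_near_chance(self, rng):
        accs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            meta = _meta(tracks_per_cluster=5)
            X = r.normal(size=(len(meta), 30))
            rep, _ = half_experiment_out_cv(X, meta, TrackClassifier("svm"))
            accs.append(rep.accuracy)
        n = len(_meta()) * len(accs)
        se = np.sqrt(0.25 / n)
        assert abs(np.mean(accs) - 0.5) < 3 * se + 1e-9


class TestClusterVote:
    @staticmethod
    def _pred(labels, predicted, scores=None):
        n = len(labels)
        return pd.DataFrame({
            "track_id": range(n), "video_id": 0, "cluster_id": 0,
            "label": labels, "fold": 0, "predicted": predicted,
            "score": scores if scores is not None else np.ones(n)})

    def test_simple_majority(self):
        votes, rep = cluster_vote(self._pred(["A"] * 3, ["A", "A", "B"]))
        assert votes.predicted.iloc[0] == "A"
        assert not votes.tie.iloc[0]
        assert rep.accuracy == 1.0

    def test_tie_breaks_by_score_then_lexicographic(self):
        votes, _ = cluster_vote(self._pred(["A"] * 2, ["A", "B"], [0.2, 0.9]))
        assert votes.predicted.iloc[0] == "B" and votes.tie.iloc[0]
        votes, _ = cluster_vote(self._pred(["A"] * 2, ["B", "A"], [0.5, 0.5]))
        assert votes.predicted.iloc[0] == "A" and votes.tie.iloc[0]

    def test_binomial_closed_form_and_monte_carlo(self, rng):
        exact = expected_cluster_accuracy(0.7, 5)
        assert exact == pytest.approx(0.83692, abs=1e-5)
        draws = rng.random((100_000, 5)) < 0.7
        mc = np.mean(draws.sum(axis=1) >= 3)
        assert mc == pytest.approx(exact, abs=0.005)

    def test_voting_beats_track_level_when_p_above_half(self):
        for p in (0.6, 0.7, 0.9):
            assert expected_cluster_accuracy(p, 5) >= p


class TestPca:
    def test_orthogonal_ordered_components(self, rng):
        X = rng.normal(size=(50, 8)) @ rng.normal(size=(8, 8))
        scores, pca = pca_scores(X, n_components=3)
        cov = scores.T @ scores
        assert np.abs(cov - np.diag(np.diag(cov))).max() < 1e-8
        evr = pca.explained_variance_ratio_
        assert np.all(np.diff(evr) <= 1e-12)

    def test_separated_classes_have_silhouette(self, rng):
        from sklearn.metrics import silhouette_score

        y = np.repeat([0, 1], 25)
        X = rng.normal(size=(50, 10))
        X[:, :3] += 6.0 * y[:, None]
        scores, _ = pca_scores(X)
        assert silhouette_score(scores, y) > 0.3

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_scores(np.ones((10, 4)))
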