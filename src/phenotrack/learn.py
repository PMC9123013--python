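"""Feature selection, track classification and cluster-consensus evaluation.

The learning layer is sklearn-shaped: ``AUCQuantileSelector`` is a
transformer, ``TrackClassifier`` a classifier wrapping the four model
families used for track-level phenotyping (linear SVM, boosted/forest tree
ensemble, diagonal LDA, KNN on a reduced feature subset), and both compose
with sklearn pipelines and model selection.

Evaluation follows the *half-experiment-out* protocol: each video's spatial
clusters are split into a left and a right partition by their time-averaged
centroid x against the frame midline; one partition (pooled across videos)
is tested while the other trains, and vice versa, so no test cluster shares
a region — or a track — with training.  Track predictions are then fused per
cluster by majority voting.  Accuracy throughout is the *unbalanced
accuracy*: the confusion-matrix trace over the total instance count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "feature_auc",
    "AUCQuantileSelector",
    "select_features",
    "DiagonalLDA",
    "TrackClassifier",
    "unbalanced_accuracy",
    "confusion_matrix_df",
    "half_split",
    "half_experiment_out_cv",
    "cluster_vote",
    "expected_cluster_accuracy",
    "pca_scores",
    "EvaluationReport",
]

META_COLUMNS = ("track_id", "video_id", "cluster_id", "label", "centroid_x",
                "frame_width")


def feature_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of one feature column for a binary labelling.

    Equals the Mann-Whitney pair statistic P(x_B > x_A) + 0.5 P(x_B = x_A),
    where B is the positive (second-sorted) class; computed via midranks so
    ties are handled exactly.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("feature_auc requires exactly two classes present")
    pos = labels == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(values)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _selection_scores(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Per-feature AUC (binary) or max one-vs-rest |AUC - 0.5| (multiclass)."""
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if classes.size == 2:
        return np.array([feature_auc(X[:, j], y) for j in range(X.shape[1])]), True
    scores = np.zeros(X.shape[1])
    for c in classes:
        ovr = (y == c).astype(int)
        aucs = np.array([feature_auc(X[:, j], ovr) for j in range(X.shape[1])])
        scores = np.maximum(scores, np.abs(aucs - 0.5))
    return scores, False


class AUCQuantileSelector(BaseEstimator, TransformerMixin):
    """Keep features whose class-separation AUC is extreme among all AUCs.

    Binary problems: a feature is selected when its AUC lies strictly below
    th_min = quantile(AUC, q_low) or strictly above th_max =
    quantile(AUC, q_high), i.e. both strongly positively and strongly
    negatively associated features survive.  Multiclass problems score each
    feature by its maximum one-vs-rest |AUC - 0.5| and keep the upper tail
    with the same total retained fraction.  If the rule degenerates (all
    scores equal, or nothing selected) the selector falls back to the top-k
    features by |AUC - 0.5| and flags it.
    """

    def __init__(self, q_low: float = 0.1, q_high: float = 0.9,
                 fallback_k: int = 10):
        self.q_low = q_low
        self.q_high = q_high
        self.fallback_k = fallback_k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not 0 <= self.q_low < self.q_high <= 1:
            raise ValueError("need 0 <= q_low < q_high <= 1")
        scores, binary = _selection_scores(X, y)
        self.auc_ = scores
        self.used_fallback_ = False
        if binary:
            self.th_min_ = float(np.quantile(scores, self.q_low))
            self.th_max_ = float(np.quantile(scores, self.q_high))
            upper = scores > self.th_max_
            if not upper.any() and self.th_max_ == scores.max():
                # saturated quantile (e.g. many features at AUC 1.0): the
                # strict rule would keep only the uninformative lower tail,
                # so boundary ties join the selection
                upper = scores >= self.th_max_
            lower = scores < self.th_min_
            if not lower.any() and self.th_min_ == scores.min():
                lower = scores <= self.th_min_
            support = lower | upper
            centred = np.abs(scores - 0.5)
        else:
            keep_frac = self.q_low + (1.0 - self.q_high)
            self.th_min_ = float("nan")
            self.th_max_ = float(np.quantile(scores, 1.0 - keep_frac))
            support = scores > self.th_max_
            if not support.any() and self.th_max_ == scores.max():
                support = scores >= self.th_max_
            centred = scores
        if not support.any() or np.allclose(scores, scores[0]):
            k = min(self.fallback_k, X.shape[1])
            support = np.zeros(X.shape[1], dtype=bool)
            support[np.argsort(-centred, kind="stable")[:k]] = True
            self.used_fallback_ = True
        self.support_ = support
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X)
        return X[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_features(auc_vector: np.ndarray, q_low: float = 0.1,
                    q_high: float = 0.9) -> tuple[np.ndarray, float, float]:
    """Functional form of the binary selection rule on precomputed AUCs."""
    auc_vector = np.asarray(auc_vector, dtype=np.float64)
    th_min = float(np.quantile(auc_vector, q_low))
    th_max = float(np.quantile(auc_vector, q_high))
    idx = np.flatnonzero((auc_vector < th_min) | (auc_vector > th_max))
    return idx, th_min, th_max


class DiagonalLDA(BaseEstimator, ClassifierMixin):
    """Gaussian linear discriminant with a shared diagonal covariance.

    Class means with a pooled per-feature variance; the discriminant of class
    c is the log-likelihood log pi_c - 1/2 sum_j (x_j - mu_cj)^2 / s_j^2.
    """

    def __init__(self, var_floor: float = 1e-9):
        self.var_floor = var_floor

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.priors_ = counts / counts.sum()
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        resid = X - self.means_[np.searchsorted(self.classes_, y)]
        dof = max(X.shape[0] - self.classes_.size, 1)
        self.var_ = np.maximum((resid ** 2).sum(axis=0) / dof, self.var_floor)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=np.float64)
        d = -0.5 * (((X[:, None, :] - self.means_[None]) ** 2)
                    / self.var_[None, None]).sum(axis=2)
        scores = d + np.log(self.priors_)[None, :]
        return scores[:, 1] - scores[:, 0] if scores.shape[1] == 2 else scores

    def predict(self, X):
        scores = self.decision_function(X)
        if scores.ndim == 1:
            return self.classes_[(scores > 0).astype(int)]
        return self.classes_[np.argmax(scores, axis=1)]


#: inner-CV grid of the boosted ensemble: cycles, splits, shrinkage
_BOOST_GRID = {"n_estimators": [50, 100], "max_leaf_nodes": [4, 16],
               "learning_rate": [0.1, 0.3]}


class TrackClassifier(BaseEstimator, ClassifierMixin):
    """One of the four track-level classifiers behind a common interface.

    kind:
      'svm'  linear-kernel SVM (C = 1 by default);
      'rf'   tree ensemble - boosted by default (its printed hyperparameter
             grid: ensemble cycles, max splits, shrinkage learning rate,
             tuned by inner 5-fold CV) or a classical random forest with
             ``rf_variant='forest'``;
      'lda'  linear discriminant with diagonal covariance;
      'knn'  K = 9 nearest neighbours on the top ``knn_feature_fraction``
             (2.5%) of features ranked by |AUC - 0.5| on the training fold.

    All kinds except KNN first pass features through the AUC-quantile
    selector; all thresholds, subsets and standardization statistics are fit
    on the training data only.  Deterministic given ``seed``.
    """

    def __init__(self, kind: str = "svm", q_low: float = 0.1,
                 q_high: float = 0.9, C: float = 1.0, knn_k: int = 9,
                 knn_feature_fraction: float = 0.025,
                 rf_variant: str = "boosted", standardize: bool = True,
                 inner_cv: int = 5, seed: int = 0):
        self.kind = kind
        self.q_low = q_low
        self.q_high = q_high
        self.C = C
        self.knn_k = knn_k
        self.knn_feature_fraction = knn_feature_fraction
        self.rf_variant = rf_variant
        self.standardize = standardize
        self.inner_cv = inner_cv
        self.seed = seed

    def _make_model(self):
        if self.kind == "svm":
            return SVC(kernel="linear", C=self.C, random_state=self.seed)
        if self.kind == "rf":
            if self.rf_variant == "forest":
                return RandomForestClassifier(n_estimators=200,
                                              random_state=self.seed)
            return GridSearchCV(
                GradientBoostingClassifier(random_state=self.seed),
                _BOOST_GRID, cv=self.inner_cv, n_jobs=1)
        if self.kind == "lda":
            return DiagonalLDA()
        if self.kind == "knn":
            if self.knn_k % 2 == 0:
                raise ValueError("knn_k must be odd")
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.kind == "knn":
            scores, binary = _selection_scores(X, y)
            centred = np.abs(scores - 0.5) if binary else scores
            k = max(1, int(round(self.knn_feature_fraction * X.shape[1])))
            support = np.zeros(X.shape[1], dtype=bool)
            support[np.argsort(-centred, kind="stable")[:k]] = True
            self.support_ = support
            self.selector_ = None
        else:
            self.selector_ = AUCQuantileSelector(self.q_low, self.q_high)
            self.selector_.fit(X, y)
            self.support_ = self.selector_.get_support()
        if not self.support_.any():
            raise ValueError(
                "empty selected feature set (AUC-quantile selection and its "
                "top-k fallback both failed)")
        Xs = X[:, self.support_]
        self.scaler_ = StandardScaler() if self.standardize else None
        if self.scaler_ is not None:
            Xs = self.scaler_.fit_transform(Xs)
        self.model_ = self._make_model()
        self.model_.fit(Xs, y)
        return self

    def _prepare(self, X):
        check_is_fitted(self, "model_")
        Xs = np.asarray(X)[:, self.support_]
        if self.scaler_ is not None:
            Xs = self.scaler_.transform(Xs)
        return Xs

    def predict(self, X):
        return self.model_.predict(self._prepare(X))

    def decision_scores(self, X) -> np.ndarray:
        """Per-sample confidence magnitude of the predicted label."""
        Xs = self._prepare(X)
        model = self.model_
        if isinstance(model, GridSearchCV):
            model = model.best_estimator_
        if hasattr(model, "decision_function"):
            s = np.asarray(model.decision_function(Xs))
            return np.abs(s) if s.ndim == 1 else s.max(axis=1)
        proba = model.predict_proba(Xs)
        return proba.max(axis=1)


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    level: str                       # single-time-point | single-track | cluster
    confusion: pd.DataFrame          # rows true, columns predicted (counts)
    fold_accuracies: list[float]
    classifier: str = "svm"
    mode: str = "background_suppression"
    bias: float = 0.0
    backbone: str = "fallback"
    notes: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return unbalanced_accuracy(self.confusion.to_numpy())

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) \
            if len(self.fold_accuracies) > 1 else 0.0


def accuracy_spread(accuracies) -> float:
    """Largest minus smallest accuracy across pipeline variants.

    Used to report how much the result moves when one component (e.g. the
    feature backbone) is swapped, everything else held fixed.
    """
    accuracies = np.asarray(list(accuracies), dtype=np.float64)
    if accuracies.size < 2:
        raise ValueError("need at least two accuracies to compare")
    return float(accuracies.max() - accuracies.min())


def accuracy_delta(method: float, baseline: float) -> float:
    """Improvement of one method's accuracy over a baseline's."""
    return float(method - baseline)


def unbalanced_accuracy(confusion: np.ndarray) -> float:
    """Trace over total of a confusion-count matrix."""
    confusion = np.asarray(confusion, dtype=np.float64)
    if (confusion < 0).any():
        raise ValueError("confusion counts must be non-negative")
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion matrix has zero total")
    return float(np.trace(confusion) / total)


def confusion_matrix_df(y_true, y_pred, classes) -> pd.DataFrame:
    classes = list(classes)
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return pd.DataFrame(mat, index=pd.Index(classes, name="true"),
                        columns=pd.Index(classes, name="predicted"))


def half_split(meta: pd.DataFrame) -> pd.Series:
    """Assign each track a spatial side: 'left'/'right' of its video midline.

    A cluster's side is the sign of its time-averaged centroid x minus half
    the frame width; all tracks of a cluster share a side.  Raises when any
    video has all its clusters on one side (the protocol needs both folds).
    """
    for col in ("video_id", "cluster_id", "centroid_x", "frame_width"):
        if col not in meta:
            raise ValueError(f"meta is missing column {col!r}")
    sides = pd.Series(index=meta.index, dtype=object)
    for (vid, cid), g in meta.groupby(["video_id", "cluster_id"]):
        side = "left" if g.centroid_x.mean() < g.frame_width.iloc[0] / 2.0 \
            else "right"
        sides.loc[g.index] = side
    for vid, g in meta.groupby("video_id"):
        present = set(sides.loc[g.index])
        if present != {"left", "right"}:
            raise ValueError(
                f"video {vid!r} has clusters only on the "
                f"{present.pop()} side; cannot form both folds")
    return sides


def half_experiment_out_cv(X: np.ndarray, meta: pd.DataFrame,
                           classifier: TrackClassifier,
                           level: str = "single-track"
                           ) -> tuple[EvaluationReport, pd.DataFrame]:
    """Two-fold leave-half-the-clusters-out evaluation.

    Fold 0 tests every video's left clusters (training on all right
    clusters, pooled over videos); fold 1 swaps.  Selection thresholds,
    KNN subsets and standardization are re-fit inside each training fold.
    Returns the single-track report and a per-track prediction table
    (track_id, video_id, cluster_id, label, fold, predicted, score).
    """
    from sklearn.base import clone

    X = np.asarray(X, dtype=np.float64)
    sides = half_split(meta)
    classes = sorted(meta.label.unique())
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    fold_acc, pred_rows = [], []
    for fold, test_side in enumerate(("left", "right")):
        test = (sides == test_side).to_numpy()
        train = ~test
        test_clusters = set(map(tuple, meta.loc[test, ["video_id", "cluster_id"]]
                                .itertuples(index=False)))
        train_clusters = set(map(tuple, meta.loc[train, ["video_id", "cluster_id"]]
                                 .itertuples(index=False)))
        assert not (test_clusters & train_clusters), "cluster leakage"
        clf = clone(classifier).fit(X[train], meta.label.to_numpy()[train])
        pred = clf.predict(X[test])
        score = clf.decision_scores(X[test])
        y_test = meta.label.to_numpy()[test]
        for t, p in zip(y_test, pred):
            confusion[index[t], index[p]] += 1
        fold_acc.append(float(np.mean(pred == y_test)))
        sub = meta.loc[test, ["track_id", "video_id", "cluster_id", "label"]]
        sub = sub.assign(fold=fold, predicted=pred, score=score)
        pred_rows.append(sub)
    report = EvaluationReport(
        level=level,
        confusion=pd.DataFrame(confusion, index=pd.Index(classes, name="true"),
                               columns=pd.Index(classes, name="predicted")),
        fold_accuracies=fold_acc, classifier=classifier.kind)
    return report, pd.concat(pred_rows, ignore_index=True)


def cluster_vote(predictions: pd.DataFrame) -> tuple[pd.DataFrame,
                                                     EvaluationReport]:
    """Fuse track predictions into one label per cluster by majority vote.

    Ties are resolved by the larger summed classifier score, then
    lexicographically, and flagged.  The cluster-level confusion counts
    clusters, not tracks.
    """
    classes = sorted(set(predictions.label) | set(predictions.predicted))
    rows = []
    for (vid, cid), g in predictions.groupby(["video_id", "cluster_id"]):
        counts = g.predicted.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        tie = len(top) > 1
        if tie:
            sums = g.groupby("predicted").score.sum()
            best = sums.loc[top].max()
            top = sorted(sums.loc[top][sums.loc[top] == best].index.tolist())
        winner = sorted(top)[0] if tie else top[0]
        true = g.label.iloc[0]
        rows.append((vid, cid, true, winner, tie, len(g), g.fold.iloc[0]))
    table = pd.DataFrame(rows, columns=["video_id", "cluster_id", "label",
                                        "predicted", "tie", "n_tracks", "fold"])
    confusion = confusion_matrix_df(table.label, table.predicted, classes)
    fold_acc = [float(np.mean(g.predicted == g.label))
                for _, g in table.groupby("fold")]
    report = EvaluationReport(level="cluster", confusion=confusion,
                              fold_accuracies=fold_acc)
    return table, report


def expected_cluster_accuracy(p: float, size: int) -> float:
    """Closed-form majority-vote accuracy: independent per-track accuracy
    ``p``, odd cluster ``size`` -> P(Binomial(size, p) > size/2)."""
    from math import comb

    return float(sum(comb(size, k) * p ** k * (1 - p) ** (size - k)
                     for k in range(size // 2 + 1, size + 1)))


def pca_scores(X: np.ndarray, n_components: int = 2,
               standardize: bool = True) -> tuple[np.ndarray, PCA]:
    """Principal-component scores of track descriptors for visualization."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 tracks for PCA")
    sd = X.std(axis=0)
    if np.all(sd < 1e-12):
        raise ValueError("constant feature matrix")
    if standardize:
        keep = sd > 1e-12
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(X), pca
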