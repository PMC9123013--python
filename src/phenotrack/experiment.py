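"""End-to-end experiment protocols on synthetic videos.

Glues the stages together: simulate videos, detect and track cells, label
recovered tracks against the ground truth, extract and preprocess ROI
sequences, encode them into track descriptors, and evaluate with the
half-experiment-out protocol at the single-time-point, single-track and
cluster levels — including the luminance-bias sensitivity comparison between
the background-suppression and no-preprocessing arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import DetectionConfig, Track, track_video
from .features import BackboneSpec, FeatureSignals, backbone_features
from .learn import (EvaluationReport, TrackClassifier, cluster_vote,
                    half_experiment_out_cv, half_split)
from .roi import PreprocessConfig, RoiSequence, extract_roi_sequence, preprocess
from .simulate import GroundTruth, SimulationConfig, generate_video, inject_bias

__all__ = [
    "ExperimentData",
    "build_dataset",
    "descriptor_matrix",
    "descriptor_table",
    "traditional_descriptor_table",
    "run_classification",
    "bias_sensitivity",
    "single_timepoint_baseline",
]


@dataclass
class ExperimentData:
    """Raw ROI sequences plus per-track metadata for a set of videos."""

    rois: list[RoiSequence]              # stage "raw", aligned with meta rows
    meta: pd.DataFrame                   # META_COLUMNS per track
    configs: list[SimulationConfig] = field(default_factory=list)


def _label_tracks(tracks: list[Track], truth: GroundTruth,
                  max_match_px: float = 15.0) -> dict[int, int]:
    """Assign each recovered track the class of its nearest ground-truth cell
    (mean distance over shared frames); unmatched tracks are dropped."""
    labels: dict[int, int] = {}
    cells = {cid: g.set_index("frame")
             for cid, g in truth.table.groupby("cell_id")}
    cell_class = truth.table.groupby("cell_id").class_label.first()
    for tr in tracks:
        tf = np.asarray(tr.frames)
        xy = tr.positions()
        best, best_d = None, np.inf
        for cid, g in cells.items():
            gg = g.loc[tf]
            d = float(np.mean(np.hypot(gg.x_px.to_numpy() - xy[:, 0],
                                       gg.y_px.to_numpy() - xy[:, 1])))
            if d < best_d:
                best, best_d = cid, d
        if best is not None and best_d <= max_match_px:
            labels[tr.track_id] = int(cell_class.loc[best])
    return labels


def build_dataset(configs: list[SimulationConfig],
                  detection: DetectionConfig | None = None,
                  preprocessing: PreprocessConfig | None = None,
                  use_truth_tracks: bool = False) -> ExperimentData:
    """Simulate each config as one video and return labelled raw ROI sequences.

    With ``use_truth_tracks`` the detector/tracker is bypassed and ground-truth
    trajectories are used directly (useful to isolate the learning stages).
    """
    det = detection or DetectionConfig()
    pre = preprocessing or PreprocessConfig()
    rois: list[RoiSequence] = []
    rows = []
    for vid, cfg in enumerate(configs):
        stack, truth = generate_video(cfg)
        if use_truth_tracks:
            tracks = _truth_tracks(truth)
            labels = {tr.track_id: int(truth.table[
                truth.table.cell_id == tr.track_id].class_label.iloc[0])
                for tr in tracks}
        else:
            tracks = track_video(stack, det)
            labels = _label_tracks(tracks, truth)
        for tr in tracks:
            if tr.track_id not in labels:
                continue
            roi = extract_roi_sequence(stack, tr, pre)
            rois.append(roi)
            cx, _ = tr.centroid
            rows.append((tr.track_id, vid, tr.cluster_id,
                         labels[tr.track_id], cx, cfg.image_size[1]))
    meta = pd.DataFrame(rows, columns=["track_id", "video_id", "cluster_id",
                                       "label", "centroid_x", "frame_width"])
    return ExperimentData(rois=rois, meta=meta, configs=list(configs))


def _truth_tracks(truth: GroundTruth) -> list[Track]:
    tracks = []
    for cid, g in truth.table.groupby("cell_id"):
        g = g.sort_values("frame")
        tr = Track(track_id=int(cid),
                   frames=g.frame.astype(int).tolist(),
                   xs=g.x_px.tolist(), ys=g.y_px.tolist(),
                   radii=g.radius_px.tolist(),
                   interpolated=[False] * len(g),
                   cluster_id=int(g.cluster_id.iloc[0]))
        tracks.append(tr)
    return tracks


def _signals(roi: RoiSequence, mode: str, pre: PreprocessConfig,
             spec: BackboneSpec, bias: float = 0.0) -> FeatureSignals:
    raw = roi
    if bias > 0:
        raw = RoiSequence(pixels=inject_bias(roi.pixels, bias),
                          track_id=roi.track_id, frames=roi.frames,
                          stage="raw", bias=bias)
    return backbone_features(preprocess(raw, pre, mode), spec)


def descriptor_matrix(all_signals: list[FeatureSignals]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-track dynamics descriptors into a matrix on a common basis.

    Each track's descriptor is the per-feature temporal std; features that
    are identically zero in *every* track are inactive and dropped, the
    returned mask records the survivors (features inactive only in some
    tracks legitimately contribute a 0 there).
    """
    stds = np.stack([s.values.std(axis=1, ddof=1) for s in all_signals])
    active = ~np.all([np.all(s.values == 0.0, axis=1) for s in all_signals],
                     axis=0)
    return stds[:, active], active


def descriptor_table(data: ExperimentData, mode: str = "background_suppression",
                     pre: PreprocessConfig | None = None,
                     spec: BackboneSpec | None = None,
                     bias: float = 0.0,
                     drop_inactive: bool = True) -> tuple[np.ndarray, pd.DataFrame]:
    """Descriptor matrix + metadata for one (mode, bias) condition.

    ``drop_inactive=False`` keeps the full backbone dimensionality (inactive
    features contribute a 0), which conditions that must share a feature
    basis — e.g. the bias protocol's train/test pairs — rely on.
    """
    pre = pre or PreprocessConfig()
    spec = spec or BackboneSpec()
    sigs = [_signals(roi, mode, pre, spec, bias) for roi in data.rois]
    if drop_inactive:
        X, _ = descriptor_matrix(sigs)
    else:
        X = np.stack([s.values.std(axis=1, ddof=1) for s in sigs])
    return X, data.meta


def traditional_descriptor_table(
        data: ExperimentData, mode: str = "background_suppression",
        pre: PreprocessConfig | None = None
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Benchmark branch: segmented shape + Haralick texture trajectories.

    Each track is preprocessed, segmented per frame, and summarized by the
    five trajectory statistics of its 4 shape + 13 texture features.  Tracks
    whose segmentation fails on all but one frame are dropped from the table
    (with their metadata rows), so the matrix stays aligned with the
    returned metadata.
    """
    from .features import segment_sequence, shape_texture_descriptor

    pre = pre or PreprocessConfig()
    rows, kept, names = [], [], None
    for i, roi in enumerate(data.rois):
        proc = preprocess(roi, pre, mode)
        masks, ok = segment_sequence(proc)
        if ok.sum() < 2:
            continue
        desc, names = shape_texture_descriptor(proc, masks, ok)
        rows.append(desc)
        kept.append(i)
    if not rows:
        raise ValueError("segmentation failed on every track")
    X = np.vstack(rows)
    meta = data.meta.iloc[kept].reset_index(drop=True)
    return X, meta, names


def run_classification(data: ExperimentData,
                       classifier: TrackClassifier | None = None,
                       mode: str = "background_suppression",
                       pre: PreprocessConfig | None = None,
                       spec: BackboneSpec | None = None,
                       branch: str = "deep") -> dict[str, EvaluationReport]:
    """Half-experiment-out evaluation at track and cluster level.

    ``branch='deep'`` uses backbone feature dynamics, ``'traditional'`` the
    segmentation-based shape + texture benchmark.
    """
    clf = classifier or TrackClassifier(kind="svm")
    if branch == "deep":
        X, meta = descriptor_table(data, mode, pre, spec)
    elif branch == "traditional":
        X, meta, _ = traditional_descriptor_table(data, mode, pre)
    else:
        raise ValueError(f"unknown branch {branch!r}")
    track_report, predictions = half_experiment_out_cv(X, meta, clf)
    _, cluster_report = cluster_vote(predictions)
    for rep in (track_report, cluster_report):
        rep.mode = mode
        rep.classifier = clf.kind
    return {"single-track": track_report, "cluster": cluster_report}


def bias_sensitivity(data: ExperimentData,
                     biases: tuple[float, ...] = (0.0, 0.3, 0.5),
                     modes: tuple[str, ...] = ("no_preprocessing",
                                               "background_suppression"),
                     classifier: TrackClassifier | None = None,
                     pre: PreprocessConfig | None = None,
                     spec: BackboneSpec | None = None) -> pd.DataFrame:
    """Luminance-robustness protocol.

    Models are trained once per (mode, fold) on unbiased training ROIs; the
    configured constant bias is injected into the *test* ROIs only (no
    clipping), and accuracy is reported per (mode, bias) cell.  With
    background suppression and headroom against clipping the accuracies are
    identical across biases by construction.
    """
    from sklearn.base import clone

    pre = pre or PreprocessConfig()
    spec = spec or BackboneSpec()
    base_clf = classifier or TrackClassifier(kind="svm")
    sides = half_split(data.meta)
    rows = []
    for mode in modes:
        X_train_all, meta = descriptor_table(data, mode, pre, spec, bias=0.0,
                                             drop_inactive=False)
        biased = {b: descriptor_table(data, mode, pre, spec, bias=b,
                                      drop_inactive=False)[0]
                  for b in biases}
        for bias in biases:
            confusion_total = 0
            correct_total = 0
            fold_acc = []
            for test_side in ("left", "right"):
                test = (sides == test_side).to_numpy()
                clf = clone(base_clf).fit(
                    X_train_all[~test], meta.label.to_numpy()[~test])
                pred = clf.predict(biased[bias][test])
                y = meta.label.to_numpy()[test]
                fold_acc.append(float(np.mean(pred == y)))
                correct_total += int((pred == y).sum())
                confusion_total += int(test.sum())
            rows.append((mode, bias, correct_total / confusion_total,
                         float(np.mean(fold_acc)), float(np.std(fold_acc, ddof=1))))
    return pd.DataFrame(rows, columns=["mode", "bias", "accuracy",
                                       "fold_mean", "fold_std"])


def single_timepoint_baseline(data: ExperimentData,
                              classifier: TrackClassifier | None = None,
                              mode: str = "background_suppression",
                              pre: PreprocessConfig | None = None,
                              spec: BackboneSpec | None = None
                              ) -> EvaluationReport:
    """Classify every frame as an independent instance (no dynamics).

    Per-frame backbone feature vectors inherit their track's label and the
    track-level left/right folds, so no frame of a test track is ever seen
    in training.  The contrast with the track-level result isolates the
    value of the temporal-dynamics descriptor.
    """
    from sklearn.base import clone

    pre = pre or PreprocessConfig()
    spec = spec or BackboneSpec()
    base_clf = classifier or TrackClassifier(kind="svm")
    sigs = [_signals(roi, mode, pre, spec) for roi in data.rois]
    sides = half_split(data.meta).to_numpy()
    frames_X = [s.values.T for s in sigs]             # (T, n_features) each
    labels = data.meta.label.to_numpy()
    classes = sorted(data.meta.label.unique())
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    for test_side in ("left", "right"):
        test = sides == test_side
        Xtr = np.vstack([f for f, t in zip(frames_X, test) if not t])
        ytr = np.concatenate([[lab] * len(f) for f, lab, t
                              in zip(frames_X, labels, test) if not t])
        Xte = np.vstack([f for f, t in zip(frames_X, test) if t])
        yte = np.concatenate([[lab] * len(f) for f, lab, t
                              in zip(frames_X, labels, test) if t])
        clf = clone(base_clf).fit(Xtr, ytr)
        pred = clf.predict(Xte)
        for t, p in zip(yte, pred):
            confusion[index[t], index[p]] += 1
        fold_acc.append(float(np.mean(pred == yte)))
    return EvaluationReport(
        level="single-time-point",
        confusion=pd.DataFrame(confusion,
                               index=pd.Index(classes, name="true"),
                               columns=pd.Index(classes, name="predicted")),
        fold_accuracies=fold_acc, classifier=base_clf.kind, mode=mode)
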