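"""Per-track feature signals and track descriptors.

Two branches, mirroring the two arms of the benchmark:

* deep branch — every preprocessed crop is pushed through a pluggable
  *backbone* whose flattened activations give one feature vector per frame;
  stacking over frames yields feature signals f_i(t), and the track
  descriptor is the per-feature standard deviation over time (features that
  are identically zero along the whole sequence are dropped as inactive).

* traditional branch — the cell is segmented in every crop, and classical
  shape descriptors (perimeter, area, eccentricity, solidity) plus 13
  Haralick GLCM texture statistics are computed per frame; each feature's
  trajectory is summarized by five statistics (mean, std, skewness, kurtosis,
  Shannon entropy of its value histogram).

Named pretrained CNN backbones (alexnet, googlenet, resnet101, nasnetlarge)
are declared with their published pooling layer, input size and feature
count; instantiating them requires torch/torchvision.  The always-available
``fallback`` backbone is a deterministic multi-scale filter bank with
spatially pooled, randomly mixed rectified units — it preserves the
interface and the qualitative behaviour of a fixed convolutional feature
extractor (including sensitivity to global luminance, through its ReLU
thresholds) without any model download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.feature import graycomatrix
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing, disk
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu

from .roi import RoiSequence

__all__ = [
    "BACKBONE_REGISTRY",
    "BackboneSpec",
    "FeatureSignals",
    "FilterBankBackbone",
    "backbone_features",
    "dynamics_descriptor",
    "segment_cell",
    "segment_sequence",
    "shape_texture_descriptor",
    "haralick_features",
    "HARALICK_NAMES",
    "TRAJECTORY_STATS",
]

#: published transfer-learning contract of each supported CNN:
#: (pooling layer, input size px, number of extracted features)
BACKBONE_REGISTRY = {
    "alexnet": {"layer": "pool5", "input_size": 227, "n_features": 9216},
    "googlenet": {"layer": "pool5", "input_size": 224, "n_features": 1024},
    "resnet101": {"layer": "pool5", "input_size": 224, "n_features": 2048},
    "nasnetlarge": {"layer": "average_pooling", "input_size": 331,
                    "n_features": 4032},
}

TRAJECTORY_STATS = ("mean", "std", "skewness", "kurtosis", "entropy")


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "fallback"
    output_dim: int = 256        # fallback only; named backbones are fixed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("fallback", *BACKBONE_REGISTRY):
            raise ValueError(f"unknown backbone {self.name!r}")
        if self.output_dim < 1:
            raise ValueError("output_dim must be positive")

    @property
    def n_features(self) -> int:
        if self.name == "fallback":
            return self.output_dim
        return BACKBONE_REGISTRY[self.name]["n_features"]


@dataclass
class FeatureSignals:
    """Feature signals f_i(t): one row per feature, one column per frame."""

    values: np.ndarray           # (n_features, T)
    track_id: int
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature signals must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


class FilterBankBackbone:
    """Deterministic hand-designed feature extractor for 2D crops.

    Stage 1 computes nine 63x63 feature maps: Gaussian-smoothed intensity at
    two scales, two difference-of-Gaussian band-pass maps, gradient
    magnitude, and four oriented first-derivative maps.  Stage 2 pools each
    map over a 3x3 spatial grid (mean and max).  Stage 3 mixes the pooled
    vector through a fixed seeded random affine map followed by a ReLU,
    emulating the rectified, luminance-dependent units of a convolutional
    network: half of each unit's weight mass lies (positively) on the
    intensity channels, so a global graylevel shift moves units across their
    activation threshold instead of cancelling out.
    """

    _GRID = 3

    def __init__(self, output_dim: int = 256, seed: int = 0) -> None:
        self.output_dim = int(output_dim)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        n_maps, stats_per_cell = 9, 2
        self._n_int = 2 * self._GRID ** 2 * stats_per_cell  # intensity dims
        n_pool = n_maps * self._GRID ** 2 * stats_per_cell
        w_int = np.abs(rng.normal(size=(self.output_dim, self._n_int)))
        w_int /= w_int.sum(axis=1, keepdims=True)
        w_edge = rng.normal(size=(self.output_dim, n_pool - self._n_int))
        w_edge /= np.abs(w_edge).sum(axis=1, keepdims=True)
        # equal L1 mass on intensity (positive) and edge (signed) channels
        self._w = np.hstack([0.5 * w_int, 0.5 * w_edge])
        self._theta = rng.uniform(0.0, 0.35, size=self.output_dim)

    def _maps(self, frame: np.ndarray) -> list[np.ndarray]:
        g1 = ndimage.gaussian_filter(frame, 1.5)
        g2 = ndimage.gaussian_filter(frame, 3.0)
        g3 = ndimage.gaussian_filter(frame, 6.0)
        gy, gx = np.gradient(g1)
        return [g1, g2, g1 - g2, g2 - g3, np.hypot(gx, gy),
                gx, gy, (gx + gy) / np.sqrt(2), (gx - gy) / np.sqrt(2)]

    def _pool(self, m: np.ndarray) -> np.ndarray:
        h, w = m.shape
        ys = np.linspace(0, h, self._GRID + 1).astype(int)
        xs = np.linspace(0, w, self._GRID + 1).astype(int)
        out = []
        for i in range(self._GRID):
            for j in range(self._GRID):
                cell = m[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
                out.append(cell.mean())
                out.append(cell.max())
        return np.asarray(out)

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=np.float64)
        maps = self._maps(frame)
        pooled = np.concatenate([self._pool(m) for m in maps])
        pre = self._w @ pooled - self._theta
        return np.maximum(pre, 0.0)


def _load_pretrained(spec: BackboneSpec):
    try:
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            f"backbone {spec.name!r} requires torchvision (layer "
            f"{BACKBONE_REGISTRY[spec.name]['layer']!r}, "
            f"{BACKBONE_REGISTRY[spec.name]['n_features']} features). "
            "Install torch+torchvision, or use BackboneSpec(name='fallback') "
            "for the built-in deterministic filter bank.") from exc
    raise NotImplementedError(
        "pretrained backbone loading is delegated to torchvision; resize the "
        f"crop bicubically to {BACKBONE_REGISTRY[spec.name]['input_size']} px, "
        "replicate to 3 channels and read the registered pooling layer")


def backbone_features(roi: RoiSequence, spec: BackboneSpec) -> FeatureSignals:
    """Encode every crop of a preprocessed ROI sequence into feature signals."""
    if spec.name != "fallback":
        _load_pretrained(spec)
    backbone = FilterBankBackbone(spec.output_dim, spec.seed)
    vecs = np.stack([backbone(frame) for frame in roi.pixels], axis=1)
    return FeatureSignals(values=vecs, track_id=roi.track_id,
                          feature_ids=np.arange(spec.n_features))


def dynamics_descriptor(signals: FeatureSignals,
                        relative: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature temporal variability: sample std of f_i(t) over t.

    Features that are zero for the entire sequence are inactive and dropped;
    the returned ``feature_ids`` identify the survivors.  With ``relative``
    the coefficient of variation std/|mean| is used instead (mean-zero
    survivors fall back to plain std).
    """
    if signals.n_frames < 2:
        raise ValueError("dynamics are undefined on single-frame tracks")
    active = ~np.all(signals.values == 0.0, axis=1)
    vals = signals.values[active]
    sd = vals.std(axis=1, ddof=1)
    if relative:
        m = np.abs(vals.mean(axis=1))
        sd = np.where(m > 1e-12, sd / np.maximum(m, 1e-12), sd)
    return sd, signals.feature_ids[active]


# ---------------------------------------------------------------------------
# traditional branch: segmentation + shape/texture descriptors
# ---------------------------------------------------------------------------

def segment_cell(frame: np.ndarray, min_size: int = 16) -> tuple[np.ndarray, bool]:
    """Classical central-cell segmentation of one preprocessed crop.

    Otsu threshold, morphological closing, hole filling, small-object
    removal, then the component closest to the crop centre is kept.  Returns
    (mask, ok); an empty foreground gives an all-false mask with ok=False.
    Any mask provider with this signature can stand in (e.g. a trained
    semantic-segmentation model).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.max() - frame.min() < 1e-9:
        return np.zeros(frame.shape, dtype=bool), False
    th = threshold_otsu(frame)
    mask = frame > th
    mask = closing(mask, disk(2))
    mask = binary_fill_holes(mask)
    labels0 = cc_label(mask)
    for prop in regionprops(labels0):
        if prop.area < min_size:
            mask[labels0 == prop.label] = False
    if not mask.any():
        return np.zeros(frame.shape, dtype=bool), False
    labels = cc_label(mask)
    cy, cx = (np.asarray(frame.shape) - 1) / 2.0
    best, best_d = 0, np.inf
    for prop in regionprops(labels):
        d = np.hypot(prop.centroid[0] - cy, prop.centroid[1] - cx)
        if d < best_d:
            best, best_d = prop.label, d
    return labels == best, True


def segment_sequence(roi: RoiSequence) -> tuple[np.ndarray, np.ndarray]:
    """Segment every crop; returns (masks (T,S,S) bool, ok flags (T,))."""
    masks = np.zeros_like(roi.pixels, dtype=bool)
    ok = np.zeros(len(roi), dtype=bool)
    for t, frame in enumerate(roi.pixels):
        masks[t], ok[t] = segment_cell(frame)
    return masks, ok


HARALICK_NAMES = (
    "angular_second_moment", "contrast", "correlation", "sum_of_squares",
    "inverse_difference_moment", "sum_average", "sum_variance", "sum_entropy",
    "entropy", "difference_variance", "difference_entropy",
    "info_measure_corr_1", "info_measure_corr_2",
)

_EPS = 1e-12


def _haralick_from_glcm(p: np.ndarray) -> np.ndarray:
    """The 13 classical co-occurrence statistics of one normalized GLCM."""
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x, mu_y = (i * px).sum(), (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())
    k_sum = np.arange(2 * n - 1, dtype=np.float64)
    p_sum = np.array([p[ii + jj == k].sum() for k in range(2 * n - 1)])
    k_diff = np.arange(n, dtype=np.float64)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in range(n)])

    asm = (p ** 2).sum()
    contrast = (k_diff ** 2 * p_diff).sum()
    if sd_x * sd_y > _EPS:
        corr = (((ii - mu_x) * (jj - mu_y) * p).sum()) / (sd_x * sd_y)
    else:
        corr = 0.0
    ssq = ((ii - mu_x) ** 2 * p).sum()
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()
    sum_avg = (k_sum * p_sum).sum()
    sum_ent = -(p_sum * np.log2(p_sum + _EPS))[p_sum > 0].sum()
    sum_var = ((k_sum - sum_avg) ** 2 * p_sum).sum()
    ent = -(p * np.log2(p + _EPS))[p > 0].sum()
    diff_avg = (k_diff * p_diff).sum()
    diff_var = ((k_diff - diff_avg) ** 2 * p_diff).sum()
    diff_ent = -(p_diff * np.log2(p_diff + _EPS))[p_diff > 0].sum()
    hx = -(px * np.log2(px + _EPS))[px > 0].sum()
    hy = -(py * np.log2(py + _EPS))[py > 0].sum()
    pxy = np.outer(px, py)
    hxy1 = -(p * np.log2(pxy + _EPS)).sum()
    hxy2 = -(pxy * np.log2(pxy + _EPS)).sum()
    denom = max(hx, hy)
    imc1 = (ent - hxy1) / denom if denom > _EPS else 0.0
    imc2 = np.sqrt(max(1.0 - np.exp(-2.0 * np.log(2) * (hxy2 - ent)), 0.0))
    return np.array([asm, contrast, corr, ssq, idm, sum_avg, sum_var,
                     sum_ent, ent, diff_var, diff_ent, imc1, imc2])


def haralick_features(frame: np.ndarray, mask: np.ndarray,
                      levels: int = 64) -> np.ndarray:
    """13 Haralick statistics inside a mask, averaged over 4 directions.

    Graylevels are quantized to ``levels`` bins over the masked intensity
    range; pixels outside the mask are excluded from the co-occurrence counts
    by mapping them to a reserved level whose row/column is discarded.
    """
    vals = frame[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    lo, hi = vals.min(), vals.max()
    if hi - lo < _EPS:
        quant = np.ones_like(frame, dtype=np.uint8)  # single occupied level
    else:
        quant = np.clip(((frame - lo) / (hi - lo) * levels).astype(int) + 1,
                        1, levels).astype(np.uint8)
    quant[~mask] = 0
    glcm = graycomatrix(quant, distances=[1],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=levels + 1, symmetric=True, normed=False)
    feats = np.zeros(len(HARALICK_NAMES))
    for a in range(4):
        m = glcm[1:, 1:, 0, a].astype(np.float64)
        tot = m.sum()
        if tot > 0:
            feats += _haralick_from_glcm(m / tot)
    return feats / 4.0


def _shannon_entropy(signal: np.ndarray, bins: int = 32) -> float:
    """Shannon entropy (bits) of a 32-bin histogram of the signal's values."""
    if np.ptp(signal) < 1e-12:
        return 0.0  # effectively constant: single occupied bin
    h, _ = np.histogram(signal, bins=bins)
    p = h / h.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _trajectory_stats(signal: np.ndarray) -> np.ndarray:
    m = float(np.mean(signal))
    sd = float(np.std(signal, ddof=1))
    if sd < _EPS:
        skew = kurt = 0.0  # degenerate-moment convention
    else:
        skew = float(stats.skew(signal))
        kurt = float(stats.kurtosis(signal))
    return np.array([m, sd, skew, kurt, _shannon_entropy(signal)])


def shape_texture_descriptor(
        roi: RoiSequence, masks: np.ndarray,
        ok: np.ndarray | None = None) -> tuple[np.ndarray, list[str]]:
    """Traditional-branch track descriptor.

    Per frame with a valid mask: perimeter, area, eccentricity, solidity of
    the segmented cell plus 13 Haralick texture statistics inside it; each of
    the 17 per-frame features is then summarized over the trajectory by the
    five statistics (mean, std, skewness, kurtosis, Shannon entropy),
    concatenated feature-major.
    """
    if ok is None:
        ok = np.array([m.any() for m in masks])
    if ok.sum() < 2:
        raise ValueError("need valid masks on at least 2 frames")
    base = ["perimeter", "area", "eccentricity", "solidity"] + \
        [f"haralick_{n}" for n in HARALICK_NAMES]
    per_frame = []
    for t in np.flatnonzero(ok):
        prop = max(regionprops(masks[t].astype(np.uint8)), key=lambda r: r.area)
        shape_feats = [prop.perimeter, prop.area, prop.eccentricity,
                       prop.solidity]
        per_frame.append(np.concatenate([
            shape_feats, haralick_features(roi.pixels[t], masks[t])]))
    sigs = np.asarray(per_frame).T  # (17, T_valid)
    desc = np.concatenate([_trajectory_stats(s) for s in sigs])
    names = [f"{b}_{s}" for b in base for s in TRAJECTORY_STATS]
    return desc, names
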