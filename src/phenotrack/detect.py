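"""Cell localization and frame-to-frame tracking.

Detection uses the Circular Hough Transform on Canny edges, tuned for dark
quasi-circular cells on a brighter background, searching radii in a physical
range (default 4.3–7.6 µm, ~13–23 px at 0.33 µm/px).  Detections are linked
across frames by solving the minimum-cost bipartite assignment (Munkres /
Hungarian) on squared centroid distances with a gating radius; unmatched
detections open new tracks and short detection gaps are bridged by linear
interpolation.  Tracks are finally grouped into spatial clusters as connected
components of the time-averaged-centroid proximity graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "DetectionConfig",
    "Detection",
    "Track",
    "ClusterAssignment",
    "detect_cells",
    "detect_stack",
    "link_tracks",
    "assignment_cost",
    "identify_clusters",
    "tracks_to_frame",
    "track_video",
]

_GATE_COST_FACTOR = 1.0000001  # virtual non-link cost slightly above the gate


@dataclass(frozen=True)
class DetectionConfig:
    radius_range_um: tuple[float, float] = (4.3, 7.6)
    resolution_um_per_px: float = 0.33
    sensitivity: float = 0.30       # Hough accumulator threshold, fraction of max
    canny_sigma: float = 2.0
    radius_step_px: int = 2
    min_separation_factor: float = 1.5  # peak suppression, in units of min radius

    def __post_init__(self) -> None:
        lo, hi = self.radius_range_um
        if not 0 < lo < hi:
            raise ValueError("radius_range_um must be increasing and positive")
        if not 0 < self.sensitivity <= 1:
            raise ValueError("sensitivity must be in (0, 1]")

    @property
    def radii_px(self) -> np.ndarray:
        lo = self.radius_range_um[0] / self.resolution_um_per_px
        hi = self.radius_range_um[1] / self.resolution_um_per_px
        return np.arange(int(np.floor(lo)), int(np.ceil(hi)) + 1,
                         self.radius_step_px)


@dataclass(frozen=True)
class Detection:
    frame: int
    x: float  # column, 0-based
    y: float  # row, 0-based
    radius: float


@dataclass
class Track:
    track_id: int
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    radii: list[float] = field(default_factory=list)
    interpolated: list[bool] = field(default_factory=list)
    cluster_id: int = -1

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(np.mean(self.xs)), float(np.mean(self.ys))

    def positions(self) -> np.ndarray:
        return np.column_stack([self.xs, self.ys])


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[int, int]          # track_id -> cluster_id
    distance_threshold_px: float
    linkage: str = "single-linkage connected components"

    def cluster_of(self, track_id: int) -> int:
        return self.labels[track_id]


def _refine_center(frame: np.ndarray, x: float, y: float,
                   radius: float) -> tuple[float, float]:
    """Sub-pixel refinement: dark-mass centroid inside the detected circle."""
    h, w = frame.shape
    r = int(np.ceil(radius)) + 2
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    win = frame[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = np.hypot(xx - x, yy - y) <= radius + 1
    weight = np.where(inside, np.maximum(win.max() - win, 0.0), 0.0)
    total = weight.sum()
    if total <= 0:
        return x, y
    return float((xx * weight).sum() / total), float((yy * weight).sum() / total)


def detect_cells(frame: np.ndarray, config: DetectionConfig) -> list[Detection]:
    """Locate circular cells in one calibrated grayscale frame.

    Hough peaks (integer accumulator grid) are refined to sub-pixel centers
    by the dark-mass centroid inside the detected circle.  A uniform frame
    yields no edges and hence an empty list.
    """
    frame = np.asarray(frame, dtype=np.float64)
    edges = canny(frame, sigma=config.canny_sigma)
    if not edges.any():
        return []
    radii = config.radii_px
    accum = hough_circle(edges, radii)
    min_dist = max(int(radii[0] * config.min_separation_factor), 1)
    _, cx, cy, rad = hough_circle_peaks(
        accum, radii, min_xdistance=min_dist, min_ydistance=min_dist,
        threshold=config.sensitivity * accum.max(), normalize=False)
    h, w = frame.shape
    out = []
    for x, y, r in zip(cx, cy, rad):
        if not (0 <= x < w and 0 <= y < h):
            continue
        rx, ry = _refine_center(frame, float(x), float(y), float(r))
        out.append(Detection(frame=-1, x=rx, y=ry, radius=float(r)))
    return out


def detect_stack(stack: np.ndarray, config: DetectionConfig) -> list[list[Detection]]:
    """Run detection over every frame of a (T, H, W) stack."""
    out = []
    for t, frame in enumerate(stack):
        dets = [Detection(frame=t, x=d.x, y=d.y, radius=d.radius)
                for d in detect_cells(frame, config)]
        out.append(dets)
    return out


def assignment_cost(cost: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """Minimum-total-cost assignment of a rectangular cost matrix.

    Exact Hungarian solution; returns (total cost, matched (row, col) pairs).
    This is the primitive the tracker uses for frame-to-frame linking.
    """
    cost = np.asarray(cost, dtype=np.float64)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum()), list(zip(rows.tolist(), cols.tolist()))


def _gated_assignment(prev_xy: np.ndarray, det_xy: np.ndarray,
                      gate_px: float) -> list[tuple[int, int]]:
    """Assign tracks to detections with a gating radius.

    The cost matrix is padded with virtual birth/death nodes priced at the
    gate cost, so pairs farther apart than the gate are never linked while
    total cost remains the Hungarian minimum over admissible pairings.
    """
    n, m = len(prev_xy), len(det_xy)
    if n == 0 or m == 0:
        return []
    d2 = ((prev_xy[:, None, :] - det_xy[None, :, :]) ** 2).sum(-1)
    gate2 = gate_px * gate_px * _GATE_COST_FACTOR
    size = n + m
    big = np.full((size, size), 0.0)
    big[:n, :m] = d2
    big[:n, m:] = np.inf
    big[n:, :m] = np.inf
    np.fill_diagonal(big[:n, m:], gate2)
    np.fill_diagonal(big[n:, :m], gate2)
    rows, cols = linear_sum_assignment(big)
    return [(r, c) for r, c in zip(rows, cols)
            if r < n and c < m and d2[r, c] <= gate_px * gate_px]


def link_tracks(detections: list[list[Detection]], max_link_distance: float,
                max_gap: int = 2, min_track_length: int = 10) -> list[Track]:
    """Link per-frame detections into trajectories.

    Frame-to-frame pairings minimise total squared centroid displacement
    among pairings within ``max_link_distance`` px.  Tracks missing from up to
    ``max_gap`` consecutive frames stay open; bridged positions are linearly
    interpolated and flagged.  Tracks shorter than ``min_track_length`` frames
    are discarded (dynamics statistics on very short signals are meaningless).
    """
    open_tracks: list[tuple[Track, int]] = []  # (track, last frame seen)
    done: list[Track] = []
    next_id = 0
    for t, dets in enumerate(detections):
        still_open = []
        for track, last in open_tracks:
            if t - last > max_gap + 1:
                done.append(track)
            else:
                still_open.append((track, last))
        open_tracks = still_open
        det_xy = np.array([[d.x, d.y] for d in dets], dtype=float).reshape(-1, 2)
        prev_xy = np.array([[tr.xs[-1], tr.ys[-1]] for tr, _ in open_tracks],
                           dtype=float).reshape(-1, 2)
        matches = _gated_assignment(prev_xy, det_xy, max_link_distance)
        matched_tracks, matched_dets = set(), set()
        for r, c in matches:
            track, last = open_tracks[r]
            d = dets[c]
            _append_with_gap_fill(track, last, t, d)
            open_tracks[r] = (track, t)
            matched_tracks.add(r)
            matched_dets.add(c)
        for c, d in enumerate(dets):
            if c not in matched_dets:
                tr = Track(track_id=next_id)
                next_id += 1
                tr.frames.append(t)
                tr.xs.append(d.x)
                tr.ys.append(d.y)
                tr.radii.append(d.radius)
                tr.interpolated.append(False)
                open_tracks.append((tr, t))
    done.extend(tr for tr, _ in open_tracks)
    done = [tr for tr in done if len(tr) >= min_track_length]
    done.sort(key=lambda tr: (tr.frames[0], tr.track_id))
    for new_id, tr in enumerate(done):
        tr.track_id = new_id
    return done


def _append_with_gap_fill(track: Track, last_frame: int, frame: int,
                          det: Detection) -> None:
    gap = frame - last_frame - 1
    if gap > 0:
        x0, y0, r0 = track.xs[-1], track.ys[-1], track.radii[-1]
        for g in range(1, gap + 1):
            w = g / (gap + 1)
            track.frames.append(last_frame + g)
            track.xs.append(x0 + w * (det.x - x0))
            track.ys.append(y0 + w * (det.y - y0))
            track.radii.append(r0 + w * (det.radius - r0))
            track.interpolated.append(True)
    track.frames.append(frame)
    track.xs.append(det.x)
    track.ys.append(det.y)
    track.radii.append(det.radius)
    track.interpolated.append(False)


def identify_clusters(tracks: list[Track], threshold_px: float) -> ClusterAssignment:
    """Group tracks into spatial clusters.

    Single-linkage: two tracks are joined when their time-averaged centroids
    are closer than ``threshold_px``; clusters are the connected components.
    Invariant to the order of the input tracks (components are relabelled by
    the smallest member track_id).
    """
    if not tracks:
        raise ValueError("identify_clusters requires at least one track")
    cent = np.array([tr.centroid for tr in tracks])
    d = np.sqrt(((cent[:, None, :] - cent[None, :, :]) ** 2).sum(-1))
    adj = csr_matrix(d < threshold_px)
    n_comp, labels = connected_components(adj, directed=False)
    # canonical relabelling: order components by their minimum track_id
    ids = np.array([tr.track_id for tr in tracks])
    order = sorted(range(n_comp), key=lambda c: ids[labels == c].min())
    remap = {c: i for i, c in enumerate(order)}
    mapping = {int(tr.track_id): remap[int(lab)]
               for tr, lab in zip(tracks, labels)}
    for tr in tracks:
        tr.cluster_id = mapping[tr.track_id]
    return ClusterAssignment(labels=mapping, distance_threshold_px=threshold_px)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to a tidy table (0-based px coordinates, x = column)."""
    rows = []
    for tr in tracks:
        for f, x, y, r, itp in zip(tr.frames, tr.xs, tr.ys, tr.radii,
                                   tr.interpolated):
            rows.append((tr.track_id, f, x, y, r, tr.cluster_id, itp))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                       "radius_px", "cluster_id", "interpolated"])


def track_video(stack: np.ndarray, config: DetectionConfig,
                max_link_distance: float | None = None, max_gap: int = 2,
                min_track_length: int = 10,
                cluster_threshold: float | None = None) -> list[Track]:
    """Detect, link and cluster in one call; defaults derive from cell size.

    The gating radius defaults to 2x the mean radius of the configured search
    range; the cluster threshold to 2x the mean diameter.
    """
    mean_r = float(np.mean(config.radii_px))
    if max_link_distance is None:
        max_link_distance = 2.0 * mean_r
    if cluster_threshold is None:
        cluster_threshold = 4.0 * mean_r
    dets = detect_stack(stack, config)
    tracks = link_tracks(dets, max_link_distance, max_gap, min_track_length)
    if tracks:
        identify_clusters(tracks, cluster_threshold)
    return tracks
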