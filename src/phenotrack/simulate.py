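"""Synthetic label-free time-lapse videos with ground-truth tracks.

Emulates brightfield acquisitions of clustered, slowly moving epithelial-like
cells: dark, roughly circular objects on a brighter uniform background, with a
class-dependent *morphodynamic* signal injected as a time-varying perturbation
of the cell boundary.  Every quantity a downstream stage estimates (centers,
radii, cluster membership, class labels) is available as ground truth, so the
whole pipeline is testable without external data.

Physical conventions: positions and radii in the truth tables are in pixels,
0-based, ``x`` = column, ``y`` = row.  The configuration speaks micrometres
and minutes and is converted through ``resolution`` (µm/px) and
``frame_interval`` (min/frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ClassParams",
    "SimulationConfig",
    "generate_video",
    "inject_bias",
    "truth_mask",
    "truth_area_signal",
]

#: harmonic orders of the boundary perturbation and their relative weights;
#: low orders dominate, as in blebbing/ruffling cells
_HARMONICS = (2, 3, 4, 5)
_HARMONIC_WEIGHTS = (1.0, 0.7, 0.5, 0.35)


@dataclass(frozen=True)
class ClassParams:
    """Morphodynamic parameters of one phenotype class.

    fluctuation_amplitude is the dimensionless scale of the radial boundary
    perturbation (0 = rigid disc); fluctuation_rate (1/min) sets how fast the
    perturbation phases drift, i.e. how quickly the shape decorrelates.
    """

    radius_mean_um: float = 5.9
    radius_sd_um: float = 0.5
    speed_um_min: float = 0.10
    fluctuation_amplitude: float = 0.0
    fluctuation_rate_per_min: float = 0.15


@dataclass(frozen=True)
class SimulationConfig:
    image_size: tuple[int, int] = (512, 512)  # (H, W) px
    n_frames: int = 60
    frame_interval_min: float = 1.0
    resolution_um_per_px: float = 0.33
    classes: tuple[ClassParams, ...] = (ClassParams(), ClassParams())
    n_clusters: int = 4
    cells_per_cluster: int = 5
    intra_cluster_spacing_um: float = 18.0
    inter_cluster_spacing_um: float = 84.5
    background_level: float = 0.44
    cell_depth: float = 0.28  # graylevel drop of a cell below background
    noise_sd: float = 0.008
    ou_tether_per_min: float = 0.05  # mean-reversion rate toward cluster anchor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_clusters < 1 or self.cells_per_cluster < 1:
            raise ValueError("counts must be positive")
        for name in ("frame_interval_min", "resolution_um_per_px",
                     "intra_cluster_spacing_um", "inter_cluster_spacing_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.classes:
            raise ValueError("at least one phenotype class is required")
        lo = self.background_level - self.cell_depth - 3 * self.noise_sd
        hi = self.background_level + 3 * self.noise_sd
        if lo < 0 or hi > 1:
            raise ValueError(
                "background_level / cell_depth / noise_sd leave the [0, 1] "
                "graylevel range (checked at +-3 sigma)")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def px(self, um: float) -> float:
        """Convert micrometres to pixels."""
        return um / self.resolution_um_per_px


@dataclass
class _Cell:
    cell_id: int
    cluster_id: int
    class_label: int
    radius_px: float
    anchor: np.ndarray          # (2,) cluster-tether point, (x, y) px
    positions: np.ndarray       # (T, 2) float px
    phases: np.ndarray          # (T, len(_HARMONICS)) boundary phases
    amplitude: float            # fluctuation_amplitude of its class


@dataclass
class GroundTruth:
    """Per-cell trajectories, labels and cluster memberships of a simulation."""

    table: pd.DataFrame  # cell_id, frame, x_px, y_px, radius_px, class_label, cluster_id
    config: SimulationConfig
    cells: list[_Cell] = field(repr=False, default_factory=list)

    def trajectory(self, cell_id: int) -> pd.DataFrame:
        return self.table[self.table.cell_id == cell_id].sort_values("frame")


def _cluster_centers(cfg: SimulationConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    """Lay cluster anchors on a centred grid with the configured pitch.

    Classes are assigned in a checkerboard pattern ((row + col) mod
    n_classes) so that each lateral half of the field of view contains every
    class — a requirement of the left/right cross-validation protocol.
    """
    h, w = cfg.image_size
    pitch = cfg.px(cfg.inter_cluster_spacing_um)
    ncol = int(np.ceil(np.sqrt(cfg.n_clusters)))
    nrow = int(np.ceil(cfg.n_clusters / ncol))
    margin = cfg.px(cfg.intra_cluster_spacing_um) + \
        cfg.px(cfg.classes[0].radius_mean_um) * 3
    grid_w, grid_h = (ncol - 1) * pitch, (nrow - 1) * pitch
    if grid_w + 2 * margin > w or grid_h + 2 * margin > h:
        raise ValueError(
            "cluster layout does not fit the field of view: "
            f"need {grid_w + 2 * margin:.0f}x{grid_h + 2 * margin:.0f} px, "
            f"have {w}x{h}; reduce n_clusters or spacings")
    x0, y0 = (w - grid_w) / 2, (h - grid_h) / 2
    cells = [(x0 + c * pitch, y0 + r * pitch, (r + c) % cfg.n_classes)
             for r in range(nrow) for c in range(ncol)][: cfg.n_clusters]
    centers = np.asarray([(x, y) for x, y, _ in cells], dtype=float)
    return centers, [k for _, _, k in cells]


def _place_cells(cfg: SimulationConfig, rng: np.random.Generator) -> list[_Cell]:
    centers, classes = _cluster_centers(cfg, rng)
    ring = cfg.px(cfg.intra_cluster_spacing_um)
    cells: list[_Cell] = []
    cid = 0
    for k, (center, klass) in enumerate(zip(centers, classes)):
        params = cfg.classes[klass]
        n = cfg.cells_per_cluster
        base_angle = rng.uniform(0, 2 * np.pi)
        for j in range(n):
            ang = base_angle + 2 * np.pi * j / n
            pos = center + ring * np.array([np.cos(ang), np.sin(ang)])
            radius = cfg.px(max(rng.normal(params.radius_mean_um,
                                           params.radius_sd_um),
                                0.3 * params.radius_mean_um))
            cells.append(_Cell(cell_id=cid, cluster_id=k, class_label=klass,
                               radius_px=radius, anchor=pos,
                               positions=np.empty((cfg.n_frames, 2)),
                               phases=np.empty((cfg.n_frames, len(_HARMONICS))),
                               amplitude=params.fluctuation_amplitude))
            cid += 1
        # minimum pairwise spacing inside the ring must clear 2 radii + margin
        chord = 2 * ring * np.sin(np.pi / n) if n > 1 else np.inf
        max_r = max(c.radius_px for c in cells[-n:])
        if chord < 2.2 * max_r:
            raise ValueError(
                "cell density too high: intra-cluster chord "
                f"{chord:.1f} px < 2.2 x radius {max_r:.1f} px")
    return cells


def _simulate_motion(cfg: SimulationConfig, cells: list[_Cell],
                     rng: np.random.Generator) -> None:
    dt = cfg.frame_interval_min
    kappa = cfg.ou_tether_per_min * dt
    for cell in cells:
        params = cfg.classes[cell.class_label]
        step_sd = cfg.px(params.speed_um_min) * dt
        pos = cell.anchor.copy()
        phase = rng.uniform(0, 2 * np.pi, size=len(_HARMONICS))
        phase_sd = params.fluctuation_rate_per_min * dt * 2 * np.pi
        for t in range(cfg.n_frames):
            cell.positions[t] = pos
            cell.phases[t] = phase
            pos = pos + kappa * (cell.anchor - pos) + rng.normal(0, step_sd, 2)
            phase = phase + rng.normal(0, phase_sd, len(_HARMONICS))


def _boundary_radius(cell: _Cell, t: int, theta: np.ndarray) -> np.ndarray:
    """Perturbed radius r(theta, t) of the cell boundary, in px."""
    r = np.ones_like(theta)
    if cell.amplitude > 0:
        wsum = sum(_HARMONIC_WEIGHTS)
        for k, w, ph in zip(_HARMONICS, _HARMONIC_WEIGHTS, cell.phases[t]):
            r = r + cell.amplitude * (w / wsum) * np.sin(k * theta + ph)
    return cell.radius_px * r


def _render_cell(frame: np.ndarray, cell: _Cell, t: int, depth: float) -> None:
    """Subtract a soft-edged, boundary-perturbed disc from `frame` in place."""
    h, w = frame.shape
    cx, cy = cell.positions[t]
    rmax = cell.radius_px * (1 + cell.amplitude) + 2
    x0, x1 = int(max(np.floor(cx - rmax), 0)), int(min(np.ceil(cx + rmax) + 1, w))
    y0, y1 = int(max(np.floor(cy - rmax), 0)), int(min(np.ceil(cy + rmax) + 1, h))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    edge = _boundary_radius(cell, t, theta)
    # soft edge ~1 px wide keeps the rendering band-limited
    mask = 1.0 / (1.0 + np.exp((rho - edge) / 0.6))
    frame[y0:y1, x0:x1] -= depth * mask


def truth_mask(cell: _Cell, t: int, shape: tuple[int, int]) -> np.ndarray:
    """Boolean ground-truth mask of one cell at frame t (hard boundary)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cell.positions[t, 0], yy - cell.positions[t, 1]
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    return rho <= _boundary_radius(cell, t, theta)


def truth_area_signal(cell: _Cell, n_theta: int = 720) -> np.ndarray:
    """Analytic cell area over time, A(t) = 1/2 ∮ r(theta,t)^2 dtheta, in px^2."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    areas = []
    for t in range(cell.phases.shape[0]):
        r = _boundary_radius(cell, t, theta)
        areas.append(0.5 * np.sum(r ** 2) * (2 * np.pi / n_theta))
    return np.asarray(areas)


def generate_video(config: SimulationConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render a (T, H, W) float64 graylevel stack in [0, 1] plus ground truth.

    Classes differ only through their ``ClassParams``; clusters are assigned
    classes round-robin.  Deterministic: the same config (including seed)
    yields bit-identical pixels and truth tables.
    """
    rng = np.random.default_rng(config.seed)
    cells = _place_cells(config, rng)
    _simulate_motion(config, cells, rng)
    h, w = config.image_size
    stack = np.empty((config.n_frames, h, w), dtype=np.float64)
    for t in range(config.n_frames):
        frame = np.full((h, w), config.background_level, dtype=np.float64)
        for cell in cells:
            _render_cell(frame, cell, t, config.cell_depth)
        frame += rng.normal(0, config.noise_sd, size=frame.shape)
        np.clip(frame, 0.0, 1.0, out=frame)
        stack[t] = frame
    rows = [(c.cell_id, t, c.positions[t, 0], c.positions[t, 1], c.radius_px,
             c.class_label, c.cluster_id)
            for c in cells for t in range(config.n_frames)]
    table = pd.DataFrame(rows, columns=["cell_id", "frame", "x_px", "y_px",
                                        "radius_px", "class_label", "cluster_id"])
    return stack, GroundTruth(table=table, config=config, cells=cells)


def inject_bias(images: np.ndarray, bias: float, clip: bool = False) -> np.ndarray:
    """Add a constant graylevel offset to an image set.

    Models a global luminance drift between acquisitions (light source,
    exposure).  With ``clip`` the result is clamped to [0, 1]; without, values
    may exceed 1, which downstream stages must tolerate.
    """
    if bias < 0:
        raise ValueError("bias must be non-negative")
    out = np.asarray(images, dtype=np.float64) + bias
    if clip:
        np.clip(out, 0.0, 1.0, out=out)
    return out


def two_class_config(fluctuation_a: float = 0.0, fluctuation_b: float = 0.3,
                     n_clusters: int = 4, cells_per_cluster: int = 5,
                     n_frames: int = 60, seed: int = 0,
                     **overrides) -> SimulationConfig:
    """Convenience config: two classes differing only in boundary dynamics."""
    base = ClassParams()
    return SimulationConfig(
        classes=(replace(base, fluctuation_amplitude=fluctuation_a),
                 replace(base, fluctuation_amplitude=fluctuation_b)),
        n_clusters=n_clusters, cells_per_cluster=cells_per_cluster,
        n_frames=n_frames, seed=seed, **overrides)
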