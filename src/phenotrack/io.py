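"""Readers/writers and run provenance.

All tabular interchange is CSV with documented columns and 0-based pixel
coordinates (x = column, y = row); videos and ROI stacks are multi-page
grayscale TIFF; configuration is YAML.  Every artifact directory receives a
``provenance.json`` with the resolved configuration, its hash and the seed,
so identical configs reproduce identical CSV outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

TRACK_COLUMNS = ["track_id", "frame", "x_px", "y_px", "radius_px",
                 "cluster_id", "interpolated"]
TRUTH_COLUMNS = ["cell_id", "frame", "x_px", "y_px", "radius_px",
                 "class_label", "cluster_id"]


def write_video(path: str | Path, stack: np.ndarray) -> None:
    """Write a (T, H, W) graylevel stack in [0, 1] as float32 multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_video(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(str(path)).astype(np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.max() > 1.0 + 1e-6:  # integer-encoded gray levels
        stack = stack / np.iinfo(tifffile.imread(str(path)).dtype).max
    return stack


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_tracks(path: str | Path):
    from .detect import Track

    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"tracks file {path} is missing columns {sorted(missing)}")
    tracks = []
    for tid, g in df.groupby("track_id"):
        g = g.sort_values("frame")
        tracks.append(Track(
            track_id=int(tid), frames=g.frame.astype(int).tolist(),
            xs=g.x_px.tolist(), ys=g.y_px.tolist(),
            radii=g.radius_px.tolist(),
            interpolated=(g.interpolated.astype(bool).tolist()
                          if "interpolated" in g else [False] * len(g)),
            cluster_id=int(g.cluster_id.iloc[0])))
    return tracks


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def resolve_config(obj) -> dict:
    """Expand dataclass configs (defaults included) into plain dicts."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: resolve_config(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: resolve_config(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [resolve_config(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(resolved: dict) -> str:
    blob = json.dumps(resolved, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(out_dir: str | Path, resolved: dict, seed: int) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"config": resolved, "config_hash": config_hash(resolved),
               "seed": int(seed)}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str, sort_keys=True))
    return path
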