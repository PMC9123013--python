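"""Shared fixtures: small seeded synthetic scenes reused across test modules."""

import numpy as np
import pytest

from phenotrack.simulate import (ClassParams, SimulationConfig, generate_video,
                                 two_class_config)


@pytest.fixture(scope="session")
def two_class_scene():
    """One rendered video with 2 morphodynamic classes + ground truth."""
    cfg = two_class_config(seed=1)
    stack, truth = generate_video(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def single_cell_scene():
    """A static single cell centred in a small field (detection fixture)."""
    cfg = SimulationConfig(
        image_size=(240, 240), n_frames=5,
        classes=(ClassParams(radius_mean_um=5.9, radius_sd_um=0.0,
                             speed_um_min=0.0, fluctuation_amplitude=0.0),),
        n_clusters=1, cells_per_cluster=1,
        intra_cluster_spacing_um=10.0, noise_sd=0.003, seed=3)
    stack, truth = generate_video(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def truth_dataset():
    """Two-video labelled dataset built on ground-truth tracks (fast path)."""
    from phenotrack.experiment import build_dataset

    cfgs = [two_class_config(seed=s) for s in (11, 12)]
    return build_dataset(cfgs, use_truth_tracks=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
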