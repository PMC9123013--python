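"""Backbone contract, dynamics descriptors, segmentation, shape/texture."""

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from phenotrack.features import (BACKBONE_REGISTRY, BackboneSpec,
                                 FeatureSignals, FilterBankBackbone,
                                 _haralick_from_glcm, backbone_features,
                                 dynamics_descriptor, haralick_features,
                                 segment_cell, shape_texture_descriptor)
from phenotrack.roi import RoiSequence


def _roi(pixels):
    pixels = np.asarray(pixels, dtype=np.float64)
    return RoiSequence(pixels=pixels, track_id=0,
                       frames=np.arange(len(pixels)), stage="enhanced")


def _disc_frame(radius=10.0, size=63, soft=0.8):
    yy, xx = np.mgrid[0:size, 0:size]
    rho = np.hypot(xx - size // 2, yy - size // 2)
    return 1.0 / (1.0 + np.exp((rho - radius) / soft))


class TestBackbone:
    @pytest.mark.parametrize("name,expected", [
        ("alexnet", 9216), ("googlenet", 1024),
        ("resnet101", 2048), ("nasnetlarge", 4032)])
    def test_registry_feature_counts(self, name, expected):
        assert BackboneSpec(name=name).n_features == expected
        assert BACKBONE_REGISTRY[name]["n_features"] == expected

    def test_named_backbone_without_torchvision_raises_remediation(self, rng):
        roi = _roi(rng.uniform(size=(2, 63, 63)))
        with pytest.raises(RuntimeError, match="torchvision.*fallback"):
            backbone_features(roi, BackboneSpec(name="alexnet"))

    def test_fallback_deterministic_given_seed(self, rng):
        frame = rng.uniform(size=(63, 63))
        a = FilterBankBackbone(output_dim=64, seed=7)(frame)
        b = FilterBankBackbone(output_dim=64, seed=7)(frame)
        c = FilterBankBackbone(output_dim=64, seed=8)(frame)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert a.shape == (64,)

    def test_all_zero_input_finite(self):
        roi = _roi(np.zeros((3, 63, 63)))
        sig = backbone_features(roi, BackboneSpec(output_dim=32))
        assert sig.values.shape == (32, 3)
        assert np.all(np.isfinite(sig.values))

    def test_sensitive_to_global_luminance(self, rng):
        """ReLU units move across threshold under a graylevel shift, like a
        CNN trained on natural images; this drives the bias protocol."""
        bb = FilterBankBackbone(output_dim=128, seed=0)
        frame = rng.uniform(0.3, 0.9, size=(63, 63))
        assert not np.allclose(bb(frame), bb(frame - 0.5))


class TestDynamics:
    def test_alternating_signal_sample_std(self):
        sig = FeatureSignals(values=np.array([[0.0, 1.0, 0.0, 1.0]]),
                             track_id=0, feature_ids=np.array([0]))
        desc, ids = dynamics_descriptor(sig)
        assert desc[0] == pytest.approx(0.57735, abs=1e-5)

    def test_constant_zero_and_dropped_features(self):
        vals = np.array([[2.0, 2.0, 2.0], [0.0, 0.0, 0.0], [0.0, 1.0, 2.0]])
        sig = FeatureSignals(values=vals, track_id=0,
                             feature_ids=np.arange(3))
        desc, ids = dynamics_descriptor(sig)
        assert list(ids) == [0, 2]          # all-zero feature dropped
        assert desc[0] == 0.0               # constant -> no dynamics
        assert desc[1] == pytest.approx(1.0)

    def test_single_frame_rejected(self):
        sig = FeatureSignals(values=np.ones((4, 1)), track_id=0,
                             feature_ids=np.arange(4))
        with pytest.raises(ValueError, match="single-frame"):
            dynamics_descriptor(sig)

    def test_relative_std_is_cv(self):
        sig = FeatureSignals(values=np.array([[2.0, 4.0]]), track_id=0,
                             feature_ids=np.array([0]))
        desc, _ = dynamics_descriptor(sig, relative=True)
        assert desc[0] == pytest.approx(np.std([2.0, 4.0], ddof=1) / 3.0)


class TestSegmentation:
    def test_disc_iou_against_truth(self):
        frame = _disc_frame(radius=12)
        mask, ok = segment_cell(frame)
        assert ok
        truth = _disc_frame(radius=12) > 0.5
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.9

    def test_empty_frame_flagged(self):
        mask, ok = segment_cell(np.zeros((63, 63)))
        assert not ok and not mask.any()

    def test_central_component_kept(self):
        frame = _disc_frame(radius=8)
        frame += np.roll(_disc_frame(radius=5), 25, axis=1)  # off-centre blob
        mask, ok = segment_cell(frame)
        assert ok
        ys, xs = np.nonzero(mask)
        assert abs(xs.mean() - 31) < 4 and abs(ys.mean() - 31) < 4


class TestShapeTexture:
    def test_disc_geometry(self):
        frame = _disc_frame(radius=10)
        masks = np.stack([frame > 0.5] * 3)
        roi = _roi(np.stack([frame] * 3))
        desc, names = shape_texture_descriptor(roi, masks)
        area_mean = desc[names.index("area_mean")]
        assert area_mean == pytest.approx(np.pi * 100, rel=0.05)
        assert desc[names.index("eccentricity_mean")] <= 0.15
        assert desc[names.index("solidity_mean")] >= 0.95
        # constant trajectory: std 0, degenerate skew/kurt -> 0
        assert desc[names.index("area_std")] == 0.0
        assert desc[names.index("area_skewness")] == 0.0
        assert desc[names.index("area_kurtosis")] == 0.0

    def test_descriptor_length_contract(self, rng):
        frames = np.stack([_disc_frame(10) + 0.05 * rng.uniform(size=(63, 63))
                           for _ in range(4)])
        masks = frames > 0.5
        desc, names = shape_texture_descriptor(_roi(frames), masks)
        assert len(desc) == len(names) == (4 + 13) * 5

    def test_all_empty_masks_rejected(self, rng):
        roi = _roi(rng.uniform(size=(3, 63, 63)))
        with pytest.raises(ValueError, match="masks"):
            shape_texture_descriptor(roi, np.zeros((3, 63, 63), dtype=bool))


class TestHaralick:
    def test_constant_region_degenerate_texture(self):
        frame = np.full((63, 63), 0.5)
        mask = _disc_frame(10) > 0.5
        feats = haralick_features(frame, mask)
        named = dict(zip(
            ("angular_second_moment", "contrast", "entropy"),
            (feats[0], feats[1], feats[8])))
        assert named["angular_second_moment"] == pytest.approx(1.0)
        assert named["contrast"] == pytest.approx(0.0)
        assert named["entropy"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_skimage_props_on_shared_glcm(self, rng):
        """Independent cross-check: our formulas agree with skimage's
        graycoprops for the statistics both implement."""
        img = (rng.uniform(size=(32, 32)) * 8).astype(np.uint8)
        glcm = graycomatrix(img, [1], [0], levels=8, symmetric=True,
                            normed=False).astype(np.float64)
        p = glcm[:, :, 0, 0] / glcm[:, :, 0, 0].sum()
        ours = _haralick_from_glcm(p)
        norm = graycomatrix(img, [1], [0], levels=8, symmetric=True,
                            normed=True)
        assert ours[0] == pytest.approx(graycoprops(norm, "ASM")[0, 0])
        assert ours[1] == pytest.approx(graycoprops(norm, "contrast")[0, 0])
        assert ours[2] == pytest.approx(
            graycoprops(norm, "correlation")[0, 0], abs=1e-9)
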