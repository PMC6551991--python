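"""Lesion segmentation: configs, augmentation, false-lesion logic, tiling."""

import numpy as np
import pytest

from conftest import lesion_phantom
from tbiq.lesion_seg import (
    LesionModel,
    LesionModelConfig,
    TrainingConfig,
    UNet3DConfig,
    augment,
    build_unet3d,
    compute_false_lesion_mask,
    predict_lesions,
    train_stage1,
    train_stage2,
)
from tbiq.nn import shape_trace
from tbiq.preprocess import extract_brain, normalize_intensities


def test_config_derives_output_patch_from_trace():
    cfg = UNet3DConfig()
    assert cfg.input_patch == 132 and cfg.output_patch == 44
    small = UNet3DConfig(depth=2, first_layer_filters=(2, 3), input_patch=60)
    assert small.output_patch == shape_trace(60, 2)


def test_config_rejects_invalid_patch_size():
    with pytest.raises(ValueError):
        UNet3DConfig(depth=3, input_patch=9)
    with pytest.raises(ValueError):
        LesionModelConfig(probability_threshold=1.5)
    with pytest.raises(ValueError):
        TrainingConfig(learning_rate=0.0)


def test_built_network_output_shape_matches_trace():
    cfg = UNet3DConfig(depth=2, first_layer_filters=(2, 3), input_patch=36, n_classes=2)
    model = build_unet3d(cfg, seed=0)
    x = np.random.default_rng(0).normal(size=(1, 36, 36, 36)).astype(np.float32)
    p = model.net.predict_proba(x)
    o = cfg.output_patch
    assert p.shape == (2, o, o, o)
    assert np.allclose(p.sum(axis=0), 1.0, atol=1e-5)


# -- augmentation ------------------------------------------------------------

def _patch_pair(rng, n=12):
    img = rng.normal(size=(n, n, n)).astype(np.float32)
    lab = (rng.random((n, n, n)) > 0.8).astype(np.int64)
    return img, lab


def test_augment_all_switches_off_is_identity():
    rng = np.random.default_rng(0)
    img, lab = _patch_pair(rng)
    cfg = TrainingConfig(flip=False, translate=False, rotate=False, gaussian_noise=False)
    out_img, out_lab = augment(img, lab, cfg, np.random.default_rng(1))
    assert np.array_equal(out_img, img)
    assert np.array_equal(out_lab, lab)


def test_flip_is_involution_and_conserves_label_count():
    rng = np.random.default_rng(2)
    img, lab = _patch_pair(rng)
    cfg = TrainingConfig(flip=True, translate=False, rotate=False, gaussian_noise=False)
    img1, lab1 = augment(img, lab, cfg, np.random.default_rng(3))
    assert lab1.sum() == lab.sum()          # permutation invariance
    # applying the same flips twice returns the original
    img2, lab2 = augment(img1, lab1, cfg, np.random.default_rng(3))
    assert np.array_equal(lab2, lab)
    assert np.allclose(img2, img)


def test_noise_affects_image_only():
    rng = np.random.default_rng(4)
    img, lab = _patch_pair(rng)
    cfg = TrainingConfig(flip=False, translate=False, rotate=False,
                         gaussian_noise=True, noise_sigma=0.2)
    out_img, out_lab = augment(img, lab, cfg, np.random.default_rng(5))
    assert np.array_equal(out_lab, lab)
    assert not np.array_equal(out_img, img)


def test_augment_rejects_incongruent_pair():
    with pytest.raises(ValueError):
        augment(np.zeros((10, 10, 10), np.float32), np.zeros((9, 10, 10), np.int64),
                TrainingConfig(), np.random.default_rng(0))


# -- false-lesion mask -------------------------------------------------------

def test_false_lesion_mask_is_set_difference():
    truth = np.zeros((10, 10, 10), bool)
    truth[2:5] = True
    seg = truth.copy()
    assert not compute_false_lesion_mask(seg, truth).any()

    seg2 = truth.copy()
    seg2[6, :10, 0] = True  # 10 extra voxels
    fmask = compute_false_lesion_mask(seg2, truth)
    assert fmask.sum() == 10
    assert not (fmask & truth).any()

    assert compute_false_lesion_mask(seg2, np.zeros_like(truth)).sum() == seg2.sum()
    with pytest.raises(ValueError):
        compute_false_lesion_mask(np.zeros((5, 5, 5), bool), truth)


def test_stage2_rejects_false_mask_overlapping_truth():
    case = lesion_phantom(70, vols=((20.0, "right"),))
    cfg = UNet3DConfig(depth=2, first_layer_filters=(2, 3), input_patch=36)
    model = build_unet3d(cfg, seed=0)
    bad = case.truth_lesions.copy()  # overlaps truth entirely
    with pytest.raises(ValueError, match="overlap"):
        train_stage2(model, [case], [bad], cfg,
                     TrainingConfig(epochs=1, learning_rate=1e-3))


# -- training contracts (tiny configs) --------------------------------------

TINY = UNet3DConfig(depth=2, first_layer_filters=(2, 3), input_patch=36)


def test_stage1_requires_lesions():
    case = lesion_phantom(71, vols=())
    with pytest.raises(ValueError, match="lesion"):
        train_stage1([case], TINY, TrainingConfig(epochs=1, learning_rate=1e-3))


def test_stage1_loss_history_length_and_determinism():
    case = lesion_phantom(72, vols=((20.0, "right"),))
    tc = TrainingConfig(epochs=2, learning_rate=1e-3, seed=9)
    a = train_stage1([case], TINY, tc)
    b = train_stage1([case], TINY, tc)
    assert len(a.loss_history) == 2  # one optimizer step per case per epoch
    assert a.loss_history == b.loss_history
    assert all(np.array_equal(x, y) for x, y in zip(a.net.weights, b.net.weights))


# -- prediction --------------------------------------------------------------

class _ConstantNet:
    """Stand-in network emitting a constant lesion probability."""

    def __init__(self, cfg, p):
        self.cfg = cfg.to_net_config()
        self.p = p

    def predict_proba(self, x):
        o = shape_trace(self.cfg.input_patch, self.cfg.depth)
        out = np.empty((2, o, o, o), np.float32)
        out[1] = self.p
        out[0] = 1.0 - self.p
        return out


def _constant_model(p):
    cfg = UNet3DConfig(depth=2, first_layer_filters=(2, 3), input_patch=36)
    model = build_unet3d(cfg, seed=0)
    model.net = _ConstantNet(cfg, p)
    return model


def test_constant_probability_above_threshold_marks_whole_brain():
    case = lesion_phantom(73, vols=())
    brain = extract_brain(case.ct, "morphological")
    norm = normalize_intensities(case.ct, brain)
    _, mask = predict_lesions(_constant_model(0.8), norm, brain)
    assert np.array_equal(mask, brain)
    _, mask = predict_lesions(_constant_model(0.5), norm, brain)
    assert not mask.any()  # 0.5 < default threshold 0.7


def test_tiling_covers_every_voxel_exactly_once():
    case = lesion_phantom(74, vols=())
    brain = extract_brain(case.ct, "morphological")
    norm = normalize_intensities(case.ct, brain)

    class CountingNet(_ConstantNet):
        def __init__(self, cfg):
            super().__init__(cfg, 0.9)
            self.calls = 0

        def predict_proba(self, x):
            self.calls += 1
            return super().predict_proba(x)

    cfg = UNet3DConfig(depth=2, first_layer_filters=(2, 3), input_patch=36)
    model = build_unet3d(cfg, seed=0)
    net = CountingNet(cfg)
    model.net = net
    prob, _ = predict_lesions(model, norm, brain)
    o = cfg.output_patch
    expected_tiles = int(np.prod([int(np.ceil(s / o)) for s in case.ct.shape]))
    assert net.calls == expected_tiles
    # every voxel received a prediction (constant 0.9 everywhere)
    assert np.all(prob == np.float32(0.9))


def test_threshold_monotonicity():
    case = lesion_phantom(75, vols=((25.0, "right"),))
    brain = extract_brain(case.ct, "morphological")
    norm = normalize_intensities(case.ct, brain)
    cfg = UNet3DConfig(depth=2, first_layer_filters=(2, 3), input_patch=36)
    model = build_unet3d(cfg, seed=3)  # untrained: arbitrary probabilities
    prob, _ = predict_lesions(model, norm, brain)
    lo = (prob >= 0.3) & brain
    hi = (prob >= 0.8) & brain
    assert not (hi & ~lo).any()  # higher threshold gives a subset


def test_model_save_load_roundtrip(tmp_path):
    cfg = UNet3DConfig(depth=2, first_layer_filters=(2, 3), input_patch=36)
    model = build_unet3d(cfg, seed=5)
    model.save(tmp_path / "lesion")
    loaded = LesionModel.load(tmp_path / "lesion")
    x = np.random.default_rng(0).normal(size=(1, 36, 36, 36)).astype(np.float32)
    assert np.allclose(model.net.predict_proba(x), loaded.net.predict_proba(x))
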