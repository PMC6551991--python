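"""Patch-based 3D U-Net segmentation of acute intracranial lesions with
two-stage false-lesion retraining.

Stage 1 trains lesion-versus-background on intensity-normalized,
skull-stripped volumes. Stage 2 computes each training case's false-lesion
mask (stage-1 prediction minus ground truth: venous sinus, falx edges and
other normal blood-containing structures) and retrains with that mask as an
additional class, warm-started from the stage-1 weights (only the new
false-lesion row of the final classifier starts fresh). At inference only
the lesion-class probability is thresholded (default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import Adam, UNet, UNetConfig, shape_trace, softmax_cross_entropy
from .preprocess import extract_brain, normalize_intensities
from .volume import CTVolume

__all__ = [
    "UNet3DConfig",
    "TrainingConfig",
    "LesionModelConfig",
    "LesionModel",
    "build_unet3d",
    "augment",
    "train_stage1",
    "compute_false_lesion_mask",
    "train_stage2",
    "predict_lesions",
    "shape_trace",
]


@dataclass
class UNet3DConfig:
    """Reference-scale defaults: four resolution levels, two valid 3x3x3
    convolutions per level with first-level filters (32, 64) doubling per
    level, 2x2x2 pooling/upsampling, 132^3 input patch -> 44^3 output patch.
    A reduced desk-scale configuration (depth 2, filters (8, 16), 60^3
    input) is used for CPU training."""

    depth: int = 4
    first_layer_filters: tuple[int, int] = (32, 64)
    input_patch: int = 132
    n_classes: int = 2

    def __post_init__(self) -> None:
        # validates the shape trace (raises naming the first failing level)
        shape_trace(self.input_patch, self.depth)

    @property
    def output_patch(self) -> int:
        return shape_trace(self.input_patch, self.depth)

    @property
    def offset(self) -> int:
        return self.input_patch - self.output_patch

    def to_net_config(self) -> UNetConfig:
        return UNetConfig(
            ndim=3, depth=self.depth, first_layer_filters=self.first_layer_filters,
            kernel=3, n_classes=self.n_classes, padding="valid",
            input_patch=self.input_patch,
        )


def reduced_config(n_classes: int = 2) -> UNet3DConfig:
    """The desk-scale training configuration (60^3 input, depth 2)."""
    return UNet3DConfig(depth=2, first_layer_filters=(8, 16), input_patch=60,
                        n_classes=n_classes)


@dataclass
class TrainingConfig:
    """Adam with categorical cross-entropy, batch size one. The learning
    rate default follows the reference protocol (1e-5); reduced desk-scale
    runs use a larger rate to converge within few steps. Augmentation:
    random flips, translations, rotations, Gaussian noise."""

    learning_rate: float = 1e-5
    decay: float = 0.0
    batch_size: int = 1
    epochs: int = 30
    seed: int = 0
    flip: bool = True
    translate: bool = False
    rotate: bool = False
    gaussian_noise: bool = True
    noise_sigma: float = 0.1
    max_translate_voxels: int = 10
    max_rotate_deg: float = 10.0
    lesion_centred_fraction: float = 0.7
    patches_per_epoch: int | None = None  # default: one per training case
    rare_class_bias: float = -3.0  # initial final-layer logit for non-background classes

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class LesionModelConfig:
    probability_threshold: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


class LesionModel:
    """A trained lesion segmentation network plus its training history."""

    def __init__(self, net: UNet, cfg: UNet3DConfig):
        self.net = net
        self.cfg = cfg
        self.loss_history: list[float] = []

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path) -> "LesionModel":
        net = UNet.load(path)
        cfg = UNet3DConfig(
            depth=net.cfg.depth, first_layer_filters=net.cfg.first_layer_filters,
            input_patch=net.cfg.input_patch, n_classes=net.cfg.n_classes,
        )
        return cls(net, cfg)


def build_unet3d(cfg: UNet3DConfig, seed: int = 0) -> LesionModel:
    """Instantiate the network (untrained, seeded He-normal weights)."""
    return LesionModel(UNet(cfg.to_net_config(), seed=seed), cfg)


def augment(image: np.ndarray, label: np.ndarray, cfg: TrainingConfig,
            rng: np.random.Generator):
    """Random augmentation: the same geometric transform is applied to image
    and label (nearest-neighbour for the label); noise goes to the image only.

    The patches must be congruent: either identical spatial shapes, or the
    label centred inside the image with one uniform margin per side (the
    valid-convolution patch layout)."""
    margins = {(i - l) for i, l in zip(image.shape, label.shape)}
    if len(margins) != 1 or min(margins) < 0 or any(m % 2 for m in margins):
        raise ValueError("image and label patches must be congruent")
    img, lab = image, label
    if cfg.flip:
        for ax in range(3):
            if rng.random() < 0.5:
                img = np.flip(img, axis=ax)
                lab = np.flip(lab, axis=ax)
    if cfg.translate:
        shift = rng.integers(-cfg.max_translate_voxels, cfg.max_translate_voxels + 1, size=3)
        if np.any(shift != 0):
            img = ndimage.shift(img, shift, order=1, mode="nearest")
            lab = ndimage.shift(lab, shift, order=0, mode="nearest")
    if cfg.rotate:
        angle = float(rng.uniform(-cfg.max_rotate_deg, cfg.max_rotate_deg))
        if abs(angle) > 1e-6:
            img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
            lab = ndimage.rotate(lab, angle, axes=(0, 1), reshape=False, order=0, mode="nearest")
    img = np.ascontiguousarray(img, dtype=np.float32)
    lab = np.ascontiguousarray(lab)
    if cfg.gaussian_noise:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape).astype(np.float32)
    return img, lab


def _prepare_case(case):
    """Normalized skull-stripped intensities + brain mask for one phantom case."""
    brain = extract_brain(case.ct, "morphological")
    norm = normalize_intensities(case.ct, brain)
    return norm.data.astype(np.float32), brain


def _sample_patch(x, labels, brain, cfg: UNet3DConfig, rng, lesion_centred: bool):
    """One (input, label) patch pair; input window is mirror-padded."""
    O = cfg.output_patch
    pad = cfg.offset // 2
    shape = x.shape
    if any(s < O for s in shape):
        raise ValueError(f"volume {shape} smaller than output patch {O}")
    if lesion_centred and (labels == 1).any():
        idx = np.argwhere(labels == 1)
        c = idx[rng.integers(0, len(idx))]
        start = [int(np.clip(c[i] - O // 2, 0, shape[i] - O)) for i in range(3)]
    else:
        start = [int(rng.integers(0, shape[i] - O + 1)) for i in range(3)]
    lab = labels[tuple(slice(s, s + O) for s in start)]
    xp = np.pad(x, pad, mode="reflect")
    img = xp[tuple(slice(s, s + O + 2 * pad) for s in start)]
    return img, lab


def _init_rare_class_bias(net: UNet, tcfg: TrainingConfig) -> None:
    """Start the non-background logits at a low value so the initial
    prediction matches the rarity of lesion voxels; stabilizes short
    training runs on heavily imbalanced patches."""
    bias = net.weights[-1]
    bias[1:] = tcfg.rare_class_bias


def _train(net: UNet, case_data, cfg: UNet3DConfig, tcfg: TrainingConfig):
    """Shared training loop. case_data: list of (x, labels, brain)."""
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(net.params, lr=tcfg.learning_rate, decay=tcfg.decay)
    n_per_epoch = tcfg.patches_per_epoch or len(case_data)
    history = []
    for _ in range(tcfg.epochs):
        order = rng.permutation(len(case_data))
        for j in range(n_per_epoch):
            x, labels, brain = case_data[order[j % len(case_data)]]
            centred = rng.random() < tcfg.lesion_centred_fraction
            img, lab = _sample_patch(x, labels, brain, cfg, rng, centred)
            img, lab = augment(img, lab, tcfg, rng)
            logits = net.forward(img[None], train=True)
            loss, dl, _ = softmax_cross_entropy(logits, lab.astype(np.int64))
            grads = net.backward(dl)
            opt.step(grads)
            history.append(loss)
    return history


def train_stage1(cases, net_cfg: UNet3DConfig, train_cfg: TrainingConfig) -> LesionModel:
    """Stage-1 training: lesion versus background (2 classes)."""
    if net_cfg.n_classes != 2:
        raise ValueError("stage 1 uses 2 classes")
    if not any(case.truth_lesions.any() for case in cases):
        raise ValueError("no lesion voxels in any training case")
    data = []
    for case in cases:
        x, brain = _prepare_case(case)
        labels = case.truth_lesions.astype(np.int64)
        data.append((x, labels, brain))
    model = build_unet3d(net_cfg, seed=train_cfg.seed)
    _init_rare_class_bias(model.net, train_cfg)
    model.loss_history = _train(model.net, data, net_cfg, train_cfg)
    return model


def compute_false_lesion_mask(stage1_seg: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """False-lesion mask: stage-1 prediction minus ground truth (voxelwise)."""
    stage1_seg = np.asarray(stage1_seg, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if stage1_seg.shape != truth.shape:
        raise ValueError("shape mismatch")
    return stage1_seg & ~truth


def train_stage2(model: LesionModel, cases, false_masks,
                 net_cfg: UNet3DConfig, train_cfg: TrainingConfig) -> LesionModel:
    """Stage-2 retraining with the false-lesion class.

    Warm-started from the stage-1 weights; the final 1x1x1 convolution is
    re-initialized for 3 classes. Labels: 0 background, 1 lesion, 2 false
    lesion. A false mask overlapping the ground truth is an error.
    """
    if len(cases) != len(false_masks):
        raise ValueError("cases and false_masks must pair up")
    data = []
    for case, fmask in zip(cases, false_masks):
        if (np.asarray(fmask, dtype=bool) & case.truth_lesions).any():
            raise ValueError("false-lesion mask overlaps ground-truth lesions")
        x, brain = _prepare_case(case)
        labels = np.zeros(case.ct.shape, dtype=np.int64)
        labels[np.asarray(fmask, dtype=bool)] = 2
        labels[case.truth_lesions] = 1
        data.append((x, labels, brain))
    cfg3 = UNet3DConfig(
        depth=net_cfg.depth, first_layer_filters=net_cfg.first_layer_filters,
        input_patch=net_cfg.input_patch, n_classes=3,
    )
    stage2 = build_unet3d(cfg3, seed=train_cfg.seed + 1)
    # warm start: copy all weights; the final layer keeps the trained
    # background/lesion rows and only the new false-lesion row starts fresh
    for i in range(len(model.net.weights) - 2):
        stage2.net.weights[i] = model.net.weights[i].copy()
    w1, b1 = model.net.weights[-2], model.net.weights[-1]
    stage2.net.weights[-2][:2] = w1
    stage2.net.weights[-1][:2] = b1
    stage2.net.weights[-1][2] = train_cfg.rare_class_bias
    stage2.loss_history = _train(stage2.net, data, cfg3, train_cfg)
    return stage2


def predict_lesions(model: LesionModel, ct_norm: CTVolume, brain: np.ndarray,
                    cfg: LesionModelConfig | None = None):
    """Lesion probability volume and thresholded mask.

    The volume is tiled with non-overlapping output patches (stride = output
    size; mirror padding supplies the surrounding context and fills the grid
    to a whole number of tiles), so every brain voxel is predicted exactly
    once. Only the lesion-class probability (class 1) is thresholded.
    """
    cfg = cfg or LesionModelConfig()
    net_cfg = model.cfg
    O = net_cfg.output_patch
    pad = net_cfg.offset // 2
    x = np.asarray(ct_norm.data, dtype=np.float32)
    shape = x.shape
    tiles = [int(np.ceil(s / O)) for s in shape]
    full = [t * O for t in tiles]
    pad_spec = [(pad, pad + full[i] - shape[i]) for i in range(3)]
    if any(p[1] >= shape[i] + pad for i, p in enumerate(pad_spec)):
        raise ValueError("volume too small for the tiling configuration")
    xp = np.pad(x, pad_spec, mode="reflect")
    prob = np.zeros(full, dtype=np.float32)
    for i in range(tiles[0]):
        for j in range(tiles[1]):
            for k in range(tiles[2]):
                start = (i * O, j * O, k * O)
                win = tuple(slice(s, s + O + 2 * pad) for s in start)
                p = model.net.predict_proba(xp[win][None])
                out = tuple(slice(s, s + O) for s in start)
                prob[out] = p[1]
    prob = prob[: shape[0], : shape[1], : shape[2]]
    mask = (prob >= cfg.probability_threshold) & brain
    return prob, mask
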