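"""Brain extraction, intensity normalization, and isotropic resampling.

Two brain extractors are provided: a deterministic morphological one
(Hounsfield window, binary opening, largest connected component, hole fill)
used as the reference method, and an optional slice-wise 2D U-Net trained on
phantom cases. The U-Net mirrors the classic 2D design: per level two 3x3
convolutions with ReLU, 2x max pooling / upsampling, optimized with Adadelta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import Adadelta, UNet, UNetConfig, softmax_cross_entropy
from .volume import CTVolume

__all__ = [
    "BrainExtractorConfig",
    "BrainExtractor2D",
    "extract_brain",
    "train_brain_extractor",
    "normalize_intensities",
    "resample_to_isotropic",
]

# HU window bounding plausible brain parenchyma + CSF + acute blood
_BRAIN_HU_LO = -20.0
_BRAIN_HU_HI = 100.0
_SKULL_HU = 100.0
_AIR_HU = -200.0


class NoBrainFoundError(ValueError):
    """Raised when a volume contains no voxels compatible with brain tissue."""


def morphological_brain_mask(ct: CTVolume) -> np.ndarray:
    """Threshold-and-morphology brain extraction.

    HU window [-20, 100], binary opening (1-voxel ball), largest connected
    component, 3D hole fill. Holes (ventricles, hyperdense lesions inside the
    cranial cavity) are filled back into the mask.
    """
    window = (ct.data >= _BRAIN_HU_LO) & (ct.data <= _BRAIN_HU_HI)
    if not window.any():
        raise NoBrainFoundError("no voxels in brain HU range")
    opened = ndimage.binary_opening(window, structure=ndimage.generate_binary_structure(3, 1))
    labels, n = ndimage.label(opened)
    if n == 0:
        raise NoBrainFoundError("no brain-like component after opening")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    # never keep skull or air voxels, whatever the morphology did
    mask &= (ct.data < _SKULL_HU + 200.0) & (ct.data > _AIR_HU)
    return mask


@dataclass
class BrainExtractorConfig:
    """2D U-Net brain-extractor hyperparameters.

    Defaults follow the classic 2D architecture (five resolution levels,
    first-level filters 64 doubling per level, 3x3 kernels, Adadelta);
    reduced settings are used for CPU-scale training.
    """

    depth: int = 5
    base_filters: int = 64
    kernel: int = 3
    epochs: int = 5
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")


def _slice_features(data: np.ndarray) -> np.ndarray:
    """Standardized network input from a HU volume (soft-tissue window)."""
    x = np.clip(data, -100.0, 200.0)
    return ((x - x.mean()) / (x.std() + 1e-6)).astype(np.float32)


class BrainExtractor2D:
    """Slice-wise 2D U-Net brain extractor (same-padding, softmax over 2 classes)."""

    def __init__(self, cfg: BrainExtractorConfig):
        self.cfg = cfg
        net_cfg = UNetConfig(
            ndim=2,
            depth=cfg.depth,
            first_layer_filters=(cfg.base_filters, cfg.base_filters),
            kernel=cfg.kernel,
            n_classes=2,
            padding="same",
            input_patch=0,
        )
        self.net = UNet(net_cfg, seed=cfg.seed)
        self.loss_history: list[float] = []

    def fit(self, cases) -> "BrainExtractor2D":
        """Train on axial slice / brain-mask pairs from phantom cases."""
        if not cases:
            raise ValueError("empty case list")
        rng = np.random.default_rng(self.cfg.seed)
        opt = Adadelta(self.net.params)
        pairs = []
        for case in cases:
            feats = _slice_features(case.ct.data)
            for z in range(case.ct.shape[2]):
                pairs.append((feats[:, :, z], case.truth_brain[:, :, z].astype(np.int64)))
        for _ in range(self.cfg.epochs):
            order = rng.permutation(len(pairs))
            losses = []
            for j in order:
                img, lab = pairs[j]
                logits = self.net.forward(img[None], train=True)
                loss, dl, _ = softmax_cross_entropy(logits, lab)
                grads = self.net.backward(dl)
                opt.step(grads)
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
        return self

    def predict(self, ct: CTVolume) -> np.ndarray:
        feats = _slice_features(ct.data)
        out = np.zeros(ct.shape, dtype=bool)
        for z in range(ct.shape[2]):
            p = self.net.predict_proba(feats[:, :, z][None])
            out[:, :, z] = p[1] >= 0.5
        return out


def train_brain_extractor(cases, cfg: BrainExtractorConfig) -> BrainExtractor2D:
    """Train a slice-wise 2D U-Net extractor; deterministic for a fixed seed."""
    return BrainExtractor2D(cfg).fit(cases)


def extract_brain(ct: CTVolume, method: str = "morphological",
                  model: BrainExtractor2D | None = None) -> np.ndarray:
    """Binary brain mask: largest component, excludes skull and background air."""
    if method == "morphological":
        mask = morphological_brain_mask(ct)
    elif method == "unet2d":
        if model is None:
            raise ValueError("method='unet2d' requires a trained model")
        raw = model.predict(ct)
        raw &= (ct.data > _AIR_HU) & (ct.data < _SKULL_HU)
        if not raw.any():
            raise NoBrainFoundError("extractor produced an empty mask")
        labels, n = ndimage.label(raw)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = ndimage.binary_fill_holes(labels == int(np.argmax(sizes)) + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not mask.any():
        raise NoBrainFoundError("empty brain mask")
    return mask


def normalize_intensities(ct: CTVolume, mask: np.ndarray) -> CTVolume:
    """Zero-mean unit-variance intensities inside the mask, zero outside."""
    if not mask.any():
        raise ValueError("mask is empty")
    vals = ct.data[mask]
    sd = vals.std()
    if sd < 1e-8:
        raise ValueError("zero intensity variance inside mask")
    out = np.zeros(ct.shape, dtype=np.float32)
    out[mask] = (vals - vals.mean()) / sd
    return ct.like(out)


def resample_to_isotropic(ct: CTVolume, target_spacing: float = 1.0,
                          is_mask: bool = False) -> CTVolume:
    """Resample to isotropic spacing (trilinear; nearest-neighbour for masks)."""
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    factors = [s / target_spacing for s in ct.spacing]
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return ct
    order = 0 if is_mask else 1
    data = ndimage.zoom(np.asarray(ct.data, dtype=np.float32), factors, order=order,
                        mode="nearest", grid_mode=True)
    new_affine = ct.affine.copy()
    for i in range(3):
        scale = target_spacing / ct.spacing[i]
        new_affine[:3, i] *= scale
    return CTVolume(data=data, spacing=(target_spacing,) * 3, affine=new_affine)
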