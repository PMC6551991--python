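"""Final basal-cistern segmentation from located candidates.

The located cistern candidates are refined by the morphological sequence:
constrained dilation (accepted only where the CSF posterior is high),
smoothing (morphological closing followed by Gaussian smoothing of the
indicator and re-thresholding), and imposing non-overlap against the
ventricle mask at the cistern border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import mask_volume_ml

__all__ = ["CisternConfig", "CisternMask", "segment_cisterns", "cistern_volume"]


@dataclass
class CisternConfig:
    """Morphology parameters: CSF-posterior acceptance threshold for the
    constrained dilation, number of dilation iterations, and the Gaussian
    smoothing width (voxels) applied to the mask indicator."""

    p_csf: float = 0.5
    dilation_iters: int = 3
    smoothing_sigma: float = 1.0


@dataclass
class CisternMask:
    mask: np.ndarray
    volume_ml: float


def segment_cisterns(candidates: np.ndarray, csf_posterior: np.ndarray,
                     brain: np.ndarray, spacing,
                     cfg: CisternConfig | None = None,
                     ventricles: np.ndarray | None = None) -> CisternMask:
    """Refine cistern candidates into the final segmentation.

    Empty candidates yield an empty mask (volume 0) without error — the
    clinical reading of obliterated cisterns. The output never overlaps the
    ventricle mask and stays inside the brain mask.
    """
    cfg = cfg or CisternConfig()
    cand = candidates & brain
    if not cand.any():
        return CisternMask(mask=np.zeros_like(cand), volume_ml=0.0)

    mask = cand.copy()
    accept = (csf_posterior >= cfg.p_csf) & brain
    for _ in range(cfg.dilation_iters):
        grown = ndimage.binary_dilation(mask) & accept
        mask |= grown

    mask = ndimage.binary_closing(mask)
    if cfg.smoothing_sigma > 0:
        ind = ndimage.gaussian_filter(mask.astype(np.float32), cfg.smoothing_sigma)
        mask = ind >= 0.5
    mask &= brain
    if ventricles is not None:
        mask &= ~ventricles
    return CisternMask(mask=mask, volume_ml=mask_volume_ml(mask, spacing))


def cistern_volume(mask: np.ndarray | CisternMask, spacing) -> float:
    """Cistern volume in mL (voxel count times voxel volume)."""
    if isinstance(mask, CisternMask):
        mask = mask.mask
    return mask_volume_ml(mask, spacing)
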