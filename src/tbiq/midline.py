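"""Geometric midline-shift (MLS) estimation.

On each axial slice between the foramen-of-Monro plane and the roof of the
lateral ventricles, the shift is |B/2 - C| where B is the maximal left-right
inner-skull width on the slice and C is the distance from the inner table to
the midpoint of the frontal part of the ventricles, both measured along the
same left-right line (C starts on the side opposite the shift, matching the
manual measurement protocol). The patient-level MLS is the maximum over the
slice range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .atlas_tissue import AffineTransform
from .phantom import AtlasBundle
from .volume import CTVolume

__all__ = [
    "SliceShiftMeasurement",
    "MidlineShiftResult",
    "slice_range",
    "measure_slice_shift",
    "estimate_mls",
]


@dataclass
class SliceShiftMeasurement:
    """One axial slice's measurement: inner-skull width B, skull-to-ventricle
    distance C (shared starting x), and the resulting shift |B/2 - C|."""

    z_index: int
    B_bar: float
    C_bar: float
    shift: float
    start_x: float
    measurable: bool = True

    def __post_init__(self) -> None:
        if self.measurable:
            if self.B_bar <= 0:
                raise ValueError("B_bar must be positive")
            if not (0.0 <= self.C_bar <= self.B_bar):
                raise ValueError("C_bar must lie within [0, B_bar]")
            if self.shift < 0:
                raise ValueError("shift must be >= 0")


@dataclass
class MidlineShiftResult:
    per_slice: list
    mls: float
    argmax_z: int

    def to_json(self) -> dict:
        return {
            "mls_mm": self.mls,
            "argmax_z": int(self.argmax_z),
            "per_slice": [
                {"z": m.z_index, "B_bar": m.B_bar, "C_bar": m.C_bar, "shift": m.shift}
                for m in self.per_slice
            ],
        }


def slice_range(t: AffineTransform, atlas: AtlasBundle, subject_grid: CTVolume):
    """Subject-space axial index range between the atlas landmark planes.

    The atlas planes (foramen of Monro, roof of the lateral ventricles) are
    mapped through the inverse transform into subject voxel indices.
    """
    zs = []
    for z_atlas in (atlas.landmark_z_monro, atlas.landmark_z_roof):
        # a point on the atlas plane (plane centre) -> world -> subject voxel
        centre_idx = np.array([
            (atlas.template.shape[0] - 1) / 2.0,
            (atlas.template.shape[1] - 1) / 2.0,
            float(z_atlas),
        ])
        world_atlas = atlas.template.voxel_to_world(centre_idx)
        world_subj = (np.linalg.inv(t.matrix) @ np.append(world_atlas, 1.0))[:3]
        zs.append(subject_grid.world_to_voxel(world_subj)[2])
    z_lo, z_hi = zs
    if z_lo >= z_hi:
        raise ValueError("landmark planes out of order after mapping to subject space")
    lo = int(np.ceil(z_lo - 1e-6))
    hi = int(np.floor(z_hi + 1e-6))
    lo = max(lo, 0)
    hi = min(hi, subject_grid.shape[2] - 1)
    if hi < lo:
        raise ValueError("landmark slice range collapsed to < 1 slice")
    return lo, hi


def _frontal_midpoint(vent_slice: np.ndarray):
    """Midpoint of the frontal (anterior) part of the ventricles on a slice.

    The anterior third of the ventricle pixels (by y extent) is split into
    connected components; with two or more, the midpoint of the two largest
    components' centroids is used, otherwise the centroid of the single
    component. Returns (x, y) in voxel coordinates (floats).
    """
    xs, ys = np.nonzero(vent_slice)
    y_lo, y_hi = ys.min(), ys.max()
    y_cut = y_hi - max(1.0, (y_hi - y_lo) / 3.0)
    frontal = vent_slice.copy()
    frontal[:, : int(np.ceil(y_cut))] = False
    if not frontal.any():
        frontal = vent_slice
    labels, n = ndimage.label(frontal)
    if n >= 2:
        sizes = np.bincount(labels.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        # bilateral only if the second component is a genuine horn, not a speck
        if sizes[order[1]] >= max(3, 0.25 * sizes[order[0]]):
            c1 = ndimage.center_of_mass(labels == order[0] + 1)
            c2 = ndimage.center_of_mass(labels == order[1] + 1)
            return (0.5 * (c1[0] + c2[0]), 0.5 * (c1[1] + c2[1]))
        frontal = labels == order[0] + 1
    return ndimage.center_of_mass(frontal)


def measure_slice_shift(skull_inner: np.ndarray, ventricles: np.ndarray,
                        z: int, spacing) -> SliceShiftMeasurement:
    """Measure B, C and the shift |B/2 - C| on one axial slice.

    `skull_inner` and `ventricles` are 2D (x, y) binary slices; distances in
    mm via the in-plane spacing. An empty ventricle slice yields a sentinel
    non-measurable result.
    """
    sx = float(spacing[0])
    if not skull_inner.any():
        raise ValueError("empty inner-skull slice")
    if not ventricles.any():
        return SliceShiftMeasurement(z, 0.0, 0.0, 0.0, 0.0, measurable=False)

    mx, my = _frontal_midpoint(ventricles)
    row = int(round(my))
    row = min(max(row, 0), skull_inner.shape[1] - 1)
    cols = np.nonzero(skull_inner[:, row])[0]
    if cols.size == 0:
        return SliceShiftMeasurement(z, 0.0, 0.0, 0.0, 0.0, measurable=False)
    # inner-table edges at the row of the ventricle midpoint
    x_left = (cols.min() - 0.5) * sx
    x_right = (cols.max() + 0.5) * sx
    B = x_right - x_left
    x_mid = mx * sx
    centre = 0.5 * (x_left + x_right)
    # C starts at the inner table on the side opposite the shift
    if x_mid >= centre:
        start = x_left
        C = x_mid - start
    else:
        start = x_right
        C = start - x_mid
    C = min(max(C, 0.0), B)
    shift = abs(B / 2.0 - C)
    return SliceShiftMeasurement(z, B, C, shift, start)


def estimate_mls(ventricle_mask: np.ndarray, brain: np.ndarray,
                 skull_inner: np.ndarray | None, t: AffineTransform,
                 atlas: AtlasBundle, grid: CTVolume) -> MidlineShiftResult:
    """Patient-level midline shift: maximum per-slice shift in the landmark range.

    `skull_inner` defaults to the brain mask (its boundary is the inner
    table). Ties on the maximum break toward the most inferior slice.
    """
    if skull_inner is None:
        skull_inner = brain
    lo, hi = slice_range(t, atlas, grid)
    # restrict to slices where the ventricles are well visualized: thin
    # end-cap cross-sections give unreliable bilateral midpoints
    areas = {z: int(ventricle_mask[:, :, z].sum()) for z in range(lo, hi + 1)}
    max_area = max(areas.values(), default=0)
    per_slice = []
    for z in range(lo, hi + 1):
        sk = skull_inner[:, :, z]
        vent = ventricle_mask[:, :, z]
        if not sk.any() or not vent.any():
            continue
        if areas[z] < 0.5 * max_area:
            continue
        m = measure_slice_shift(sk, vent, z, grid.spacing)
        if m.measurable:
            per_slice.append(m)
    if not per_slice:
        raise ValueError("no measurable slice in the landmark range "
                         "(ventricles effaced on all slices)")
    best = max(per_slice, key=lambda m: (m.shift, -m.z_index))
    return MidlineShiftResult(per_slice=per_slice, mls=best.shift, argmax_z=best.z_index)
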