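"""Synthetic head-CT phantoms with exact ground truth.

The phantom emulates a non-contrast head CT of an acute TBI patient at the
level of detail the downstream pipeline needs: an ellipsoidal skull shell
(~1000 HU), cortical grey matter over white matter, CSF-filled lateral
ventricles with frontal horns, basal cisterns forming an annulus around a
brainstem cylinder, hyperdense lesions of configurable volume, an optional
thin hyperdense parasagittal sheet emulating the falx cerebri (a "false
lesion" decoy), additive Gaussian noise, and a configurable rigid lateral
displacement of the ventricular system producing a known midline shift.

All geometry is generated in world millimetres on a grid whose centre is the
world origin, so a zero-shift phantom is mirror-symmetric about the
mid-sagittal plane (use an odd x dimension for exact voxel-level symmetry).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .volume import CTVolume, centered_affine, mask_volume_ml, save_mask, save_volume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_atlas",
    "generate_cohort",
]

# Fractions of the half-extent of the grid used for the outer skull ellipsoid;
# keeps the head inside arbitrary grids while preserving proportions.
_SKULL_FRACTION = 0.45
_SKULL_THICKNESS_MM = 6.0
_GM_RIM_MM = 10.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head-CT case.

    HU means follow typical non-contrast CT: skull ~1000, GM 35-45, WM 25-35,
    CSF 0-15, acute blood 50-90. ``induced_shift`` displaces the ventricular
    system laterally (+x = subject right) by that many mm; the resulting true
    midline shift equals its magnitude. ``lesion_volumes`` are (volume_ml,
    location) pairs, location one of 'left', 'right', 'frontal', 'posterior'.
    """

    grid_shape: tuple[int, int, int] = (113, 127, 72)
    spacing: tuple[float, float, float] = (1.5, 1.5, 2.0)
    skull_hu: float = 1000.0
    gm_hu: float = 42.0
    wm_hu: float = 30.0
    csf_hu: float = 8.0
    lesion_hu: float = 70.0
    air_hu: float = -1000.0
    noise_sigma: float = 8.0
    induced_shift: float = 0.0
    lesion_volumes: tuple = ()
    cistern_volume: float = 8.0
    decoy_falx: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if abs(self.induced_shift) > 20.0:
            raise ValueError("induced_shift must be within +/-20 mm")
        lv = []
        for item in self.lesion_volumes:
            if np.isscalar(item):
                item = (float(item), "right")
            ml, loc = item
            if ml < 0:
                raise ValueError("lesion volumes must be >= 0")
            lv.append((float(ml), str(loc)))
        self.lesion_volumes = tuple(lv)
        if self.cistern_volume < 0:
            raise ValueError("cistern_volume must be >= 0")

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class PhantomCase:
    """A generated phantom: the CT plus exact truth masks."""

    ct: CTVolume
    truth_brain: np.ndarray
    truth_gm: np.ndarray
    truth_wm: np.ndarray
    truth_csf: np.ndarray
    truth_ventricles: np.ndarray
    truth_cisterns: np.ndarray
    truth_lesions: np.ndarray
    truth_falx: np.ndarray
    truth_mls: float
    spec: PhantomSpec

    def lesion_volume_ml(self) -> float:
        return mask_volume_ml(self.truth_lesions, self.ct.spacing)

    def cistern_volume_ml(self) -> float:
        return mask_volume_ml(self.truth_cisterns, self.ct.spacing)

    def save(self, outdir: str | Path, stem: str = "case") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_volume(self.ct, outdir / f"{stem}_ct.nii.gz")
        for name in ("brain", "gm", "wm", "csf", "ventricles", "cisterns", "lesions"):
            save_mask(getattr(self, f"truth_{name}"), self.ct, outdir / f"{stem}_{name}.nii.gz")
        sidecar = {"spec": self.spec.to_json(), "truth_mls": self.truth_mls}
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def _world_grid(shape, spacing):
    aff = centered_affine(shape, spacing)
    axes = [aff[i, i] * np.arange(shape[i]) + aff[i, 3] for i in range(3)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(xw, yw, zw, center, semi):
    return (
        ((xw - center[0]) / semi[0]) ** 2
        + ((yw - center[1]) / semi[1]) ** 2
        + ((zw - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _head_shape(xw, yw, zw, semi, taper=0.1):
    """Egg-shaped cranium: narrower frontally (anterior taper), as in real
    skulls. The taper makes the shape non-quadric, so a rotated head cannot
    be reproduced by a pure strain — affine registration stays well posed."""
    y_n = np.clip(yw / semi[1], -1.0, 1.0)
    sc = 1.0 - taper * y_n
    return (
        (xw / (semi[0] * sc)) ** 2
        + (yw / semi[1]) ** 2
        + (zw / (semi[2] * sc)) ** 2
    ) <= 1.0


def _head_semi_axes(shape, spacing):
    half_extent = [shape[i] * spacing[i] / 2.0 for i in range(3)]
    return tuple(2 * _SKULL_FRACTION * h for h in half_extent)


def _ventricle_mask(xw, yw, zw, shift, scale):
    """Paired lateral ventricles (body + frontal horn), displaced by `shift` mm."""
    m = np.zeros(np.broadcast_shapes(xw.shape, yw.shape, zw.shape), dtype=bool)
    for side in (-1.0, 1.0):
        body = _ellipsoid(
            xw, yw, zw,
            (side * 10.0 * scale + shift, -12.0 * scale, 2.0 * scale),
            (5.5 * scale, 24.0 * scale, 12.0 * scale),
        )
        horn = _ellipsoid(
            xw, yw, zw,
            (side * 7.0 * scale + shift, 20.0 * scale, 2.0 * scale),
            (4.5 * scale, 14.0 * scale, 9.0 * scale),
        )
        m |= body | horn
    return m


def _fit_radius(target_ml, allowed, dist2, voxel_ml, tol_frac=0.02, r_max=80.0):
    """Binary-search a radius so that the voxelized region hits a target volume.

    `dist2` is the squared 'radius' field of the shape (mm^2); the region is
    dist2 <= r^2 restricted to `allowed`.
    """
    if target_ml <= 0:
        return np.zeros_like(allowed), 0.0
    lo, hi = 0.0, r_max
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m = allowed & (dist2 <= mid * mid)
        v = np.count_nonzero(m) * voxel_ml
        best = (m, v)
        if abs(v - target_ml) <= tol_frac * target_ml:
            break
        if v < target_ml:
            lo = mid
        else:
            hi = mid
    m, v = best
    if abs(v - target_ml) > 0.05 * max(target_ml, 1e-9):
        raise ValueError(
            f"requested volume {target_ml:.1f} mL cannot be fit inside the "
            f"available cavity (achieved {v:.1f} mL)"
        )
    return m, v


_LESION_CENTRES = {
    "right": (0.55, 0.05, 0.15),
    "left": (-0.55, 0.05, 0.15),
    "frontal": (0.25, 0.55, 0.15),
    "posterior": (-0.25, -0.55, 0.15),
}


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case from a spec; bit-identical for equal specs."""
    shape, spacing = spec.grid_shape, spec.spacing
    rng = np.random.default_rng(spec.seed)
    xw, yw, zw = _world_grid(shape, spacing)
    voxel_ml = float(np.prod(spacing)) / 1000.0

    semi_out = _head_semi_axes(shape, spacing)
    semi_in = tuple(s - _SKULL_THICKNESS_MM for s in semi_out)
    # scale anatomical mm constants relative to the reference inner x-semi-axis
    scale = semi_in[0] / 70.0

    outer = _head_shape(xw, yw, zw, semi_out)
    brain = _head_shape(xw, yw, zw, semi_in)
    skull = outer & ~brain
    gm = brain & ~_head_shape(xw, yw, zw, tuple(s - _GM_RIM_MM for s in semi_in))

    shift = float(spec.induced_shift)
    ventricles = _ventricle_mask(xw, yw, zw, shift, scale) & brain

    # basal cisterns: annulus around a brainstem cylinder near the skull base
    z0 = -0.72 * semi_in[2]
    z1 = z0 + 26.0 * scale
    stem_r = 11.0 * scale
    in_slab = (zw >= z0) & (zw <= z1) & brain
    r2 = (xw - 0.0) ** 2 + (yw + 8.0 * scale) ** 2 + 0.0 * zw
    allowed = in_slab & (r2 > stem_r**2)
    cisterns, _ = _fit_radius(spec.cistern_volume, allowed, r2, voxel_ml)
    if spec.cistern_volume > 0:
        cisterns &= ~ventricles

    csf = ventricles | cisterns

    # hyperdense lesions
    lesions = np.zeros(shape, dtype=bool)
    lesion_allowed = brain & ~csf
    for ml, loc in spec.lesion_volumes:
        if ml == 0:
            continue
        frac = _LESION_CENTRES.get(loc, _LESION_CENTRES["right"])
        c = tuple(frac[i] * semi_in[i] for i in range(3))
        d2 = (xw - c[0]) ** 2 + (yw - c[1]) ** 2 + (zw - c[2]) ** 2
        m, _ = _fit_radius(ml, lesion_allowed & ~lesions, d2, voxel_ml, tol_frac=0.01)
        lesions |= m

    falx = np.zeros(shape, dtype=bool)
    if spec.decoy_falx:
        # 1-voxel-thick parasagittal sheet at the true midline (x = 0)
        ix = int(np.argmin(np.abs(xw.ravel())))
        falx[ix, :, :] = True
        falx &= brain & (zw + 0 * xw + 0 * yw > 0) & (np.abs(yw + 0 * xw + 0 * zw) < 0.6 * semi_in[1])
        falx &= ~(csf | lesions)

    gm = gm & ~(csf | lesions | falx)
    wm = brain & ~(gm | csf | lesions | falx)

    labels = np.full(shape, spec.air_hu, dtype=np.float32)
    labels[skull] = spec.skull_hu
    labels[wm] = spec.wm_hu
    labels[gm] = spec.gm_hu
    labels[csf] = spec.csf_hu
    labels[lesions] = spec.lesion_hu
    labels[falx] = 60.0

    data = labels
    if spec.noise_sigma > 0:
        data = labels + rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)

    ct = CTVolume(data=data, spacing=spacing)
    return PhantomCase(
        ct=ct,
        truth_brain=brain,
        truth_gm=gm,
        truth_wm=wm,
        truth_csf=csf,
        truth_ventricles=ventricles,
        truth_cisterns=cisterns,
        truth_lesions=lesions,
        truth_falx=falx,
        truth_mls=abs(shift),
        spec=spec,
    )


@dataclass
class AtlasBundle:
    """Template volume, tissue probability priors, binary structure priors and
    the two axial landmark planes bounding the midline-shift slice range."""

    template: CTVolume
    prior_gm: np.ndarray
    prior_wm: np.ndarray
    prior_csf: np.ndarray
    prior_ventricles: np.ndarray
    prior_cisterns: np.ndarray
    landmark_z_monro: int
    landmark_z_roof: int
    brain_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.landmark_z_monro >= self.landmark_z_roof:
            raise ValueError("landmark planes out of order (monro must be inferior to roof)")

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_volume(self.template, outdir / "template.nii.gz")
        for name in ("prior_gm", "prior_wm", "prior_csf"):
            save_volume(self.template.like(getattr(self, name)), outdir / f"{name}.nii.gz")
        for name in ("prior_ventricles", "prior_cisterns", "brain_mask"):
            save_mask(getattr(self, name), self.template, outdir / f"{name}.nii.gz")
        manifest = {
            "landmark_z_monro": int(self.landmark_z_monro),
            "landmark_z_roof": int(self.landmark_z_roof),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, indir: str | Path) -> "AtlasBundle":
        from .volume import load_mask, load_volume

        indir = Path(indir)
        manifest = json.loads((indir / "manifest.json").read_text())
        return cls(
            template=load_volume(indir / "template.nii.gz"),
            prior_gm=load_volume(indir / "prior_gm.nii.gz").data,
            prior_wm=load_volume(indir / "prior_wm.nii.gz").data,
            prior_csf=load_volume(indir / "prior_csf.nii.gz").data,
            prior_ventricles=load_mask(indir / "prior_ventricles.nii.gz"),
            prior_cisterns=load_mask(indir / "prior_cisterns.nii.gz"),
            landmark_z_monro=manifest["landmark_z_monro"],
            landmark_z_roof=manifest["landmark_z_roof"],
            brain_mask=load_mask(indir / "brain_mask.nii.gz"),
        )


def generate_atlas(spec: PhantomSpec, n_subjects: int = 5, seed: int = 0,
                   prior_smooth_mm: float = 3.0) -> AtlasBundle:
    """Build a synthetic atlas as the voxelwise average of unshifted phantoms.

    The template is the mean CT; tissue priors are voxelwise class
    frequencies (summing to 1 inside the brain), smoothed by
    `prior_smooth_mm` to emulate the soft boundaries of a population atlas;
    binary structure priors are majority votes; the landmark planes are read
    off the ventricle truth extent (foramen-of-Monro level at the ventricle
    floor, roof of the lateral ventricles at the top).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    templates = []
    counts = {k: 0.0 for k in ("gm", "wm", "csf", "ventricles", "cisterns", "brain")}
    for _ in range(n_subjects):
        sub_spec = PhantomSpec(**{**spec.to_json(), "induced_shift": 0.0,
                                  "seed": int(rng.integers(0, 2**31 - 1))})
        case = generate_phantom(sub_spec)
        templates.append(case.ct.data.astype(np.float64))
        for k in counts:
            counts[k] = counts[k] + getattr(case, f"truth_{k}").astype(np.float64)
    template = CTVolume(
        data=(np.mean(templates, axis=0)).astype(np.float32),
        spacing=spec.spacing,
    )
    brain_freq = counts["brain"] / n_subjects
    brain = brain_freq >= 0.5
    # class frequencies; normalize to sum to 1 inside the brain mask
    gm = counts["gm"] / n_subjects
    wm = counts["wm"] / n_subjects
    csf = counts["csf"] / n_subjects
    if prior_smooth_mm > 0:
        from scipy.ndimage import gaussian_filter

        sig = [prior_smooth_mm / sp for sp in spec.spacing]
        gm, wm, csf = (gaussian_filter(a, sig) for a in (gm, wm, csf))
    total = gm + wm + csf
    inside = brain & (total > 0)
    for arr in (gm, wm, csf):
        arr[inside] /= total[inside]
        arr[~inside] = 0.0
    # voxels inside brain with no tissue vote (lesion/falx sites): fall back to WM
    hole = brain & ~inside
    wm[hole] = 1.0

    vent = counts["ventricles"] / n_subjects >= 0.5
    cist = counts["cisterns"] / n_subjects >= 0.5
    zs = np.where(vent.any(axis=(0, 1)))[0]
    if zs.size < 2:
        raise ValueError("ventricle prior empty; cannot derive landmark planes")
    return AtlasBundle(
        template=template,
        prior_gm=gm.astype(np.float32),
        prior_wm=wm.astype(np.float32),
        prior_csf=csf.astype(np.float32),
        prior_ventricles=vent,
        prior_cisterns=cist,
        landmark_z_monro=int(zs.min()),
        landmark_z_roof=int(zs.max()),
        brain_mask=brain,
    )


def generate_cohort(n: int, ranges: dict, seed: int = 0, base: PhantomSpec | None = None):
    """Sample `n` phantom cases with spec fields drawn uniformly from ranges.

    `ranges` maps PhantomSpec field names to (lo, hi) tuples; `lesion_volume`
    (singular) may be given as a range for a single lesion whose side
    alternates. Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not ranges:
        raise ValueError("empty ranges")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        kw = base.to_json()
        for key, (lo, hi) in ranges.items():
            if lo > hi:
                raise ValueError(f"empty range for {key}")
            val = float(rng.uniform(lo, hi))
            if key == "lesion_volume":
                kw["lesion_volumes"] = ((val, "right" if i % 2 == 0 else "left"),)
            else:
                kw[key] = val
        kw["seed"] = int(rng.integers(0, 2**31 - 1))
        cases.append(generate_phantom(PhantomSpec(**kw)))
    return cases
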