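"""Affine registration to the atlas, EM tissue segmentation with atlas
priors, and localisation of ventricles/cisterns via binary priors.

Registration is affine-only (12 dof), driven by a multi-resolution
similarity optimization via SimpleITK (mean squares by default for
same-modality CT; mutual information available). The tissue model
is a three-class Gaussian mixture (CSF, GM, WM) whose voxelwise mixing
proportions are the warped atlas priors; it is fitted by
expectation-maximization on the normalized, skull-stripped intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .phantom import AtlasBundle
from .volume import CTVolume

__all__ = [
    "AffineTransform",
    "RegistrationConfig",
    "EMConfig",
    "TissueSegmentation",
    "register_affine",
    "warp_to_subject",
    "segment_tissues_em",
    "build_em_priors",
    "locate_structures",
    "CLASS_NAMES",
]

CLASS_NAMES = ("csf", "gm", "wm")  # argmax ties break to the lowest index


@dataclass
class AffineTransform:
    """A 4x4 world-coordinate affine mapping subject -> atlas."""

    matrix: np.ndarray
    flag_identity_fallback: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("matrix must be invertible")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def save(self, path) -> None:
        np.savetxt(path, self.matrix)

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(path))


@dataclass
class RegistrationConfig:
    """Affine registration settings.

    `metric` is 'mean_squares' (same-modality CT-to-CT template alignment)
    or 'mattes' (mutual information). `multi_start_deg` adds initial
    rotations (+/- about each axis per entry) to the identity start; all
    starts are optimized and the densely-evaluated best is kept.
    `restarts` re-runs the optimizer from the incumbent with a reset step
    size while that improves the dense metric — the regular-step descent
    shrinks its step monotonically within a run, so restarting escapes
    shallow ridges (rotation-versus-strain trade-offs of near-ellipsoidal
    heads). The defaults suit small perturbations; use multi-start plus
    restarts when subjects may be strongly rotated.
    """

    metric: str = "mean_squares"
    bins: int = 32
    sampling_fraction: float = 0.1
    shrink_factors: tuple = (4, 2, 1)
    smoothing_sigmas: tuple = (2.0, 1.0, 0.0)
    iterations: int = 60
    relaxation: float = 0.6
    learning_rate: float = 0.2
    min_step: float = 1e-4
    grad_tolerance: float = 1e-4
    multi_start_deg: tuple = ()
    restarts: int = 0
    seed: int = 12345


def _to_sitk(vol: CTVolume) -> sitk.Image:
    # sitk expects (z, y, x) arrays; our data are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T.astype(np.float32)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.affine[:3, 3]))
    return img


def _axis_rotation(axis: int, deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    u = np.zeros(3)
    u[axis] = 1.0
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


def _set_metric(reg, cfg):
    if cfg.metric == "mean_squares":
        reg.SetMetricAsMeanSquares()
    elif cfg.metric == "mattes":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.bins)
    else:
        raise ValueError(f"unknown metric {cfg.metric!r}")


def _sitk_affine_to_matrix(final) -> np.ndarray:
    at = sitk.AffineTransform(final if not isinstance(final, sitk.CompositeTransform)
                              else final.GetNthTransform(0))
    A = np.array(at.GetMatrix()).reshape(3, 3)
    c = np.array(at.GetCenter())
    t = np.array(at.GetTranslation())
    # sitk maps atlas (fixed) physical points to subject (moving):
    # p_subj = A (p_atlas - c) + c + t
    atlas_to_subj = np.eye(4)
    atlas_to_subj[:3, :3] = A
    atlas_to_subj[:3, 3] = c + t - A @ c
    return np.linalg.inv(atlas_to_subj)  # subject -> atlas


def _dense_metric(fixed, moving, transform, cfg, sampled: bool = False) -> float:
    ev = sitk.ImageRegistrationMethod()
    _set_metric(ev, cfg)
    if sampled:
        ev.SetMetricSamplingStrategy(ev.RANDOM)
        ev.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.seed)
    else:
        ev.SetMetricSamplingStrategy(ev.NONE)
    ev.SetInterpolator(sitk.sitkLinear)
    ev.SetInitialTransform(transform, inPlace=False)
    return ev.MetricEvaluate(fixed, moving)


def register_affine(subject: CTVolume, atlas: AtlasBundle,
                    cfg: RegistrationConfig | None = None,
                    initial: AffineTransform | None = None) -> AffineTransform:
    """12-dof affine registration of the subject CT to the atlas template.

    Multi-resolution regular-step gradient descent on the configured
    similarity metric, optionally preceded by a coarse-level rotation
    multi-start (the best candidate by dense metric is refined). If the
    optimum fails to improve on the identity alignment, the identity
    transform is returned with a provenance flag and a warning.
    """
    cfg = cfg or RegistrationConfig()
    fixed = _to_sitk(atlas.template)
    moving = _to_sitk(subject)

    def initial_transform(R: np.ndarray | None):
        if initial is not None:
            M0 = np.linalg.inv(initial.matrix)  # atlas -> subject for sitk
            aff = sitk.AffineTransform(3)
            aff.SetMatrix(M0[:3, :3].ravel())
            aff.SetTranslation(M0[:3, 3])
        else:
            init = sitk.CenteredTransformInitializer(
                fixed, moving, sitk.AffineTransform(3),
                sitk.CenteredTransformInitializerFilter.GEOMETRY,
            )
            aff = sitk.AffineTransform(init if not isinstance(init, sitk.CompositeTransform)
                                       else init.GetNthTransform(0))
        if R is not None:
            aff.SetMatrix(R.ravel())
        return aff

    def run(init, shrink, smooth, iters):
        reg = sitk.ImageRegistrationMethod()
        _set_metric(reg, cfg)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.seed)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=cfg.learning_rate, minStep=cfg.min_step, numberOfIterations=iters,
            relaxationFactor=cfg.relaxation,
            gradientMagnitudeTolerance=cfg.grad_tolerance,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(shrink))
        reg.SetSmoothingSigmasPerLevel(list(smooth))
        reg.SetInitialTransform(init, inPlace=False)
        return reg.Execute(fixed, moving)

    def to_affine(t):
        return sitk.AffineTransform(t if not isinstance(t, sitk.CompositeTransform)
                                    else t.GetNthTransform(0))

    starts = [initial_transform(None)]
    for deg in cfg.multi_start_deg:
        for axis in range(3):
            for sign in (1.0, -1.0):
                starts.append(initial_transform(_axis_rotation(axis, sign * deg)))

    best, best_val = None, np.inf
    for init in starts:
        candidate = run(init, cfg.shrink_factors, cfg.smoothing_sigmas, cfg.iterations)
        val = _dense_metric(fixed, moving, candidate, cfg)
        if val < best_val:
            best, best_val = candidate, val
    for _ in range(cfg.restarts):
        candidate = run(to_affine(best), cfg.shrink_factors, cfg.smoothing_sigmas,
                        cfg.iterations)
        val = _dense_metric(fixed, moving, candidate, cfg)
        if val < best_val - 1e-9:
            best, best_val = candidate, val
        else:
            break
    final = best

    metric_final = _dense_metric(fixed, moving, final, cfg)
    metric_identity = _dense_metric(fixed, moving, sitk.AffineTransform(3), cfg)
    # fall back only on a meaningful degradation; optimizer noise can leave
    # the solution a fraction of a percent on either side of the identity
    if metric_final > metric_identity + 0.02 * abs(metric_identity):
        warnings.warn("registration failed to improve on identity; returning identity")
        return AffineTransform(np.eye(4), flag_identity_fallback=True)
    return AffineTransform(_sitk_affine_to_matrix(final))


def warp_to_subject(prior: np.ndarray, t: AffineTransform, grid: CTVolume,
                    atlas: AtlasBundle, binary: bool = False) -> np.ndarray:
    """Resample an atlas-space volume onto the subject grid through t.

    Probabilities are interpolated trilinearly and clipped to [0, 1];
    binary volumes use nearest-neighbour.
    """
    # subject voxel -> subject world -> atlas world -> atlas voxel
    M = np.linalg.inv(atlas.template.affine) @ t.matrix @ grid.affine
    order = 0 if binary else 1
    arr = np.asarray(prior, dtype=np.float32)
    out = ndimage.affine_transform(
        arr, M[:3, :3], offset=M[:3, 3],
        output_shape=grid.shape, order=order, mode="constant",
        cval=float(arr.min()),
    )
    if binary:
        return out > 0.5
    # linear interpolation cannot overshoot, but guard the range anyway so
    # probability maps stay probabilities and images keep their HU range
    return np.clip(out, float(arr.min()), float(arr.max()))


@dataclass
class EMConfig:
    """EM settings. `prior_mixing` relaxes the atlas priors toward a uniform
    distribution (P' = (1-lambda) P + lambda/3), tolerating anatomy displaced
    from its atlas location (mass effect); 0 reproduces strict priors."""

    tol: float = 1e-5
    max_iter: int = 50
    variance_floor: float = 1e-6
    prior_mixing: float = 0.1
    init: str = "quantile"  # or "prior"


@dataclass
class TissueSegmentation:
    """Posterior tissue probabilities and hard labels (0 csf, 1 gm, 2 wm)."""

    post_csf: np.ndarray
    post_gm: np.ndarray
    post_wm: np.ndarray
    hard_labels: np.ndarray  # -1 outside mask
    log_likelihood: list = field(default_factory=list)
    means: np.ndarray = None  # type: ignore[assignment]
    variances: np.ndarray = None  # type: ignore[assignment]
    variance_floored: bool = False

    def posterior(self, name: str) -> np.ndarray:
        return getattr(self, f"post_{name}")


def segment_tissues_em(ct: CTVolume, mask: np.ndarray, priors: dict,
                       cfg: EMConfig | None = None) -> TissueSegmentation:
    """EM Gaussian-mixture tissue segmentation with spatial atlas priors.

    `priors` maps class names ('csf', 'gm', 'wm') to probability volumes on
    the subject grid. The E-step posterior is proportional to prior times
    Gaussian likelihood; the M-step re-estimates class means and variances
    from the posteriors. The log-likelihood is non-decreasing and iteration
    stops when its relative change falls below `tol`.
    """
    cfg = cfg or EMConfig()
    if not mask.any():
        raise ValueError("empty brain mask")
    x = np.asarray(ct.data, dtype=np.float64)[mask]
    P = np.stack([np.asarray(priors[name], dtype=np.float64)[mask] for name in CLASS_NAMES])
    total = P.sum(axis=0, keepdims=True)
    P = np.divide(P, total, out=np.full_like(P, 1.0 / 3.0), where=total > 0)
    lam = cfg.prior_mixing
    if lam > 0:
        P = (1.0 - lam) * P + lam / 3.0
    nz = (P.sum(axis=1) > 0).sum()
    if nz < 2:
        raise ValueError("need at least 2 classes with nonzero prior mass")

    if cfg.init == "quantile":
        # robust landmarks: CSF is the darkest tissue, GM the brightest
        mu = np.array([np.quantile(x, 0.005), np.quantile(x, 0.85), np.quantile(x, 0.45)])
        var = np.full(3, (x.std() / 3.0) ** 2)
        floored = False
    else:
        w0 = np.maximum(P.sum(axis=1), 1e-12)  # a zero-mass class stays benign
        mu = (P * x).sum(axis=1) / w0
        var = (P * (x - mu[:, None]) ** 2).sum(axis=1) / w0
        floored = bool((var < cfg.variance_floor).any())
    var = np.maximum(var, cfg.variance_floor)

    with np.errstate(divide="ignore"):
        logP = np.log(P)
    ll_history: list[float] = []
    post = None
    for _ in range(cfg.max_iter):
        # E-step in the log domain
        log_lik = -0.5 * (np.log(2 * np.pi * var[:, None]) + (x - mu[:, None]) ** 2 / var[:, None])
        joint = logP + log_lik
        m = joint.max(axis=0, keepdims=True)
        lse = m + np.log(np.exp(joint - m).sum(axis=0, keepdims=True))
        post = np.exp(joint - lse)
        ll = float(lse.sum())
        if ll_history and ll < ll_history[-1] - 1e-9 * abs(ll_history[-1]):
            warnings.warn("EM log-likelihood decreased; stopping")
            break
        done = bool(ll_history) and abs(ll - ll_history[-1]) <= cfg.tol * abs(ll_history[-1])
        ll_history.append(ll)
        if done:
            break
        # M-step
        w = post.sum(axis=1)
        mu = (post * x).sum(axis=1) / np.maximum(w, 1e-12)
        var = (post * (x - mu[:, None]) ** 2).sum(axis=1) / np.maximum(w, 1e-12)
        if (var < cfg.variance_floor).any():
            floored = True
            warnings.warn("EM class variance collapsed; flooring")
        var = np.maximum(var, cfg.variance_floor)

    vols = []
    for c in range(3):
        v = np.zeros(ct.shape, dtype=np.float32)
        v[mask] = post[c]
        vols.append(v)
    hard = np.full(ct.shape, -1, dtype=np.int8)
    hard[mask] = np.argmax(post, axis=0)  # ties -> lowest class index
    return TissueSegmentation(
        post_csf=vols[0], post_gm=vols[1], post_wm=vols[2],
        hard_labels=hard, log_likelihood=ll_history,
        means=mu, variances=var, variance_floored=floored,
    )


def build_em_priors(atlas: AtlasBundle, t: AffineTransform, grid: CTVolume,
                    halo_mm: float = 14.0, leak: float = 0.35,
                    confidence_cap: float = 0.75) -> dict:
    """Warp atlas tissue priors to the subject and relax the CSF prior.

    Mass effect (hematoma, midline shift) can displace the ventricles well
    away from their atlas location, where the warped CSF prior is ~0 and the
    intensity evidence could never win. The CSF prior is therefore raised to
    at least `leak` inside a `halo_mm` neighbourhood of the binary
    ventricle/cistern priors, and no class prior may exceed
    `confidence_cap`; GM/WM priors are rescaled so the three still sum to 1.
    """
    pri = {name: warp_to_subject(getattr(atlas, f"prior_{name}"), t, grid, atlas)
           for name in CLASS_NAMES}
    if confidence_cap < 1.0:
        # never let a single class claim a voxel outright: anatomy can be
        # displaced from its atlas location, so intensity must retain a vote
        total = sum(pri.values())
        capped = {n: np.minimum(p, confidence_cap) for n, p in pri.items()}
        csum = sum(capped.values())
        pri = {n: np.divide(capped[n] * total, csum, out=capped[n],
                            where=csum > 0) for n in capped}
    struct = warp_to_subject(
        (atlas.prior_ventricles | atlas.prior_cisterns).astype(np.float32),
        t, grid, atlas, binary=True,
    )
    iters = max(1, int(round(halo_mm / min(grid.spacing))))
    halo = ndimage.binary_dilation(struct, iterations=iters)
    csf = np.maximum(pri["csf"], np.float32(leak) * halo.astype(np.float32))
    rest = np.maximum(np.float32(1e-6), pri["gm"] + pri["wm"])
    scale = np.clip((1.0 - csf) / rest, 0.0, None)
    return {"csf": csf, "gm": pri["gm"] * scale, "wm": pri["wm"] * scale}


def locate_structures(seg: TissueSegmentation, atlas: AtlasBundle, t: AffineTransform,
                      grid: CTVolume, brain: np.ndarray, dilate_voxels: int = 2):
    """Ventricle and cistern candidate masks from CSF labels and binary priors.

    The warped binary prior is dilated (tolerating residual registration
    error and lateral displacement of the ventricles), intersected with the
    CSF hard label, and each CSF connected component touching the
    intersection is taken whole. Candidates are always a subset of the CSF
    hard-label mask. An empty intersection returns an empty mask with a
    warning (clinically: obliterated cisterns).
    """
    csf = (seg.hard_labels == 0) & brain
    # majority vote removes isolated noise-flip voxels before component
    # analysis; candidates stay a subset of the raw CSF hard label
    maj = ndimage.uniform_filter(csf.astype(np.float32), size=3) > 0.5
    csf_clean = csf & maj
    comp_labels, n_comp = ndimage.label(csf_clean)
    out = {}
    overlap_maps = {}
    for name, prior in (("ventricles", atlas.prior_ventricles),
                        ("cisterns", atlas.prior_cisterns)):
        warped = warp_to_subject(prior.astype(np.float32), t, grid, atlas, binary=True)
        if dilate_voxels > 0:
            warped = ndimage.binary_dilation(warped, iterations=dilate_voxels)
        seed = csf_clean & warped
        if not seed.any():
            warnings.warn(f"empty {name} candidates (no CSF under the prior)")
            out[name] = np.zeros_like(csf)
            overlap_maps[name] = np.zeros(n_comp + 1)
            continue
        hit = np.zeros(n_comp + 1, dtype=np.int64)
        ids, cnts = np.unique(comp_labels[seed], return_counts=True)
        hit[ids] = cnts
        hit[0] = 0
        out[name] = np.isin(comp_labels, np.where(hit > 0)[0]) & csf
        overlap_maps[name] = hit
    # a CSF component claimed by both priors goes to the larger overlap
    both = out["ventricles"] & out["cisterns"]
    if both.any():
        for comp_id in np.unique(comp_labels[both]):
            if comp_id == 0:
                continue
            comp = comp_labels == comp_id
            if overlap_maps["ventricles"][comp_id] >= overlap_maps["cisterns"][comp_id]:
                out["cisterns"] &= ~comp
            else:
                out["ventricles"] &= ~comp
    return out["ventricles"], out["cisterns"]
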