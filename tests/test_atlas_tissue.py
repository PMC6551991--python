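"""Registration, prior warping, EM tissue segmentation, structure location."""

import numpy as np
import pytest

from conftest import dice
from tbiq.atlas_tissue import (
    AffineTransform,
    EMConfig,
    build_em_priors,
    locate_structures,
    register_affine,
    segment_tissues_em,
    warp_to_subject,
)
from tbiq.phantom import PhantomSpec, generate_phantom
from tbiq.volume import CTVolume


def test_affine_transform_invertibility():
    m = np.eye(4)
    m[:3, 3] = (3.0, -2.0, 1.0)
    t = AffineTransform(m)
    assert np.allclose(t.matrix @ t.inverse, np.eye(4), atol=1e-8)
    with pytest.raises(ValueError):
        AffineTransform(np.zeros((4, 4)))


def test_self_registration_is_near_identity(atlas):
    t = register_affine(atlas.template, atlas)
    d = t.matrix - np.eye(4)
    assert np.abs(d[:3, 3]).max() < 0.5          # translation < 0.5 mm
    # linear deviation bound equivalent to < 0.5 degrees rotation
    assert np.abs(d[:3, :3]).max() < 0.01


def test_known_translation_is_recovered(atlas):
    from scipy import ndimage

    shift_mm = np.array([5.0, -3.0, 2.0])
    shift_vox = shift_mm / np.array(atlas.template.spacing)
    moved = ndimage.shift(atlas.template.data, shift_vox, order=1, mode="nearest")
    subject = CTVolume(data=moved, spacing=atlas.template.spacing,
                       affine=atlas.template.affine.copy())
    t = register_affine(subject, atlas)
    # moving the content by +s means the subject->atlas map subtracts s
    recovered = -t.matrix[:3, 3]
    assert np.abs(recovered - shift_mm).max() <= 1.0


def test_warp_identity_preserves_prior(atlas, shifted_case):
    # same grid + identity transform: exact preservation (nearest neighbour)
    out = warp_to_subject(atlas.prior_ventricles.astype(np.float32),
                          AffineTransform.identity(), atlas.template, atlas,
                          binary=True)
    assert np.array_equal(out, atlas.prior_ventricles)


def test_warp_roundtrip_binary_dice(atlas):
    m = np.eye(4)
    m[:3, 3] = (4.0, 2.0, -3.0)
    t = AffineTransform(m)
    fwd = warp_to_subject(atlas.brain_mask.astype(np.float32), t,
                          atlas.template, atlas, binary=True)
    back = warp_to_subject(fwd.astype(np.float32), AffineTransform(t.inverse),
                           atlas.template, atlas, binary=True)
    assert dice(back, atlas.brain_mask) >= 0.95
    # thin structures lose more to double nearest-neighbour quantization
    fwd_v = warp_to_subject(atlas.prior_ventricles.astype(np.float32), t,
                            atlas.template, atlas, binary=True)
    back_v = warp_to_subject(fwd_v.astype(np.float32), AffineTransform(t.inverse),
                             atlas.template, atlas, binary=True)
    assert dice(back_v, atlas.prior_ventricles) >= 0.85


def test_warp_keeps_probabilities_in_unit_interval(atlas, shifted_case):
    out = warp_to_subject(atlas.prior_gm, AffineTransform(np.diag([1.02, 0.98, 1.0, 1.0])),
                          shifted_case.ct, atlas)
    assert out.min() >= 0.0 and out.max() <= 1.0


# -- EM ----------------------------------------------------------------------

def _toy_ct(rng, shape=(16, 16, 8)):
    mask = np.zeros(shape, bool)
    mask[2:-2, 2:-2, 1:-1] = True
    lab = rng.integers(0, 3, size=shape)
    means = np.array([-1.8, 0.8, -0.2])
    data = means[lab] + rng.normal(0, 0.3, shape)
    ct = CTVolume(data=data.astype(np.float32), spacing=(1, 1, 1))
    priors = {}
    for i, name in enumerate(("csf", "gm", "wm")):
        p = np.full(shape, 0.1, np.float32)
        p[lab == i] = 0.8
        priors[name] = p
    return ct, mask, lab, priors


def test_em_loglikelihood_is_nondecreasing_and_posteriors_normalized():
    rng = np.random.default_rng(0)
    ct, mask, lab, priors = _toy_ct(rng)
    seg = segment_tissues_em(ct, mask, priors)
    ll = seg.log_likelihood
    assert len(ll) >= 2
    assert all(b >= a - 1e-9 * abs(a) for a, b in zip(ll, ll[1:]))
    total = seg.post_csf + seg.post_gm + seg.post_wm
    assert np.allclose(total[mask], 1.0, atol=1e-6)
    acc = (seg.hard_labels[mask] == lab[mask]).mean()
    assert acc >= 0.9


def test_em_prior_dominance_with_strict_priors():
    # a region with prior exactly 1 for one class is classified as that
    # class regardless of intensity when relaxation is disabled
    shape = (12, 12, 6)
    mask = np.ones(shape, bool)
    rng = np.random.default_rng(1)
    data = rng.normal(0.0, 1.0, shape).astype(np.float32)
    ct = CTVolume(data=data, spacing=(1, 1, 1))
    priors = {"csf": np.zeros(shape, np.float32),
              "gm": np.zeros(shape, np.float32),
              "wm": np.ones(shape, np.float32)}
    priors["csf"][:4] = 1.0
    priors["wm"][:4] = 0.0
    seg = segment_tissues_em(ct, mask, priors,
                             EMConfig(prior_mixing=0.0, init="prior", max_iter=3))
    assert (seg.hard_labels[:4] == 0).all()
    assert np.allclose(seg.post_csf[:4], 1.0, atol=1e-6)


def test_em_identical_gaussians_return_priors():
    # when every class has the same distribution the likelihood cancels and
    # the posterior equals the (normalized) prior
    shape = (10, 10, 4)
    mask = np.ones(shape, bool)
    data = np.random.default_rng(2).normal(size=shape).astype(np.float32)
    ct = CTVolume(data=data, spacing=(1, 1, 1))
    priors = {"csf": np.full(shape, 0.5, np.float32),
              "gm": np.full(shape, 0.3, np.float32),
              "wm": np.full(shape, 0.2, np.float32)}
    seg = segment_tissues_em(ct, mask, priors,
                             EMConfig(prior_mixing=0.0, init="prior", max_iter=1))
    # equal prior-weighted initial statistics for all classes -> identical
    # Gaussians -> posterior == prior
    assert np.allclose(seg.post_csf[mask], 0.5, atol=1e-6)
    assert np.allclose(seg.post_gm[mask], 0.3, atol=1e-6)


def test_em_variance_collapse_is_floored_and_flagged():
    shape = (10, 10, 4)
    mask = np.ones(shape, bool)
    data = np.zeros(shape, np.float32)
    data[:5] = 1.0  # two exact values: variances collapse
    ct = CTVolume(data=data, spacing=(1, 1, 1))
    priors = {"csf": np.full(shape, 1 / 3, np.float32),
              "gm": np.full(shape, 1 / 3, np.float32),
              "wm": np.full(shape, 1 / 3, np.float32)}
    with pytest.warns(UserWarning, match="variance"):
        seg = segment_tissues_em(ct, mask, priors, EMConfig(max_iter=5))
    assert seg.variance_floored
    assert (seg.variances >= 1e-6 - 1e-12).all()


def test_em_rejects_empty_mask(noiseless_case):
    with pytest.raises(ValueError):
        segment_tissues_em(noiseless_case.ct, np.zeros(noiseless_case.ct.shape, bool),
                           {"csf": 0, "gm": 0, "wm": 0})


# -- structure localisation --------------------------------------------------

def test_unshifted_candidates_recover_structures(noiseless_products, noiseless_case):
    assert dice(noiseless_products["vent"], noiseless_case.truth_ventricles) >= 0.7
    assert dice(noiseless_products["cist"], noiseless_case.truth_cisterns) >= 0.7


def test_candidates_are_subset_of_csf_hard_label(shifted_products):
    csf = (shifted_products["seg"].hard_labels == 0) & shifted_products["brain"]
    assert not (shifted_products["vent"] & ~csf).any()
    assert not (shifted_products["cist"] & ~csf).any()
    assert not (shifted_products["vent"] & shifted_products["cist"]).any()


def test_obliterated_cisterns_yield_empty_candidates_with_warning(atlas):
    case = generate_phantom(PhantomSpec(seed=33, cistern_volume=0.0))
    from conftest import run_localisation
    import warnings

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        prod = run_localisation(case, atlas)
    assert not prod["cist"].any()
    assert any("cistern" in str(w.message) for w in wlist)
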