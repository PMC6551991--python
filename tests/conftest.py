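"""Shared fixtures: session-scoped phantoms, atlas, and pipeline products.

Everything is generated programmatically with fixed seeds; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from tbiq.atlas_tissue import (
    build_em_priors,
    locate_structures,
    register_affine,
    segment_tissues_em,
)
from tbiq.phantom import PhantomSpec, generate_atlas, generate_phantom
from tbiq.preprocess import extract_brain, normalize_intensities


def dice(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def base_spec() -> PhantomSpec:
    return PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def atlas(base_spec):
    return generate_atlas(base_spec, n_subjects=3, seed=100)


@pytest.fixture(scope="session")
def shifted_case():
    return generate_phantom(PhantomSpec(seed=11, induced_shift=8.0))


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_phantom(PhantomSpec(seed=12, noise_sigma=0.0))


def run_localisation(case, atlas):
    """Brain extraction -> registration -> EM -> structure localisation."""
    brain = extract_brain(case.ct, "morphological")
    norm = normalize_intensities(case.ct, brain)
    t = register_affine(case.ct, atlas)
    priors = build_em_priors(atlas, t, case.ct)
    seg = segment_tissues_em(norm, brain, priors)
    vent, cist = locate_structures(seg, atlas, t, case.ct, brain)
    return {"brain": brain, "norm": norm, "t": t, "priors": priors,
            "seg": seg, "vent": vent, "cist": cist}


@pytest.fixture(scope="session")
def shifted_products(shifted_case, atlas):
    return run_localisation(shifted_case, atlas)


@pytest.fixture(scope="session")
def noiseless_products(noiseless_case, atlas):
    return run_localisation(noiseless_case, atlas)


def lesion_phantom(seed: int, vols=((40.0, "right"),), falx: bool = True):
    """Small phantom sized for the reduced 60^3-input lesion network."""
    return generate_phantom(PhantomSpec(
        grid_shape=(64, 72, 44), spacing=(2.5, 2.5, 2.5),
        lesion_volumes=vols, decoy_falx=falx, seed=seed,
    ))
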