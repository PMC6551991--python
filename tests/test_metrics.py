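"""Agreement metrics: worked examples, ANOVA oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbiq.metrics import (
    classification_accuracy,
    icc_absolute,
    overlap_metrics,
    shift_agreement,
    volume_agreement,
)


def _mask(n_true, size=64):
    m = np.zeros(size, bool)
    m[:n_true] = True
    return m


def test_identical_masks_give_perfect_overlap():
    m = _mask(10)
    dice, prec, sens, counts = overlap_metrics(m, m)
    assert (dice, prec, sens) == (1.0, 1.0, 1.0)
    assert counts.fp == counts.fn == 0


def test_disjoint_masks_give_zero_overlap():
    a = np.zeros(10, bool); a[:4] = True
    b = np.zeros(10, bool); b[5:9] = True
    dice, prec, sens, _ = overlap_metrics(a, b)
    assert (dice, prec, sens) == (0.0, 0.0, 0.0)


def test_half_overlap_worked_example():
    # |ref| = |pred| = 4 with overlap 2: Dice = 2*2 / (4 + 4) = 0.5
    a = np.zeros(12, bool); a[0:4] = True
    b = np.zeros(12, bool); b[2:6] = True
    dice, prec, sens, counts = overlap_metrics(a, b)
    assert (dice, prec, sens) == (0.5, 0.5, 0.5)
    assert (counts.tp, counts.fp, counts.fn) == (2, 2, 2)


def test_empty_mask_conventions():
    empty = np.zeros(8, bool)
    assert overlap_metrics(empty, empty)[:3] == (1.0, 1.0, 1.0)
    dice, prec, sens, _ = overlap_metrics(empty, _mask(3, 8))
    assert dice == 0.0 and prec == 0.0 and np.isnan(sens)


def test_overlap_requires_congruent_grids():
    with pytest.raises(ValueError):
        overlap_metrics(np.zeros(4, bool), np.zeros(5, bool))


def test_volume_difference_sign_convention():
    spacing = (10.0, 10.0, 10.0)  # 1 mL voxels
    ref = np.zeros((40, 1, 1), bool); ref[:30] = True
    pred = np.zeros((40, 1, 1), bool); pred[:20] = True
    diff, absdiff = volume_agreement(ref, pred, spacing)
    assert diff == pytest.approx(10.0)   # positive = undersegmentation
    assert absdiff == pytest.approx(10.0)
    diff, absdiff = volume_agreement(pred, ref, spacing)
    assert diff == pytest.approx(-10.0) and absdiff == pytest.approx(10.0)


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=64))
@settings(deadline=None, max_examples=50)
def test_dice_symmetry_and_f1_identity(pairs):
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    d_ab = overlap_metrics(a, b)[0]
    d_ba = overlap_metrics(b, a)[0]
    assert d_ab == pytest.approx(d_ba)
    dice, prec, sens, _ = overlap_metrics(a, b)
    if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0:
        assert dice == pytest.approx(2 * prec * sens / (prec + sens))


# -- ICC(2,1) ----------------------------------------------------------------

def icc21_bruteforce(x, y):
    """Independent oracle: explicit two-way ANOVA decomposition via loops."""
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_perfect_agreement_is_one():
    x = np.array([1.0, 2.0, 5.0, 9.0])
    assert icc_absolute(x, x) == pytest.approx(1.0)


def test_icc_decreases_with_systematic_offset():
    x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
    iccs = [icc_absolute(x, x + c) for c in (0.0, 1.0, 3.0, 6.0)]
    assert all(b < a for a, b in zip(iccs, iccs[1:]))
    assert iccs[1] < 1.0


def test_icc_matches_bruteforce_anova_oracle():
    rng = np.random.default_rng(123)
    for _ in range(100):
        n = int(rng.integers(3, 40))
        x = rng.normal(size=n) * rng.uniform(0.5, 5)
        y = x * rng.uniform(0.5, 1.5) + rng.normal(size=n) + rng.uniform(-2, 2)
        assert icc_absolute(x, y) == pytest.approx(icc21_bruteforce(x, y), abs=1e-10)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(5)
    x = rng.normal(size=25)
    y = x + rng.normal(scale=0.3, size=25) + 0.2
    df = pd.DataFrame({
        "targets": np.repeat(np.arange(25), 2),
        "raters": np.tile(["a", "b"], 25),
        "scores": np.stack([x, y], axis=1).ravel(),
    })
    icc_pg = pg.intraclass_corr(df, targets="targets", raters="raters",
                                ratings="scores").set_index("Type").loc["ICC(A,1)", "ICC"]
    assert icc_absolute(x, y) == pytest.approx(float(icc_pg), abs=1e-8)


def test_icc_near_zero_for_independent_series():
    rng = np.random.default_rng(77)
    x = rng.normal(size=1000)
    y = rng.normal(size=1000)
    assert abs(icc_absolute(x, y)) < 0.1


def test_icc_input_validation():
    with pytest.raises(ValueError):
        icc_absolute([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        icc_absolute([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])


# -- classification accuracy / kappa ----------------------------------------

def test_identical_series_accuracy_and_kappa():
    vals = np.array([10.0, 30.0, 40.0, 2.0])
    acc, kappa = classification_accuracy(vals, vals, cutoff=25.0)
    assert acc == 1.0 and kappa == pytest.approx(1.0)


def test_accuracy_fraction_worked_example():
    # 36 of 39 agree at the cutoff
    ref = np.array([30.0] * 20 + [10.0] * 19)
    pred = ref.copy()
    pred[:3] = 10.0
    acc, _ = classification_accuracy(ref, pred, cutoff=25.0)
    assert acc == pytest.approx(36 / 39)


def test_single_class_agreement_gives_nan_kappa():
    vals = np.array([1.0, 2.0, 3.0])
    with pytest.warns(UserWarning, match="kappa"):
        acc, kappa = classification_accuracy(vals, vals, cutoff=25.0)
    assert acc == 1.0 and np.isnan(kappa)


def test_value_exactly_at_cutoff_classifies_as_not_greater():
    acc, _ = classification_accuracy([25.0, 30.0], [20.0, 30.0], cutoff=25.0)
    assert acc == 1.0


# -- shift agreement ---------------------------------------------------------

@pytest.mark.parametrize("ref,pred,expected_diff", [
    (5.60, 5.95, -0.35),
    (1.10, 1.91, -0.81),
    (4.2, 4.2, 0.0),
])
def test_shift_agreement_examples(ref, pred, expected_diff):
    diff, absdiff = shift_agreement(ref, pred)
    assert diff == pytest.approx(expected_diff, abs=1e-9)
    assert absdiff == pytest.approx(abs(expected_diff), abs=1e-9)


def test_shift_agreement_rejects_nonfinite():
    with pytest.raises(ValueError):
        shift_agreement(float("nan"), 1.0)
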