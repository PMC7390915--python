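import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import ttest_1samp

from slicechain.exceptions import DegenerateInputError, UndefinedMetricError, ValidationError
from slicechain.seg_metrics import asd, dsc, evaluate_pair, hd, jaccard, paired_t, surface_points

SPACING = (2.5, 0.98, 0.98)
UNIT = (1.0, 1.0, 1.0)


def brute_force_surface(mask):
    """Oracle: explicit 6-neighbour scan, border counts as background."""
    mask = np.asarray(mask, bool)
    points = []
    for idx in np.argwhere(mask):
        z, y, x = idx
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            zz, yy, xx = z + dz, y + dy, x + dx
            outside = not (0 <= zz < mask.shape[0] and 0 <= yy < mask.shape[1]
                           and 0 <= xx < mask.shape[2])
            if outside or not mask[zz, yy, xx]:
                points.append(idx)
                break
    return np.array(points, dtype=float)


def brute_force_asd_hd(a, b, spacing):
    pa = brute_force_surface(a) * np.asarray(spacing)
    pb = brute_force_surface(b) * np.asarray(spacing)
    d = cdist(pa, pb)
    dab, dba = d.min(axis=1), d.min(axis=0)
    return (dab.mean() + dba.mean()) / 2.0, max(dab.max(), dba.max())


def _pair(shape=(4, 16, 16), seed=0, p=0.2):
    rng = np.random.default_rng(seed)
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    if not a.any():
        a[0, 0, 0] = True
    if not b.any():
        b[-1, -1, -1] = True
    return a, b


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def test_dsc_identity_and_disjoint():
    a, _ = _pair(seed=1)
    assert dsc(a, a) == 1.0
    assert dsc(a, ~a) == 0.0


def test_offset_squares_worked_example():
    a = np.zeros((1, 4, 4), bool)
    b = np.zeros((1, 4, 4), bool)
    a[0, 1:3, 0:2] = True  # |A| = 4
    b[0, 1:3, 1:3] = True  # |B| = 4, overlap 2
    assert dsc(a, b) == 0.5
    assert jaccard(a, b) == pytest.approx(2 / 6)


@pytest.mark.parametrize("seed", range(10))
def test_dsc_jaccard_algebraic_identity(seed):
    a, b = _pair(seed=seed)
    j = jaccard(a, b)
    assert dsc(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)


def test_empty_pair_is_undefined():
    z = np.zeros((2, 4, 4), bool)
    with pytest.raises(UndefinedMetricError):
        dsc(z, z)
    with pytest.raises(UndefinedMetricError):
        jaccard(z, z)


def test_shape_mismatch_rejected():
    with pytest.raises(ValidationError):
        dsc(np.ones((2, 4, 4), bool), np.ones((2, 4, 5), bool))


# ---------------------------------------------------------------------------
# surfaces and distances
# ---------------------------------------------------------------------------

def test_single_voxel_surface_is_one_point():
    m = np.zeros((3, 3, 3), bool)
    m[1, 1, 1] = True
    assert surface_points(m, UNIT).shape == (1, 3)


def test_cube_surface_excludes_only_the_center():
    m = np.zeros((5, 5, 5), bool)
    m[1:4, 1:4, 1:4] = True
    assert surface_points(m, UNIT).shape == (26, 3)


def test_single_slice_slab_is_all_boundary():
    m = np.zeros((3, 8, 8), bool)
    m[1] = True  # every voxel has an out-of-plane background neighbour
    assert surface_points(m, UNIT).shape == (64, 3)


def test_surface_of_empty_mask_is_undefined():
    with pytest.raises(UndefinedMetricError):
        surface_points(np.zeros((2, 2, 2), bool), UNIT)


def test_axis_separation_in_mm():
    a = np.zeros((8, 8, 8), bool)
    b = np.zeros((8, 8, 8), bool)
    a[1, 1, 1] = True
    b[4, 1, 1] = True  # 3 voxels apart along the slice axis
    assert asd(a, b, UNIT) == pytest.approx(3.0)
    assert hd(a, b, UNIT) == pytest.approx(3.0)


def test_three_four_five_triangle():
    a = np.zeros((8, 8, 8), bool)
    b = np.zeros((8, 8, 8), bool)
    a[0, 0, 0] = True
    b[0, 3, 4] = True
    assert asd(a, b, UNIT) == pytest.approx(5.0)
    assert hd(a, b, UNIT) == pytest.approx(5.0)


def test_directed_distances_are_asymmetric_but_hd_takes_the_max():
    a = np.zeros((8, 8, 8), bool)
    b = np.zeros((8, 8, 8), bool)
    a[0, 0, 0] = True
    b[0, 0, 0] = True
    b[7, 0, 0] = True  # 7 mm away at unit spacing
    assert hd(a, b, UNIT) == pytest.approx(7.0)
    assert asd(a, b, UNIT) == pytest.approx((0.0 + 3.5) / 2)


def test_identical_masks_have_zero_distances():
    a, _ = _pair(seed=3)
    assert asd(a, a, SPACING) == 0.0
    assert hd(a, a, SPACING) == 0.0


@pytest.mark.parametrize("seed", range(30))
def test_distances_match_brute_force_oracle(seed):
    a, b = _pair(seed=seed)
    asd_o, hd_o = brute_force_asd_hd(a, b, SPACING)
    assert asd(a, b, SPACING) == pytest.approx(asd_o, abs=1e-9)
    assert hd(a, b, SPACING) == pytest.approx(hd_o, abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_all_metrics_are_symmetric(seed):
    a, b = _pair(seed=100 + seed)
    assert dsc(a, b) == dsc(b, a)
    assert jaccard(a, b) == jaccard(b, a)
    assert asd(a, b, SPACING) == pytest.approx(asd(b, a, SPACING), abs=1e-12)
    assert hd(a, b, SPACING) == pytest.approx(hd(b, a, SPACING), abs=1e-12)


def test_hd_nondecreasing_under_translation(disk):
    base = np.zeros((3, 32, 32), bool)
    base[1] = disk(32, (16, 8), 5)
    prev = 0.0
    for k in range(0, 12, 2):
        shifted = np.roll(base, k, axis=2)
        h = hd(base, shifted, UNIT)
        assert h >= prev - 1e-12
        prev = h


def test_evaluate_pair_bundles_all_metrics():
    a, b = _pair(seed=11)
    rep = evaluate_pair(a, b, SPACING)
    assert rep.dsc == dsc(a, b)
    assert rep.ji == jaccard(a, b)
    assert rep.asd_mm == pytest.approx(asd(a, b, SPACING))
    assert rep.hd_mm == pytest.approx(hd(a, b, SPACING))


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

def test_paired_t_worked_example():
    t, p = paired_t([1.0, 2.0, 3.0])
    assert t == pytest.approx(np.sqrt(12), abs=1e-4)  # mean 2 / (1/sqrt(3))
    assert p == pytest.approx(0.0742, abs=2e-4)


def test_paired_t_matches_scipy():
    rng = np.random.default_rng(0)
    d = rng.normal(0.3, 1.0, 20)
    t, p = paired_t(d)
    ref = ttest_1samp(d, 0.0)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_paired_t_sign_symmetry():
    d = [0.1, 0.5, -0.2, 0.3]
    t1, p1 = paired_t(d)
    t2, p2 = paired_t([-x for x in d])
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_paired_t_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        paired_t([0.0, 0.0, 0.0])
    with pytest.raises(DegenerateInputError):
        paired_t([1.0])
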