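import numpy as np
import pytest

from slicechain.exceptions import DegenerateInputError, ValidationError
from slicechain.preprocess import (
    BodyMaskConfig,
    NormalizationConfig,
    apply_body_mask,
    augment_sample,
    compute_body_mask,
    normalize,
    otsu_threshold,
    preprocess_case,
)
from slicechain.seg_metrics import dsc
from slicechain.volume_io import BinaryMask, CTVolume

SPACING = (2.5, 0.98, 0.98)


def brute_force_otsu(values, bins=256):
    """Independent oracle: scan all candidate splits of the histogram."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_t = -1.0, None
    for i in range(bins - 1):
        w0, w1 = counts[: i + 1].sum(), counts[i + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: i + 1] * centers[: i + 1]).sum() / w0
        mu1 = (counts[i + 1 :] * centers[i + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[i]
    return best_t


@pytest.mark.parametrize(
    "values",
    [
        np.r_[np.zeros(50), np.full(50, 100.0)],
        np.random.default_rng(0).normal(-1000, 50, 10000).tolist()
        + np.random.default_rng(1).normal(0, 50, 10000).tolist(),
        np.random.default_rng(2).uniform(-500, 500, 5000),
    ],
    ids=["bimodal-exact", "two-gaussians", "uniform"],
)
def test_otsu_matches_brute_force_oracle(values):
    values = np.asarray(values)
    assert otsu_threshold(values) == pytest.approx(brute_force_otsu(values))


def test_otsu_separates_two_point_distribution_exactly():
    values = np.r_[np.zeros(50), np.full(50, 100.0)]
    t = otsu_threshold(values)
    assert 0 <= t < 100
    assert (values > t).sum() == 50


def test_otsu_on_gaussian_clusters_lands_between_modes():
    rng = np.random.default_rng(42)
    values = np.r_[rng.normal(-1000, 50, 10000), rng.normal(0, 50, 10000)]
    t = otsu_threshold(values)
    assert -900 < t < -100
    # independent library cross-check (same histogram convention)
    from skimage.filters import threshold_otsu

    assert t == pytest.approx(threshold_otsu(values, nbins=256), abs=10.0)


def test_otsu_rejects_constant_input():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full(100, 7.0))


# ---------------------------------------------------------------------------
# body mask
# ---------------------------------------------------------------------------

def _disk_volume(disk, n=64, n_slices=3, radius=20, intensity=0.0, background=-1000.0):
    d = disk(n, (n / 2, n / 2), radius)
    vox = np.full((n_slices, n, n), background, dtype=np.float32)
    vox[:, d] = intensity
    return CTVolume(voxels=vox, spacing=SPACING), d


def test_body_mask_recovers_clean_disk(disk):
    vol, d = _disk_volume(disk)
    mask = compute_body_mask(vol)
    truth = np.broadcast_to(d, vol.shape)
    assert dsc(mask.voxels, truth) >= 0.99


def test_body_mask_fills_interior_hole_smaller_than_closing_radius(disk):
    vol, d = _disk_volume(disk)
    hole = disk(64, (32, 32), 3)  # radius 3 px < closing radius 5 px
    vol.voxels[:, hole] = -1000.0
    mask = compute_body_mask(vol)
    assert mask.voxels[1][hole].all()
    assert dsc(mask.voxels, np.broadcast_to(d, vol.shape)) >= 0.99


def test_body_mask_drops_detached_couch_bar(disk):
    # gap between disk bottom and bar exceeds twice the closing radius,
    # so closing cannot bridge them and the component filter drops the bar
    vol, d = _disk_volume(disk, radius=16)
    vol.voxels[:, 62:, 16:48] = 200.0  # couch bar, detached from the disk
    mask = compute_body_mask(vol, BodyMaskConfig(keep_largest_component=True))
    assert not mask.voxels[:, 62:, :].any()
    assert dsc(mask.voxels, np.broadcast_to(d, vol.shape)) >= 0.99


def test_body_mask_constant_slice_left_empty(disk):
    vol, d = _disk_volume(disk)
    vol.voxels[0] = -1000.0
    mask = compute_body_mask(vol)
    assert not mask.voxels[0].any()
    assert mask.voxels[1].any()


def test_body_mask_idempotent_on_masked_volume(noiseless_phantom):
    vol = noiseless_phantom.volume
    mask1 = compute_body_mask(vol)
    masked = apply_body_mask(vol, mask1)
    mask2 = compute_body_mask(masked)
    overlap = (mask1.voxels & mask2.voxels).sum() / mask1.voxels.sum()
    assert overlap >= 0.99


# ---------------------------------------------------------------------------
# apply_body_mask / normalize
# ---------------------------------------------------------------------------

def test_apply_all_ones_mask_is_identity():
    rng = np.random.default_rng(0)
    vol = CTVolume(rng.normal(0, 100, (4, 8, 8)).astype(np.float32), SPACING)
    out = apply_body_mask(vol, BinaryMask(np.ones(vol.shape, bool), SPACING))
    np.testing.assert_array_equal(out.voxels, vol.voxels)


def test_apply_all_zero_mask_gives_constant_background():
    rng = np.random.default_rng(1)
    vol = CTVolume(rng.normal(0, 100, (4, 8, 8)).astype(np.float32), SPACING)
    out = apply_body_mask(vol, BinaryMask(np.zeros(vol.shape, bool), SPACING))
    assert np.all(out.voxels == vol.voxels.min())


def test_apply_half_mask_preserves_inside_bit_exactly():
    rng = np.random.default_rng(2)
    vol = CTVolume(rng.normal(0, 100, (4, 8, 8)).astype(np.float32), SPACING)
    half = np.zeros(vol.shape, bool)
    half[:2] = True
    out = apply_body_mask(vol, BinaryMask(half, SPACING))
    np.testing.assert_array_equal(out.voxels[:2], vol.voxels[:2])
    assert np.all(out.voxels[2:] == vol.voxels.min())


def test_apply_mask_shape_mismatch_rejected():
    vol = CTVolume(np.zeros((4, 8, 8), np.float32), SPACING)
    with pytest.raises(ValidationError):
        apply_body_mask(vol, BinaryMask(np.ones((3, 8, 8), bool), SPACING))


@pytest.mark.parametrize(
    "value,expected",
    [(-1000.0, 0.0), (1000.0, 1.0), (0.0, 0.5), (1500.0, 1.0), (-2000.0, 0.0)],
)
def test_normalize_window_endpoints_midpoint_and_clipping(value, expected):
    vol = CTVolume(np.full((1, 2, 2), value, np.float32), SPACING)
    out = normalize(vol, NormalizationConfig())
    assert out.voxels[0, 0, 0] == pytest.approx(expected)


def test_normalization_config_rejects_inverted_window():
    with pytest.raises(ValidationError):
        NormalizationConfig(window_low=10, window_high=-10)


def test_preprocess_case_output_in_unit_range(default_phantom):
    prepped = preprocess_case(default_phantom.case)
    assert prepped.volume.voxels.min() >= 0.0
    assert prepped.volume.voxels.max() <= 1.0
    assert prepped.mask is default_phantom.case.mask


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_augment_forced_identity(disk):
    img = np.random.default_rng(0).random((32, 32)).astype(np.float32)
    m = disk(32, (16, 16), 6)
    (img2,), (m2,) = augment_sample([img], [m], rng=0, flip=False, angle_deg=0.0)
    np.testing.assert_array_equal(img2, img)
    np.testing.assert_array_equal(m2, m)


def test_flip_applied_twice_recovers_mask_bit_exactly(disk):
    m = disk(32, (16, 10), 6)
    _, (m1,) = augment_sample([], [m], rng=0, flip=True, angle_deg=0.0)
    _, (m2,) = augment_sample([], [m1], rng=0, flip=True, angle_deg=0.0)
    np.testing.assert_array_equal(m2, m)


def test_augmented_mask_stays_binary_with_stable_area(disk):
    m = disk(64, (32, 32), 10).astype(np.uint8)
    base = m.sum()
    for seed in range(100):
        _, (m2,) = augment_sample([], [m], rng=seed)
        assert set(np.unique(m2)) <= {0, 1}
        assert abs(int(m2.sum()) - int(base)) / base < 0.15


def test_augmentation_keeps_image_and_mask_aligned(disk):
    d = disk(64, (32, 28), 12)
    img = d.astype(np.float32)
    for seed in range(20):
        (img2,), (m2,) = augment_sample([img], [d], rng=seed)
        assert dsc(img2 > 0.5, m2.astype(bool)) >= 0.95


def test_augment_shape_mismatch_rejected():
    with pytest.raises(ValidationError):
        augment_sample([np.zeros((8, 8))], [np.zeros((9, 9))], rng=0)
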