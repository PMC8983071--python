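"""Intensity normalization, resampling operators, lung mask, patch sampling."""

import numpy as np
import pytest
from scipy import stats

from microsr.imaging import (
    CLINICAL,
    MICRO,
    BinaryMask,
    CTVolume,
    IntensityDomain,
    average_pool_downsample,
    bicubic_resample,
    denormalize_intensity,
    extract_patches,
    lung_mask,
    nearest_upsample,
    normalize_intensity,
)
from microsr.imaging import DomainName, _keys_kernel


# ------------------------------------------------------------ normalization


@pytest.mark.parametrize(
    "domain, native, expected",
    [
        (CLINICAL, 2500.0, 1.0),  # upper clip endpoint
        (CLINICAL, -1500.0, -1.0),  # clipped to -1000 then endpoint
        (CLINICAL, 750.0, 0.0),  # midpoint of [-1000, 2500]
        (CLINICAL, -1000.0, -1.0),
        (MICRO, 7500.0, 0.0),  # midpoint of [0, 15000]
        (MICRO, 15000.0, 1.0),
        (MICRO, -5.0, -1.0),
    ],
)
def test_normalize_clip_and_affine_map(domain, native, expected):
    assert normalize_intensity(np.array([native]), domain)[0] == pytest.approx(
        expected, abs=1e-12
    )


def test_normalize_rejects_non_finite_with_index():
    arr = np.zeros((2, 3))
    arr[1, 2] = np.nan
    with pytest.raises(ValueError, match=r"\(1, 2\)"):
        normalize_intensity(arr, CLINICAL)


def test_denormalize_endpoints_and_out_of_range():
    assert denormalize_intensity(np.array([1.0]), CLINICAL)[0] == 2500.0
    assert denormalize_intensity(np.array([-1.0]), MICRO)[0] == 0.0
    with pytest.raises(ValueError, match="outside"):
        denormalize_intensity(np.array([1.1]), CLINICAL)


@pytest.mark.parametrize("domain", [CLINICAL, MICRO])
def test_normalize_denormalize_round_trip_on_grid(domain):
    # both directions, exercised over a dense grid of the normalized range
    grid = np.linspace(-1.0, 1.0, 101)
    native = denormalize_intensity(grid, domain)
    assert np.allclose(normalize_intensity(native, domain), grid, atol=1e-12)
    native_grid = np.linspace(domain.clip_low, domain.clip_high, 101)
    back = denormalize_intensity(normalize_intensity(native_grid, domain), domain)
    assert np.allclose(back, native_grid, atol=1e-9)


def test_intensity_domain_validates_bounds():
    with pytest.raises(ValueError):
        IntensityDomain(DomainName.CLINICAL, 10.0, -10.0)


# -------------------------------------------------------------- f-down/f-up


def test_average_pool_block_means_and_errors():
    assert average_pool_downsample(np.array([[0.0, 1.0], [1.0, 0.0]]), 2) == pytest.approx(
        np.array([[0.5]])
    )
    const = np.full((8, 8), 0.37)
    assert np.allclose(average_pool_downsample(const, 4), 0.37)
    with pytest.raises(ValueError, match="divisible"):
        average_pool_downsample(np.zeros((6, 6)), 4)


def test_nearest_upsample_replication_and_identity():
    assert np.array_equal(
        nearest_upsample(np.array([[3.0]]), 2), np.array([[3.0, 3.0], [3.0, 3.0]])
    )
    img = np.arange(9.0).reshape(3, 3)
    assert np.array_equal(nearest_upsample(img, 1), img)
    with pytest.raises(ValueError):
        nearest_upsample(img, 0)


@pytest.mark.parametrize("r", [2, 4, 8])
def test_pool_after_nearest_upsample_is_identity(rng, r):
    x = rng.uniform(-1, 1, (4, 4))
    assert np.allclose(average_pool_downsample(nearest_upsample(x, r), r), x, atol=1e-12)


def test_upsample_then_pool_not_identity_on_checkerboard():
    x = np.array([[1.0, -1.0], [-1.0, 1.0]])
    assert not np.allclose(nearest_upsample(average_pool_downsample(x, 2), 2), x)


def test_nearest_upsample_composition(rng):
    x = rng.uniform(-1, 1, (3, 3))
    assert np.array_equal(
        nearest_upsample(nearest_upsample(x, 2), 3), nearest_upsample(x, 6)
    )


def test_operators_preserve_mean_and_range(rng):
    x = rng.uniform(-1, 1, (8, 8))
    for out in (average_pool_downsample(x, 2), nearest_upsample(x, 3)):
        assert out.mean() == pytest.approx(x.mean(), abs=1e-12)
        assert out.min() >= -1.0 and out.max() <= 1.0


# ------------------------------------------------------------------ bicubic


def test_bicubic_preserves_constants_and_validates():
    const = np.full((6, 6), -0.25)
    for shape in [(6, 6), (13, 9), (3, 24)]:
        assert np.allclose(bicubic_resample(const, shape), -0.25, atol=1e-12)
    with pytest.raises(ValueError):
        bicubic_resample(const, (0, 4))


def test_bicubic_interior_sample_uses_exactly_16_pixels():
    """Perturbing any pixel of the 4x4 neighbourhood moves an interior output
    sample; pixels outside it leave the sample unchanged."""
    n = 12
    base = np.zeros((n, n))
    out_shape = (2 * n, 2 * n)
    oy, ox = n, n  # interior output sample
    ref = bicubic_resample(base, out_shape)[oy, ox]
    src = (oy + 0.5) * n / (2 * n) - 0.5
    base_idx = int(np.floor(src))
    support = range(base_idx - 1, base_idx + 3)
    touched = set()
    for iy in range(n):
        for ix in range(n):
            img = base.copy()
            img[iy, ix] = 1.0
            if bicubic_resample(img, out_shape)[oy, ox] != ref:
                touched.add((iy, ix))
    assert touched == {(iy, ix) for iy in support for ix in support}
    assert len(touched) == 16


def test_bicubic_reproduces_linear_ramp_interior():
    n = 16
    ramp = np.outer(np.linspace(0, 1, n), np.ones(n))
    up = bicubic_resample(ramp, (2 * n, 2 * n))
    expect = (np.arange(2 * n) + 0.5) / 2 - 0.5  # source coordinate of each row
    expect = np.interp(expect, np.arange(n), ramp[:, 0])
    interior = slice(4, -4)
    assert np.allclose(up[interior, 8], expect[interior], atol=1e-6)


def test_bicubic_matches_direct_weighted_sum_oracle(rng):
    """Interior samples equal an independently coded 4x4 Keys weighted sum."""
    img = rng.uniform(-1, 1, (10, 10))
    out = bicubic_resample(img, (25, 17))
    for oy, ox in [(12, 8), (10, 5), (13, 10)]:
        sy = (oy + 0.5) * 10 / 25 - 0.5
        sx = (ox + 0.5) * 10 / 17 - 0.5
        by, bx = int(np.floor(sy)), int(np.floor(sx))
        acc = 0.0
        for dy in range(-1, 3):
            for dx in range(-1, 3):
                wy = _keys_kernel(np.array([sy - (by + dy)]))[0]
                wx = _keys_kernel(np.array([sx - (bx + dx)]))[0]
                acc += wy * wx * img[by + dy, bx + dx]
        assert out[oy, ox] == pytest.approx(acc, abs=1e-10)


# ---------------------------------------------------------------- lung mask


def _body_phantom():
    """Disk of soft tissue (0 H.U.) holding two lung ellipses (-800 H.U.)
    with small +100 H.U. vessel inclusions; air (-1000) outside the body."""
    n = 64
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    vol = np.full((4, n, n), -1000.0)
    truth = np.zeros((4, n, n), dtype=bool)
    body = (yy - 32) ** 2 + (xx - 32) ** 2 <= 28**2
    for z in range(4):
        sl = np.full((n, n), -1000.0)
        sl[body] = 0.0
        lungs = np.zeros((n, n), dtype=bool)
        for cx in (20, 44):
            lung = ((yy - 32) / 14) ** 2 + ((xx - cx) / 9) ** 2 <= 1.0
            lungs |= lung
        sl[lungs] = -800.0
        for cx in (20, 44):  # vessel inside each lung
            vessel = (yy - 32) ** 2 + (xx - cx) ** 2 <= 2**2
            sl[vessel] = 100.0
        vol[z] = sl
        truth[z] = lungs
    return CTVolume(vol, (1.0, 1.0, 1.0), CLINICAL), truth


def test_lung_mask_recovers_lungs_including_vessel_holes():
    vol, truth = _body_phantom()
    mask = lung_mask(vol)
    assert mask.data.shape == vol.shape
    assert np.array_equal(mask.data, truth)


def test_lung_mask_all_air_raises():
    vol = CTVolume(np.full((4, 16, 16), -1000.0), (1, 1, 1), CLINICAL)
    with pytest.raises(ValueError, match="no lung region"):
        lung_mask(vol)


def test_lung_mask_idempotent_under_second_fill():
    from scipy import ndimage

    vol, _ = _body_phantom()
    mask = lung_mask(vol).data
    refilled = np.stack([ndimage.binary_fill_holes(sl) for sl in mask])
    assert np.array_equal(mask, refilled)


def test_lung_mask_rejects_micro_domain():
    vol = CTVolume(np.zeros((2, 16, 16)), (1, 1, 1), MICRO)
    with pytest.raises(ValueError, match="CLINICAL"):
        lung_mask(vol)


# ----------------------------------------------------------- patch sampling


def test_extract_patches_count_shape_and_determinism():
    vol = CTVolume(
        np.random.default_rng(0).uniform(-1000, 2500, (3, 64, 64)),
        (1, 1, 1),
        CLINICAL,
    )
    patches = extract_patches(vol, size=32, n=50, seed=11)
    assert len(patches) == 50
    assert all(p.shape == (32, 32) for p in patches)
    assert all(p.normalized and np.abs(p.data).max() <= 1.0 for p in patches)
    again = extract_patches(vol, size=32, n=50, seed=11)
    assert all(
        np.array_equal(a.data, b.data) and a.meta == b.meta
        for a, b in zip(patches, again)
    )


def test_extract_patches_respects_mask_coverage():
    vol = CTVolume(np.zeros((2, 32, 32)), (1, 1, 1), CLINICAL)
    mask = np.zeros((2, 32, 32), dtype=bool)
    mask[:, :20, :] = True  # top band only
    patches = extract_patches(vol, size=8, n=100, seed=3, mask=BinaryMask(mask))
    for p in patches:
        y = p.meta["y"]
        cov = mask[p.meta["z"], y : y + 8, p.meta["x"] : p.meta["x"] + 8].mean()
        assert cov >= 0.5


def test_extract_patches_impossible_mask_raises():
    vol = CTVolume(np.zeros((1, 16, 16)), (1, 1, 1), CLINICAL)
    with pytest.raises(RuntimeError, match="acceptance rate"):
        extract_patches(
            vol, size=8, n=2, seed=0, mask=BinaryMask(np.zeros((1, 16, 16), bool))
        )


def test_all_true_mask_matches_unmasked_distribution():
    """An all-true mask must not bias position sampling (chi-square check)."""
    vol = CTVolume(np.zeros((1, 12, 12)), (1, 1, 1), CLINICAL)
    full = BinaryMask(np.ones((1, 12, 12), bool))
    n = 10_000
    masked = extract_patches(vol, size=8, n=n, seed=21, mask=full)
    plain = extract_patches(vol, size=8, n=n, seed=21)
    # identical seed and acceptance-free sampling => identical positions
    assert [p.meta for p in masked] == [p.meta for p in plain]
    # and positions are uniform over the 5x5 grid of valid top-lefts
    counts = np.zeros(25)
    for p in plain:
        counts[p.meta["y"] * 5 + p.meta["x"]] += 1
    chi2 = ((counts - n / 25) ** 2 / (n / 25)).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=24)


def test_extract_patches_validation():
    vol = CTVolume(np.zeros((1, 16, 16)), (1, 1, 1), CLINICAL)
    with pytest.raises(ValueError, match="does not fit"):
        extract_patches(vol, size=32, n=1, seed=0)
    with pytest.raises(ValueError, match="n must be"):
        extract_patches(vol, size=8, n=0, seed=0)
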