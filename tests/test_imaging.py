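"""I/O round-trips, resampling, discretisation and sphere rasterisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctrad import (
    GridSpec,
    ROIMask,
    VoxelImage,
    discretize_fixed_bin_width,
    make_spherical_mask,
    read_mask,
    read_volume,
    resample_slice_thickness,
    write_mask,
    write_volume,
)


# ------------------------------------------------------------------- I/O ----

@pytest.mark.parametrize("suffix", [".nii", ".nii.gz", ".nrrd"])
def test_volume_round_trip(tmp_path, suffix):
    rng = np.random.default_rng(0)
    img = VoxelImage(rng.normal(size=(8, 8, 8)), (0.26, 0.3, 0.3), (1.0, 2.0, 3.0))
    path = tmp_path / f"vol{suffix}"
    write_volume(img, path)
    back = read_volume(path)
    np.testing.assert_allclose(back.values, img.values, rtol=1e-12)
    np.testing.assert_allclose(back.spacing, img.spacing, rtol=1e-6)
    np.testing.assert_allclose(back.origin, img.origin, atol=1e-6)


def test_nrrd_and_nifti_agree(tmp_path):
    rng = np.random.default_rng(1)
    img = VoxelImage(rng.normal(size=(6, 7, 8)), (0.26, 0.26, 0.26))
    write_volume(img, tmp_path / "a.nrrd")
    write_volume(img, tmp_path / "a.nii.gz")
    a = read_volume(tmp_path / "a.nrrd")
    b = read_volume(tmp_path / "a.nii.gz")
    np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
    np.testing.assert_allclose(a.spacing, b.spacing, rtol=1e-6)


def test_nifti_cross_checked_against_nibabel(tmp_path):
    nib = pytest.importorskip("nibabel")
    rng = np.random.default_rng(2)
    img = VoxelImage(rng.normal(size=(5, 6, 7)), (0.5, 0.4, 0.3))
    path = tmp_path / "x.nii"
    write_volume(img, path)
    loaded = nib.load(str(path))
    # nibabel axis order is (x, y, z) = reversed from ours
    np.testing.assert_allclose(np.transpose(loaded.get_fdata(), (2, 1, 0)), img.values, rtol=1e-6)
    np.testing.assert_allclose(sorted(loaded.header.get_zooms()), sorted(img.spacing), rtol=1e-6)


def test_mask_round_trip_stays_binary(tmp_path):
    rng = np.random.default_rng(3)
    mask = ROIMask(rng.random((8, 8, 8)) > 0.5, (0.26, 0.26, 0.26))
    write_mask(mask, tmp_path / "m.nrrd")
    back = read_mask(tmp_path / "m.nrrd")
    assert back.values.dtype == bool
    np.testing.assert_array_equal(back.values, mask.values)


def test_non_positive_spacing_rejected(tmp_path):
    # hand-written NRRD with a zero spacing entry
    path = tmp_path / "bad.nrrd"
    header = (
        "NRRD0004\n"
        "type: float\n"
        "dimension: 3\n"
        "sizes: 2 2 2\n"
        "spacings: 0 1 1\n"
        "encoding: ascii\n"
        "\n"
    )
    path.write_text(header + " ".join(["1.0"] * 8) + "\n")
    with pytest.raises(ValueError, match="spacing"):
        read_volume(path)


def test_constructor_invariants():
    with pytest.raises(ValueError):
        VoxelImage(np.zeros((4, 4, 4)), (0.26, -1.0, 0.26))
    with pytest.raises(ValueError):
        VoxelImage(np.full((4, 4, 4), np.nan), (0.26, 0.26, 0.26))
    with pytest.raises(ValueError):
        ROIMask(np.full((4, 4, 4), 2), (0.26, 0.26, 0.26))
    with pytest.raises(ValueError):
        GridSpec((0, 4, 4))


# ------------------------------------------------------------ resampling ----

def test_identity_resample_is_noop():
    rng = np.random.default_rng(4)
    img = VoxelImage(rng.normal(size=(10, 6, 6)), (0.26, 0.26, 0.26))
    out = resample_slice_thickness(img, 0.26)
    np.testing.assert_array_equal(out.values, img.values)
    assert out.spacing == img.spacing


def test_constant_image_stays_constant_at_any_thickness():
    img = VoxelImage(np.full((20, 6, 6), 3.5), (0.26, 0.26, 0.26))
    for t in (0.2, 0.3, 0.5, 1.0):
        out = resample_slice_thickness(img, t)
        np.testing.assert_allclose(out.values, 3.5, rtol=1e-12)
        assert out.spacing[0] == t
        assert out.spacing[1:] == img.spacing[1:]


@pytest.mark.parametrize("n,old,new", [(64, 0.26, 0.5), (64, 0.26, 0.2), (64, 0.26, 1.0), (31, 0.26, 0.3)])
def test_slice_count_follows_extent_rounding(n, old, new):
    img = VoxelImage(np.zeros((n, 4, 4)), (old, 0.26, 0.26))
    out = resample_slice_thickness(img, new)
    assert out.values.shape[0] == round(n * old / new)


def test_mask_resampling_preserves_binarity_and_extent():
    rng = np.random.default_rng(5)
    img = VoxelImage(rng.normal(size=(40, 8, 8)), (0.26, 0.26, 0.26))
    mask = ROIMask(rng.random((40, 8, 8)) > 0.6, (0.26, 0.26, 0.26))
    out_img, out_mask = resample_slice_thickness(img, 0.5, mask)
    assert set(np.unique(out_mask.values.astype(int))) <= {0, 1}
    assert out_img.values.shape == out_mask.values.shape
    # same physical extent within one voxel
    assert abs(out_img.values.shape[0] * 0.5 - 40 * 0.26) <= 0.5


def test_resample_rejects_non_positive_thickness():
    img = VoxelImage(np.zeros((4, 4, 4)), (0.26, 0.26, 0.26))
    with pytest.raises(ValueError):
        resample_slice_thickness(img, 0.0)


# --------------------------------------------------------- discretisation ----

def test_fixed_bin_width_example():
    d = discretize_fixed_bin_width(np.array([0.0, 24.0, 25.0, 49.0, 100.0]), 25.0)
    np.testing.assert_array_equal(d.levels, [1, 1, 2, 2, 5])
    assert d.n_levels == 5


def test_constant_roi_single_level():
    d = discretize_fixed_bin_width(np.full(10, 7.3), 25.0)
    assert d.n_levels == 1
    assert set(d.levels) == {1}


def test_finer_bins_give_at_least_as_many_levels():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 100, size=500)
    n10 = discretize_fixed_bin_width(x, 10.0).n_levels
    n100 = discretize_fixed_bin_width(x, 100.0).n_levels
    assert n10 >= n100


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    shift=st.floats(-1e4, 1e4, allow_nan=False),
    seed=st.integers(0, 1000),
    bw=st.sampled_from([10.0, 25.0, 50.0, 100.0]),
)
def test_discretisation_translation_covariant(shift, seed, bw):
    """Adding a constant to all intensities leaves the levels unchanged."""
    x = np.random.default_rng(seed).normal(0, 120, size=60)
    a = discretize_fixed_bin_width(x, bw)
    b = discretize_fixed_bin_width(x + shift, bw)
    np.testing.assert_array_equal(a.levels, b.levels)
    assert a.n_levels == b.n_levels


def test_discretisation_rejects_bad_input():
    with pytest.raises(ValueError):
        discretize_fixed_bin_width(np.array([]), 25.0)
    with pytest.raises(ValueError):
        discretize_fixed_bin_width(np.array([1.0, np.inf]), 25.0)
    with pytest.raises(ValueError):
        discretize_fixed_bin_width(np.array([1.0]), 0.0)


# ------------------------------------------------------------- spheres ----

@pytest.mark.parametrize("volume", [27.68, 34.38, 41.71, 92.24, 94.25, 237.5])
def test_sphere_volume_within_5pct_at_standard_spacing(volume):
    grid = GridSpec((96, 96, 96))
    mask = make_spherical_mask(grid, grid.center, volume)
    assert abs(mask.volume_mm3 - volume) / volume < 0.05


def test_sphere_voxel_count_matches_enumeration():
    """r = 2 on unit spacing: count voxel centres with ||c|| <= 2 by brute force."""
    grid = GridSpec((11, 11, 11), spacing=(1.0, 1.0, 1.0))
    r = 2.0
    volume = 4.0 / 3.0 * np.pi * r**3
    mask = make_spherical_mask(grid, (5.0, 5.0, 5.0), volume)
    count = sum(
        1
        for i in range(11)
        for j in range(11)
        for k in range(11)
        if (i - 5) ** 2 + (j - 5) ** 2 + (k - 5) ** 2 <= r**2 + 1e-12
    )
    assert mask.voxel_count == count == 33


def test_sphere_volume_converges_with_spacing():
    v = 42.0
    err = []
    for sp in (0.5, 0.1):
        n = int(10 / sp)
        grid = GridSpec((n, n, n), spacing=(sp, sp, sp))
        mask = make_spherical_mask(grid, grid.center, v)
        err.append(abs(mask.volume_mm3 - v) / v)
    assert err[1] < err[0]
    assert err[1] < 0.01


def test_sub_voxel_sphere_rejected():
    grid = GridSpec((10, 10, 10), spacing=(2.0, 2.0, 2.0))
    with pytest.raises(ValueError, match="minimum"):
        make_spherical_mask(grid, (5.0, 5.0, 5.0), 0.5)
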