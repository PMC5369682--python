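"""Distance maps, tumor prior, STD/SLIC planes, θ-band mask, assembly."""

import numpy as np
import pytest

import oculoseg as oc
from oculoseg.features import (
    FeatureConfig,
    anisotropic_diffusion,
    assemble_features,
    boundary_voxels,
    compute_slic_features,
    compute_std_features,
    compute_tumor_prior,
    compute_vh_mask,
    distance_to_boundary,
    von_neumann_mean,
)
from oculoseg.volume import EyeLabelMap, MultiChannelVolume


def brute_force_distance(region, spacing):
    b = np.array(np.nonzero(boundary_voxels(region))).T * spacing
    grid = np.indices(region.shape).reshape(3, -1).T * spacing
    return np.sqrt(((grid[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min(1).reshape(region.shape)


class TestDistanceFeatures:
    def test_boundary_voxels_are_zero(self):
        region = np.zeros((8, 8, 8), bool)
        region[2:6, 2:6, 2:6] = True
        d = distance_to_boundary(region, np.ones(3))
        assert np.all(d[boundary_voxels(region)] == 0)

    def test_single_boundary_voxel_axis_distance(self):
        region = np.zeros((8, 8, 8), bool)
        region[0, 0, 0] = True
        d = distance_to_boundary(region, np.ones(3))
        assert d[0, 0, 3] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_8cubed(self, seed):
        rng = np.random.default_rng(seed)
        region = rng.random((8, 8, 8)) < 0.4
        if not region.any():
            region[4, 4, 4] = True
        spacing = rng.uniform(0.3, 1.5, 3)
        np.testing.assert_allclose(
            distance_to_boundary(region, spacing),
            brute_force_distance(region, spacing),
            atol=1e-9,
        )

    def test_lipschitz_in_mm(self, clean_case):
        from oculoseg.features import compute_distance_features
        f_l, f_vh = compute_distance_features(clean_case.labels)
        sp = clean_case.labels.spacing
        for f in (f_l, f_vh):
            for axis in range(3):
                diff = np.abs(np.diff(f, axis=axis))
                assert diff.max() <= sp[axis] + 1e-9

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            boundary_voxels(np.zeros((4, 4, 4), bool))


class TestTumorPrior:
    def test_single_mask_no_smoothing_identity(self):
        m = np.zeros((10, 10, 10), bool)
        m[3:6, 3:6, 3:6] = True
        prior = compute_tumor_prior([m], np.ones(3), sigma_mm=0)
        np.testing.assert_array_equal(prior, m.astype(float))

    def test_three_of_four_is_075(self):
        m1 = np.zeros((6, 6, 6), bool)
        m1[2, 2, 2] = True
        masks = [m1, m1, m1, np.zeros_like(m1)]
        prior = compute_tumor_prior(masks, np.ones(3), sigma_mm=0)
        assert prior[2, 2, 2] == pytest.approx(0.75)

    def test_smoothing_conserves_interior_mass(self):
        m = np.zeros((40, 40, 40), bool)
        m[17:23, 17:23, 17:23] = True
        raw = compute_tumor_prior([m], np.ones(3), sigma_mm=0)
        smooth = compute_tumor_prior([m], np.ones(3), sigma_mm=3.0)
        assert abs(smooth.sum() - raw.sum()) / raw.sum() < 0.01

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        masks = [rng.random((8, 8, 8)) < 0.3 for _ in range(4)]
        a = compute_tumor_prior(masks, np.ones(3))
        b = compute_tumor_prior(masks[::-1], np.ones(3))
        np.testing.assert_array_equal(a, b)

    def test_identical_masks_indicator(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:4, 2:4, 2:4] = True
        prior = compute_tumor_prior([m] * 5, np.ones(3), sigma_mm=0)
        assert set(np.unique(prior)) <= {0.0, 1.0}

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            compute_tumor_prior([np.zeros((4, 4, 4)), np.zeros((5, 5, 5))], np.ones(3))


class TestStdFeatures:
    def test_constant_volume_constant_neighbors(self):
        vol = MultiChannelVolume(
            {"T1": np.full((12, 12, 12), 5.0), "T2": np.full((12, 12, 12), 9.0)}
        )
        planes = compute_std_features(vol)
        for name in ("nbr_t1", "nbr_t2", "nbr_at1"):
            np.testing.assert_allclose(planes[name], planes[name.replace("nbr_", "")][0, 0, 0])

    def test_center_excluded_from_neighbor_mean(self):
        arr = np.zeros((9, 9, 9))
        arr[4, 4, 4] = 6.0
        nbr = von_neumann_mean(arr)
        assert nbr[4, 4, 4] == 0.0
        for d in ((3, 4, 4), (5, 4, 4), (4, 3, 4), (4, 5, 4), (4, 4, 3), (4, 4, 5)):
            assert nbr[d] == pytest.approx(1.0)

    def test_diffusion_edge_preserving_on_clean_phantom(self, clean_case):
        t1 = clean_case.volume.channels["T1"]
        at1 = anisotropic_diffusion(t1, clean_case.volume.spacing)
        interior = (clean_case.labels.data == oc.LABEL_VH)
        from scipy import ndimage
        interior = ndimage.binary_erosion(interior, iterations=2)
        # noise-free piecewise-constant input is nearly a fixed point inside regions
        assert np.abs(at1 - t1)[interior].mean() < 1.0


class TestSlicFeatures:
    def test_constant_slices(self):
        vol = MultiChannelVolume(
            {"T1": np.full((24, 24, 4), 3.0), "T2": np.full((24, 24, 4), 8.0)}
        )
        planes = compute_slic_features(vol)
        np.testing.assert_allclose(planes["slic_t1"], 3.0)
        np.testing.assert_allclose(planes["slic_t2"], 8.0)

    def test_two_half_contrast_adherence(self):
        t1 = np.zeros((40, 40, 2))
        t1[20:, :, :] = 100.0
        vol = MultiChannelVolume({"T1": t1, "T2": t1.copy()})
        planes = compute_slic_features(vol)
        # away from the boundary each voxel keeps its half's intensity ±5%
        assert np.all(np.abs(planes["slic_t1"][:15]) <= 5.0)
        assert np.all(np.abs(planes["slic_t1"][25:] - 100.0) <= 5.0)

    def test_superpixel_density(self):
        # structured slice (disk + shell): superpixel count ~ area / size^2
        rng = np.random.default_rng(1)
        x, y = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        r = np.sqrt((x - 32) ** 2 + (y - 32) ** 2)
        t1 = np.where(r < 16, 160.0, np.where(r < 19, 60.0, 25.0)) + rng.normal(0, 10, (64, 64))
        t2 = np.where(r < 16, 60.0, np.where(r < 19, 110.0, 25.0)) + rng.normal(0, 10, (64, 64))
        vol = MultiChannelVolume({"T1": t1[:, :, None], "T2": t2[:, :, None]})
        planes = compute_slic_features(vol)
        n = len(np.unique(planes["slic_t1"]))
        target = (64 * 64) / 100
        assert target / 2 <= n <= target * 2


class TestVhMask:
    def test_theta_zero_is_vh_exactly(self, clean_case):
        vh = clean_case.labels.data == oc.LABEL_VH
        mask = compute_vh_mask(vh, clean_case.labels.spacing, 0.0)
        np.testing.assert_array_equal(mask, vh)

    def test_theta_two_band_bounded(self, clean_case):
        vh = clean_case.labels.data == oc.LABEL_VH
        mask = compute_vh_mask(vh, clean_case.labels.spacing, 2.0)
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(~vh, sampling=clean_case.labels.spacing)
        extra = mask & ~vh
        assert np.all(dist[extra] <= 2.0)
        assert np.all(mask[vh])

    def test_monotone_in_theta(self, clean_case):
        vh = clean_case.labels.data == oc.LABEL_VH
        m1 = compute_vh_mask(vh, clean_case.labels.spacing, 1.0)
        m2 = compute_vh_mask(vh, clean_case.labels.spacing, 2.0)
        assert np.all(m2[m1])


class TestAssemble:
    def _planes(self, shape=(6, 6, 6)):
        rng = np.random.default_rng(0)
        std = {n: rng.random(shape) for n in ("t1", "t2", "at1", "nbr_t1", "nbr_t2", "nbr_at1")}
        slic = {n: rng.random(shape) for n in ("slic_t1", "slic_t2")}
        epsf = {n: rng.random(shape) for n in ("f_l", "f_vh", "f_t")}
        return std, slic, epsf

    def test_std_only_8_columns(self):
        std, slic, _ = self._planes()
        stack = assemble_features(std, slic, None, np.ones((6, 6, 6), bool), np.ones(3), use_epsf=False)
        assert stack.matrix().shape[1] == 8

    def test_epsf_11_columns(self):
        std, slic, epsf = self._planes()
        stack = assemble_features(std, slic, epsf, np.ones((6, 6, 6), bool), np.ones(3), use_epsf=True)
        assert stack.matrix().shape[1] == 11
        assert stack.feature_order[-3:] == ("f_l", "f_vh", "f_t")

    def test_empty_mask_zero_rows(self):
        std, slic, epsf = self._planes()
        stack = assemble_features(std, slic, epsf, np.zeros((6, 6, 6), bool), np.ones(3))
        assert stack.matrix().shape == (0, 11)

    def test_mismatched_grid_rejected(self):
        std, slic, epsf = self._planes()
        epsf["f_t"] = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="mismatched"):
            assemble_features(std, slic, epsf, np.ones((6, 6, 6), bool), np.ones(3))


def test_feature_stack_h5_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    shape = (6, 6, 6)
    std = {n: rng.random(shape) for n in ("t1", "t2", "at1", "nbr_t1", "nbr_t2", "nbr_at1")}
    slic = {n: rng.random(shape) for n in ("slic_t1", "slic_t2")}
    epsf = {n: rng.random(shape) for n in ("f_l", "f_vh", "f_t")}
    mask = rng.random(shape) < 0.5
    stack = assemble_features(std, slic, epsf, mask, np.array([0.5, 0.6, 0.7]))
    stack.save(tmp_path / "stack.h5")
    loaded = oc.FeatureStack.load(tmp_path / "stack.h5")
    assert loaded.feature_order == stack.feature_order
    np.testing.assert_array_equal(loaded.mask, stack.mask)
    np.testing.assert_array_equal(loaded.matrix(), stack.matrix())
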