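"""VMHC core, map comparison, VCC leave-one-out, difference map, enrichment."""

import numpy as np
import pytest

import homokappa as hk
from homokappa.vmhc import R_CLIP


def _map_pair(grid, x, y):
    a = hk.VoxelMap(grid, x, "kappa")
    b = hk.VoxelMap(grid, y, "fisher_z")
    return hk.ComparisonInput(a, b, np.ones(grid.shape, bool))


def _line_grid(n):
    return hk.VolumeGrid.symmetric((n, 1, 1), 2.0)


class TestVmhc:
    def test_self_mirror_series_clipped_not_infinite(self, grid_odd):
        spec = hk.RestSpec(n_timepoints=40, homotopic_rho=1.0, seed=0)
        data = hk.gen_rest_timeseries(spec, grid_odd)
        z = hk.vmhc(data, grid_odd)
        off_mid = (grid_odd.world_x() != 0)
        vals = z.values[off_mid][z.grid.mask[off_mid]]
        assert np.isfinite(vals).all()
        assert np.allclose(vals, np.arctanh(R_CLIP))

    def test_output_is_exactly_symmetric(self, grid20, rng):
        data = rng.normal(size=grid20.shape + (60,))
        z = hk.vmhc(data, grid20)
        perm = grid20.mirror_permutation()
        assert np.array_equal(z.values, z.values[perm, :, :])
        assert np.array_equal(z.grid.mask, z.grid.mask[perm, :, :])

    def test_constant_series_set_missing(self, grid20, rng):
        data = rng.normal(size=grid20.shape + (30,))
        data[3, 4, 5, :] = 7.0
        z = hk.vmhc(data, grid20)
        perm = grid20.mirror_permutation()
        assert not z.grid.mask[3, 4, 5]
        assert not z.grid.mask[perm[3], 4, 5]  # its mirror too

    def test_fisher_z_of_known_r(self):
        assert abs(hk.fisher_z(np.array(0.5)) - 0.5493061443340549) < 1e-12

    def test_too_few_timepoints_rejected(self, grid20):
        with pytest.raises(ValueError):
            hk.vmhc(np.zeros(grid20.shape + (2,)), grid20)


class TestGroupAverage:
    def test_identical_maps_average_to_themselves(self, grid20, rng):
        m = hk.VoxelMap(grid20, rng.normal(size=grid20.shape), "fisher_z")
        out = hk.group_average([m, m, m])
        np.testing.assert_allclose(out.values, m.values)

    def test_opposite_maps_cancel(self, grid20, rng):
        v = rng.normal(size=grid20.shape)
        out = hk.group_average([hk.VoxelMap(grid20, v, "fisher_z"),
                                hk.VoxelMap(grid20, -v, "fisher_z")])
        assert np.abs(out.values).max() < 1e-15

    def test_matches_brute_force_mean(self, grid20, rng):
        maps = [hk.VoxelMap(grid20, rng.normal(size=grid20.shape), "fisher_z")
                for _ in range(5)]
        out = hk.group_average(maps)
        brute = np.mean([m.values for m in maps], axis=0)
        assert np.abs(out.values - brute).max() <= 1e-15

    def test_partial_masks_counted_per_voxel(self, grid20, rng):
        v1, v2 = rng.normal(size=(2,) + grid20.shape)
        m1 = hk.VoxelMap(grid20, v1, "fisher_z")
        half = np.zeros(grid20.shape, bool)
        half[:10] = True
        m2 = hk.VoxelMap(grid20.with_mask(half), v2, "fisher_z")
        out = hk.group_average([m1, m2])
        np.testing.assert_allclose(out.values[:10], (v1[:10] + v2[:10]) / 2)
        np.testing.assert_allclose(out.values[10:], v1[10:])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            hk.group_average([])


class TestZScore:
    def test_mean_zero_sd_one(self, grid20, rng):
        m = hk.VoxelMap(grid20, rng.normal(3.0, 5.0, size=grid20.shape))
        z = hk.zscore_map(m)
        assert abs(z.masked_values().mean()) < 1e-12
        assert abs(z.masked_values().std() - 1.0) < 1e-12

    def test_affine_invariance(self, grid20, rng):
        v = rng.normal(size=grid20.shape)
        z1 = hk.zscore_map(hk.VoxelMap(grid20, v))
        z2 = hk.zscore_map(hk.VoxelMap(grid20, 2.5 * v + 7.0))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-12)

    def test_constant_map_rejected(self, grid20):
        with pytest.raises(ValueError, match="variance"):
            hk.zscore_map(hk.VoxelMap(grid20, np.full(grid20.shape, 3.0)))


class TestMapCorrelation:
    def test_self_correlation_is_one(self, grid20, rng):
        v = rng.normal(size=grid20.shape)
        ci = _map_pair(grid20, v, v)
        assert abs(hk.map_correlation(ci) - 1.0) < 1e-12

    def test_negation_gives_minus_one(self, grid20, rng):
        v = rng.normal(size=grid20.shape)
        assert abs(hk.map_correlation(_map_pair(grid20, v, -v)) + 1.0) < 1e-12

    def test_matches_two_pass_formula(self, grid20, rng):
        x = rng.normal(size=grid20.shape)
        y = rng.normal(size=grid20.shape)
        r = hk.map_correlation(_map_pair(grid20, x, y))
        xf, yf = x.ravel(), y.ravel()
        ref = (((xf - xf.mean()) * (yf - yf.mean())).sum()
               / np.sqrt(((xf - xf.mean()) ** 2).sum()
                         * ((yf - yf.mean()) ** 2).sum()))
        assert abs(r - ref) < 1e-12

    def test_out_of_mask_voxels_never_influence(self, grid20, rng):
        x = rng.normal(size=grid20.shape)
        y = rng.normal(size=grid20.shape)
        mask = rng.random(grid20.shape) > 0.5
        a = hk.VoxelMap(grid20, x, "kappa")
        b = hk.VoxelMap(grid20, y, "fisher_z")
        r1 = hk.map_correlation(hk.ComparisonInput(a, b, mask))
        x2, y2 = x.copy(), y.copy()
        x2[~mask] = 1e6  # garbage outside the mask
        y2[~mask] = -1e6
        r2 = hk.map_correlation(hk.ComparisonInput(
            hk.VoxelMap(grid20, x2, "kappa"),
            hk.VoxelMap(grid20, y2, "fisher_z"), mask))
        assert r1 == r2


class TestVcc:
    def test_perfect_correlation_gives_zero_deltas(self):
        grid = _line_grid(10)
        x = np.arange(10.0).reshape(-1, 1, 1)
        res = hk.vcc(hk.ComparisonInput(
            hk.VoxelMap(grid, x, "kappa"),
            hk.VoxelMap(grid, 2 * x + 1, "fisher_z"),
            np.ones(grid.shape, bool)))
        assert abs(res.r_global - 1.0) < 1e-12
        assert np.abs(res.raw_delta).max() < 1e-9

    def test_downdating_equals_naive_recomputation(self, rng):
        grid = _line_grid(5)
        x = rng.normal(size=(5, 1, 1))
        y = rng.normal(size=(5, 1, 1))
        res = hk.vcc(_map_pair(grid, x, y))
        xf, yf = x.ravel(), y.ravel()
        for i in range(5):
            keep = np.ones(5, bool)
            keep[i] = False
            naive = res.r_global - np.corrcoef(xf[keep], yf[keep])[0, 1]
            assert abs(res.raw_delta[i] - naive) < 1e-12

    def test_extreme_discordant_voxel_most_negative(self, rng):
        grid = _line_grid(50)
        x = rng.normal(size=50)
        y = x + 0.1 * rng.normal(size=50)
        x[17], y[17] = 4.0, -4.0  # one strongly discordant voxel pair
        res = hk.vcc(_map_pair(grid, x.reshape(-1, 1, 1),
                               y.reshape(-1, 1, 1)))
        assert np.argmin(res.map.values[:, 0, 0]) == 17

    def test_normalized_values_are_zscores(self, grid20, rng):
        res = hk.vcc(_map_pair(grid20, rng.normal(size=grid20.shape),
                               rng.normal(size=grid20.shape)))
        vals = res.map.values[res.map.grid.mask]
        assert abs(vals.mean()) < 1e-10
        assert abs(vals.std() - 1.0) < 1e-10


class TestDifferenceMap:
    def test_identical_maps_give_zero(self, grid20, rng):
        v = rng.normal(size=grid20.shape)
        d = hk.difference_map(_map_pair(grid20, v, v.copy()))
        assert np.abs(d.values).max() < 1e-12

    def test_negated_second_map_doubles_zscore(self, grid20, rng):
        v = rng.normal(size=grid20.shape)
        ci = _map_pair(grid20, v, -v)
        d = hk.difference_map(ci)
        z = hk.zscore_map(hk.VoxelMap(grid20, v))
        np.testing.assert_allclose(d.values, 2 * z.values, atol=1e-12)

    def test_antisymmetry(self, grid20, rng):
        x = rng.normal(size=grid20.shape)
        y = rng.normal(size=grid20.shape)
        d1 = hk.difference_map(_map_pair(grid20, x, y))
        d2 = hk.difference_map(_map_pair(grid20, y, x))
        np.testing.assert_allclose(d1.values, -d2.values, atol=1e-12)


class TestRoiAndEnrichment:
    def test_strict_threshold(self, grid20):
        v = np.zeros(grid20.shape)
        v[0, 0, 0], v[1, 0, 0], v[2, 0, 0] = 0.5, 1.0, 1.5
        roi = hk.threshold_to_roi(hk.VoxelMap(grid20, v), cutoff=1.0)
        assert roi.sum() == 1 and roi[2, 0, 0]

    def test_below_max_cutoff_empty(self, grid20, rng):
        v = 0.9 * rng.random(grid20.shape)
        assert hk.threshold_to_roi(hk.VoxelMap(grid20, v), 1.0).sum() == 0

    def test_disjoint_manual_mask_empties_roi(self, grid20):
        v = np.zeros(grid20.shape)
        v[2, 2, 2] = 5.0
        manual = np.zeros(grid20.shape, bool)
        manual[10:, :, :] = True
        roi = hk.threshold_to_roi(hk.VoxelMap(grid20, v), 1.0, manual)
        assert roi.sum() == 0

    def test_concentrated_domain_top_ranked(self, grid20, rng):
        roi = np.zeros(grid20.shape, bool)
        roi[2:5, 2:5, 2:5] = True
        inside = grid20.voxel_to_world(np.argwhere(roi))
        outside = grid20.voxel_to_world(np.argwhere(~roi))
        foci = np.vstack([
            inside[rng.integers(0, len(inside), 30)],       # domain "motor"
            outside[rng.integers(0, len(outside), 300)],    # others
        ])
        domains = ["motor"] * 30 + ["language"] * 150 + ["memory"] * 150
        df = hk.domain_enrichment(roi, foci, domains, grid20)
        assert df.iloc[0]["domain"] == "motor"
        assert df.iloc[0]["z"] > 3.0
        # the other domains were drawn strictly outside: depleted, negative z
        assert (df[df.domain != "motor"]["z"] < 0).all()

    def test_roi_covering_all_foci_is_degenerate(self, grid20, rng):
        roi = np.ones(grid20.shape, bool)
        foci = grid20.voxel_to_world(rng.integers(0, 20, size=(20, 3)))
        with pytest.raises(ValueError, match="base rate"):
            hk.domain_enrichment(roi, foci, ["a"] * 10 + ["b"] * 10, grid20)

    def test_domain_at_base_rate_has_small_z(self, grid20, rng):
        roi = np.zeros(grid20.shape, bool)
        roi[:10] = True  # half the volume
        all_vox = grid20.voxel_to_world(np.argwhere(np.ones(grid20.shape,
                                                            bool)))
        foci = all_vox[rng.integers(0, len(all_vox), 400)]
        domains = ["a"] * 200 + ["b"] * 200
        df = hk.domain_enrichment(roi, foci, domains, grid20)
        assert np.abs(df["z"]).max() < 3.0
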