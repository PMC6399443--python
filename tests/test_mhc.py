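"""Activation matrix, contingency tables, Patel's kappa, MC significance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homokappa as hk
from homokappa.mhc import ContingencyTheta, _kappa_vectorized


def kappa_reference(n11, n10, n01, n00):
    """Independent literal transcription of the corrected kappa formula.

    Kept free of any shared code with the implementation under test.
    """
    n = n11 + n10 + n01 + n00
    t1, t2, t3, t4 = n11 / n, n10 / n, n01 / n, n00 / n
    E = (t1 + t2) * (t1 + t3)
    max_t1 = min(t1 + t2, t1 + t3)
    min_t1 = max(0.0, 2.0 * t1 + t2 + t3 - 1.0)
    D = 1.0 if t1 >= E else 0.0
    den = D * (max_t1 - E) + (1.0 - D) * (E - min_t1)
    if den == 0.0:
        return math.nan
    return (t1 - E) / den


counts_strategy = st.tuples(*(st.integers(0, 200),) * 4).filter(
    lambda c: sum(c) > 0)


class TestActivationMatrix:
    def _ma(self, grid, n_active, region_voxels):
        """MA map with exactly n_active positive voxels inside a region."""
        vals = np.zeros(grid.shape)
        for idx in region_voxels[:n_active]:
            vals[tuple(idx)] = 0.5
        return hk.VoxelMap(grid, vals, "MA_probability")

    @pytest.fixture
    def region50(self, grid20):
        """Single-pair atlas whose left region has exactly 50 voxels."""
        labels = np.zeros(grid20.shape, dtype=np.int32)
        coords = [(i, j, k) for i in range(2, 4) for j in range(5, 10)
                  for k in range(5, 10)]
        for c in coords:
            labels[c] = 1
        perm = grid20.mirror_permutation()
        labels = np.maximum(labels, 2 * labels[perm, :, :])
        atlas = hk.Parcellation(grid20, labels, pairs=[(1, 2)])
        assert atlas.region_size(1) == 50
        return atlas, np.array(coords)

    @pytest.mark.parametrize("n_active,threshold,expected", [
        (10, 0.20, 1),   # 10/50 = 20%: boundary is inclusive
        (9, 0.20, 0),    # 18% < 20%
        (1, 0.0, 1),     # threshold 0: a single voxel activates the region
        (0, 0.0, 0),
        (20, 0.40, 1),
        (19, 0.40, 0),
    ])
    def test_fractional_rule_boundaries(self, region50, n_active, threshold,
                                        expected):
        atlas, coords = region50
        m = self._ma(atlas.grid, n_active, coords)
        am = hk.activation_matrix([m], atlas, fraction_threshold=threshold)
        assert am.column(1)[0] == expected

    def test_streaming_matches_batch(self, spaced_atlas):
        spec = hk.CoactivationSpec(np.array([0.3, 0.1, 0.1, 0.5]), 50, seed=5)
        coll = hk.gen_coactivation_experiments(spec, spaced_atlas)
        k = hk.KernelSpec()
        mas = [hk.ma_map(e, spaced_atlas.grid, k) for e in coll]
        batch = hk.activation_matrix(mas, spaced_atlas,
                                     experiment_ids=[e.experiment_id
                                                     for e in coll])
        stream = hk.activation_matrix_from_foci(coll, spaced_atlas, k)
        assert np.array_equal(batch.values, stream.values)


class TestContingency:
    def _matrix(self, a, b):
        v = np.stack([a, b], axis=1)
        ids = [f"e{i}" for i in range(len(a))]
        return hk.ActivationMatrix(v, ids, [1, 2], 0.2)

    def test_direct_arithmetic(self):
        c = ContingencyTheta((30, 10, 10, 50))
        np.testing.assert_allclose(c.thetas, [0.30, 0.10, 0.10, 0.50])
        assert abs(c.E - 0.16) < 1e-15
        assert abs(c.theta1_max - 0.40) < 1e-15
        assert c.theta1_min == 0.0
        assert c.D == 1

    def test_identical_columns_have_no_discordance(self, rng):
        a = rng.integers(0, 2, size=40)
        c = hk.contingency(self._matrix(a, a), (1, 2))
        assert c.counts[1] == c.counts[2] == 0

    def test_complementary_columns_have_no_concordance(self, rng):
        a = rng.integers(0, 2, size=40)
        c = hk.contingency(self._matrix(a, 1 - a), (1, 2))
        assert c.counts[0] == c.counts[3] == 0


class TestPatelKappa:
    @pytest.mark.parametrize("theta,expected", [
        ((0.5, 0.0, 0.0, 0.5), 1.0),                 # perfect co-activation
        ((0.16, 0.24, 0.24, 0.36), 0.0),             # theta1 = E exactly
        ((0.30, 0.10, 0.10, 0.50), 0.14 / 0.24),     # corrected formula
        ((0.0, 0.5, 0.5, 0.0), -1.0),                # perfect avoidance
    ])
    def test_closed_form_examples(self, theta, expected):
        assert abs(hk.kappa_from_theta(theta) - expected) < 1e-12

    def test_degenerate_marginal_is_flagged_missing(self):
        # region a always active: marginal 1, denominator vanishes
        c = ContingencyTheta((30, 20, 0, 0))
        assert c.degenerate
        assert math.isnan(hk.patel_kappa(c))

    def test_kappa_spans_exactly_unit_interval_at_fixed_marginals(self):
        """Scan all joint tables with marginals p_a = p_b = 0.4: kappa must
        sweep exactly [-1, 1] from maximal avoidance to maximal overlap."""
        t1s = np.linspace(0.0, 0.4, 401)
        ks = [hk.kappa_from_theta((t1, 0.4 - t1, 0.4 - t1, 0.2 + t1))
              for t1 in t1s]
        assert abs(min(ks) - (-1.0)) < 1e-12
        assert abs(max(ks) - 1.0) < 1e-12
        assert (np.diff(ks) > 0).all()  # monotone in theta1

    @settings(max_examples=300, derandomize=True)
    @given(counts=counts_strategy)
    def test_bounds_and_reference_equivalence(self, counts):
        c = ContingencyTheta(counts)
        k = hk.patel_kappa(c)
        ref = kappa_reference(*counts)
        if math.isnan(ref) or c.degenerate:
            assert math.isnan(k)
        else:
            assert abs(k - ref) < 1e-12
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        assert c.theta1_min - 1e-12 <= c.thetas[0] <= c.theta1_max + 1e-12

    def test_kappa_one_iff_theta1_attains_max(self):
        assert hk.kappa_from_theta((0.3, 0.0, 0.0, 0.7)) == 1.0
        # theta3 = 0 means b=1 implies a=1: theta1 already at its maximum
        assert hk.kappa_from_theta((0.3, 0.01, 0.0, 0.69)) == 1.0
        assert hk.kappa_from_theta((0.3, 0.01, 0.01, 0.68)) < 1.0


class TestSignificance:
    def test_posterior_concentrates_for_strong_coactivation(self):
        res = hk.kappa_significance(ContingencyTheta((500, 0, 0, 500)),
                                    e=0.5, n_mc=10_000, seed=1)
        assert res.posterior_prob_exceeds > 0.99
        assert res.significant

    def test_posterior_near_half_at_independence(self):
        res = hk.kappa_significance(ContingencyTheta((160, 240, 240, 360)),
                                    e=0.0, n_mc=10_000, seed=2)
        assert abs(res.posterior_prob_exceeds - 0.5) < 0.1
        assert not res.significant

    def test_same_seed_reproduces_posterior(self):
        c = ContingencyTheta((30, 10, 10, 50))
        a = hk.kappa_significance(c, n_mc=2000, seed=7)
        b = hk.kappa_significance(c, n_mc=2000, seed=7)
        assert a.posterior_prob_exceeds == b.posterior_prob_exceeds


class TestMapAndTable:
    def _results(self, atlas, kappas):
        out = {}
        for pair, k in zip(atlas.pairs, kappas):
            kk = 0.05 if math.isnan(k) else k
            n11 = max(int(round(50 * max(kk, 0.05))), 1)
            c = ContingencyTheta((n11, 10, 10, 50))
            out[pair] = hk.KappaResult(k, 0.9, 0.0, 100, 0, k > 0.5,
                                       contingency=c)
        return out

    def test_map_paints_pair_constant_values(self, packed_atlas):
        res = self._results(packed_atlas, [0.8, 0.1, float("nan"), 0.4])
        m = hk.mhc_map(res, packed_atlas)
        vals = {round(float(v), 6) for v in np.unique(m.values[m.grid.mask])}
        assert vals == {0.8, 0.1, 0.4}
        # missing pair rendered as background, outside the mask
        missing_region = np.isin(packed_atlas.labels, packed_atlas.pairs[2])
        assert not m.grid.mask[missing_region].any()
        # per-region constancy
        l0 = packed_atlas.pairs[0][0]
        assert np.allclose(m.values[packed_atlas.labels == l0], 0.8)

    def test_map_equals_own_mirror(self, packed_atlas):
        res = self._results(packed_atlas, [0.8, 0.1, 0.3, 0.4])
        m = hk.mhc_map(res, packed_atlas)
        mm = hk.mirror_x(m)
        assert np.array_equal(m.values, mm.values)
        assert np.array_equal(m.grid.mask, mm.grid.mask)

    def test_table_sorted_and_round_trips(self, packed_atlas, tmp_path):
        res = self._results(packed_atlas, [0.8, 0.1, 0.3, float("nan")])
        df = hk.region_kappa_table(res, packed_atlas)
        assert len(df) == 4
        finite = df["kappa"].dropna()
        assert (finite.diff().dropna() <= 0).all()  # descending
        assert df["kappa"].isna().iloc[-1]          # missing pair flagged last
        path = tmp_path / "kappa.tsv"
        hk.write_kappa_table(df, path)
        back = hk.read_kappa_table(path)
        np.testing.assert_allclose(back["kappa"].to_numpy()[:3],
                                   df["kappa"].to_numpy()[:3], atol=1e-12)


class TestEstimatorClosure:
    def test_kappa_recovered_from_generated_matrices(self, spaced_atlas):
        """Generator/estimator closure: activation matrices built from drawn
        joint states give kappa-hat close to kappa(theta)."""
        theta = np.array([0.3, 0.1, 0.1, 0.5])
        true_k = hk.kappa_from_theta(theta)
        errs = []
        for seed in range(10):
            spec = hk.CoactivationSpec(theta, 2000, seed=seed)
            _, states = hk.gen_coactivation_experiments(
                spec, spaced_atlas, return_states=True)
            active = np.zeros((2000, 16), dtype=np.uint8)
            for p in range(8):
                active[:, 2 * p] = np.isin(states[:, p], (0, 1))
                active[:, 2 * p + 1] = np.isin(states[:, p], (0, 2))
            am = hk.ActivationMatrix(
                active, [f"e{i}" for i in range(2000)],
                [l for pair in spaced_atlas.pairs for l in pair], 0.2)
            ks = [hk.patel_kappa(hk.contingency(am, pair))
                  for pair in spaced_atlas.pairs]
            errs.append(abs(np.mean(ks) - true_k))
        assert np.mean(np.asarray(errs) < 0.05) >= 0.95
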