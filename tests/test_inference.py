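"""Permutation machinery: exchangeability, GPD tails, spin assignments,
FDR and the cross-scale contrast."""

import numpy as np
import pandas as pd
import pytest
from itertools import permutations

import hetmap as h
from hetmap.inference import (_surrogate_index, gpd_tail_pvalues, moran_i,
                              permutation_mean_difference_p, random_rotation,
                              spin_permutation_pool)


class TestFDR:
    def test_hand_computed_bh(self):
        flags = h.fdr_correct(np.array([0.001, 0.02, 0.03, 0.9]), q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_and_single_p(self):
        assert not h.fdr_correct(np.ones(5)).any()
        assert h.fdr_correct(np.array([0.04])).all()
        assert h.fdr_correct(np.array([])).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            h.fdr_correct(np.array([0.0, 0.5]))


class TestGroupPermutation:
    def test_two_vs_two_matches_exhaustive(self):
        # one region, cases {1,1}, controls {0,0}: upper p = 1/6
        p_exact = permutation_mean_difference_p(np.array([1.0, 1.0]),
                                                np.array([0.0, 0.0]))
        assert p_exact == pytest.approx(1 / 6)
        res = h.group_permutation_test(np.array([[1.0], [1.0]]),
                                       np.array([[0.0], [0.0]]),
                                       n_perm=4000, seed=0, gpd=False)
        # two-tailed MC estimate doubles the one-sided 1/6
        assert res.p_unc[0] == pytest.approx(1 / 3, abs=0.04)

    def test_identical_groups_not_significant(self):
        x = np.tile([0.2, 0.4], (6, 1))
        res = h.group_permutation_test(x, x, n_perm=300, seed=1, gpd=False)
        assert (res.p_unc >= 0.5).all()

    def test_super_uniform_under_exchangeable_null(self):
        rng = np.random.default_rng(2)
        scores = rng.random((40, 300)) < 0.3
        res = h.group_permutation_test(scores[:20].astype(float),
                                       scores[20:].astype(float),
                                       n_perm=500, seed=3, gpd=False)
        for alpha in (0.01, 0.05, 0.2):
            assert (res.p_unc <= alpha).mean() <= alpha + 0.03

    def test_seed_reproducibility_bit_for_bit(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(10, 20)); b = rng.normal(size=(12, 20))
        r1 = h.group_permutation_test(a, b, n_perm=300, seed=7)
        r2 = h.group_permutation_test(a, b, n_perm=300, seed=7)
        assert np.array_equal(r1.p_unc, r2.p_unc)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            h.group_permutation_test(np.zeros((0, 2)), np.zeros((3, 2)))

    def test_fdr_flags_subset_of_uncorrected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(15, 50)) + 0.5
        res = h.group_permutation_test(a, rng.normal(size=(15, 50)),
                                       n_perm=500, seed=8, gpd=False)
        assert not (res.p_fdr_flags & ~res.sig_unc).any()


class TestGPDTail:
    def test_median_uses_empirical_branch(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=5000)
        p = h.gpd_tail_pvalue(null, float(np.median(null)), seed=0)
        assert p == pytest.approx(0.5, abs=0.03)

    def test_below_all_nulls_is_one(self):
        null = np.random.default_rng(1).normal(size=1000)
        assert h.gpd_tail_pvalue(null, null.min() - 5, seed=0) > 0.99

    def test_exponential_tail_extrapolation(self):
        # Exp(1) exceedances are exactly GPD(shape 0, scale 1):
        # p(12) should be within a factor of 10 of exp(-12)
        null = np.random.default_rng(2).exponential(size=10_000)
        p = h.gpd_tail_pvalue(null, 12.0, seed=0)
        truth = np.exp(-12.0)
        assert truth / 10 < p < truth * 10

    def test_continuity_at_tail_threshold(self):
        null = np.random.default_rng(3).normal(size=4000)
        obs = float(np.quantile(null, 0.905))
        p_gpd = h.gpd_tail_pvalue(null, obs, seed=0)
        p_emp = (1 + (null >= obs).sum()) / (len(null) + 1)
        assert p_gpd == pytest.approx(p_emp, rel=0.25)

    def test_small_samples_fall_back_to_empirical(self):
        null = np.arange(50.0)
        p = h.gpd_tail_pvalue(null, 49.5)
        assert p == pytest.approx(1 / 51)


class TestSpin:
    def test_identity_rotation_gives_identity(self, small_scheme):
        _, cl = small_scheme.cortical_coords("L")
        _, cr = small_scheme.cortical_coords("R")
        pi = h.spin_rotation_assignment(cl, cr, rotation=np.eye(3))
        assert np.array_equal(pi, np.arange(len(cl) + len(cr)))

    def test_polar_halfturn_swaps_antipodal_equatorial_points(self):
        # 4 equatorial points at 0/90/180/270 degrees; 180-degree rotation
        # about z maps each onto its antipode
        ang = np.deg2rad([0, 90, 180, 270])
        pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(4)])
        rot = np.diag([-1.0, -1.0, 1.0])
        mirror = np.diag([-1.0, 1.0, 1.0])
        pi = h.spin_rotation_assignment(pts, pts @ mirror.T, rotation=rot)
        expected_left = np.array([2, 3, 0, 1])
        assert np.array_equal(pi[:4], expected_left)
        # oracle: brute force over all 4! matchings of rotated onto original
        rotated = pts @ rot.T
        best, best_cost = None, np.inf
        for perm in permutations(range(4)):
            cost = sum(np.linalg.norm(rotated[i] - pts[perm[i]]) for i in range(4))
            if cost < best_cost:
                best, best_cost = perm, cost
        inv = np.empty(4, int)
        inv[list(best)] = np.arange(4)
        assert np.array_equal(pi[:4], inv)

    def test_unequal_hemispheres_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            h.spin_rotation_assignment(np.eye(3), np.eye(3)[:2], seed=0)

    def test_values_multiset_preserved(self, small_scheme):
        _, cl = small_scheme.cortical_coords("L")
        _, cr = small_scheme.cortical_coords("R")
        rng = np.random.default_rng(6)
        values = rng.normal(size=len(cl) + len(cr))
        for s in range(5):
            pi = h.spin_rotation_assignment(cl, cr, seed=s)
            assert np.allclose(np.sort(values[pi]), np.sort(values))

    def test_surrogate_rows_are_permutations(self, small_scheme):
        cpos, pool = spin_permutation_pool(small_scheme, 20, seed=0)
        spos = np.flatnonzero(~small_scheme.is_cortex())
        rng = np.random.default_rng(1)
        idx = _surrogate_index(cpos, spos, pool,
                               rng.integers(0, 20, size=8), rng)
        n = small_scheme.n_regions
        for row in idx:
            assert np.array_equal(np.sort(row), np.arange(n))

    def test_surrogate_autocorrelation_preserved(self, labelled_scheme):
        """Spin surrogates keep Moran's I of a patchy cortical map within 20%."""
        ids, coords = labelled_scheme.cortical_coords("L")
        net = labelled_scheme.regions.loc[ids, "network10"]
        rng = np.random.default_rng(7)
        patchy = (net == "DM").to_numpy().astype(float) + rng.normal(0, 0.1, len(ids))
        i_obs = moran_i(patchy, coords)
        sur = []
        for s in range(40):
            rot = random_rotation(rng)
            pi = h.spin_rotation_assignment(coords, coords @ np.diag([-1., 1., 1.]).T,
                                            rotation=rot)[:len(ids)]
            sur.append(moran_i(patchy[pi], coords))
        assert abs(np.mean(sur) - i_obs) <= 0.2 * abs(i_obs)


class TestSpatialNullTest:
    def test_burden_preserved_and_deterministic(self, small_fit, small_scheme):
        dmap = small_fit["dmap"]
        groups = dmap.groups
        cases = groups.str.startswith("case:").to_numpy()
        hc = (groups == "HC_test").to_numpy()
        r1 = h.spatial_null_test(dmap.z, small_scheme, cases, hc,
                                 downstream="regional", n_perm=200, seed=9, gpd=False,
                                 keep_null=True)
        r2 = h.spatial_null_test(dmap.z, small_scheme, cases, hc,
                                 downstream="regional", n_perm=200, seed=9, gpd=False,
                                 keep_null=True)
        assert np.array_equal(r1.p_unc, r2.p_unc)
        # burden preservation: every null draw keeps the group burden total,
        # so the region-summed delta is constant across permutations
        total = r1.null.sum(axis=1)
        assert np.allclose(total, total[0], atol=1e-9)

    def test_requires_circuit_matrix(self, small_fit, small_scheme):
        dmap = small_fit["dmap"]
        cases = dmap.groups.str.startswith("case:").to_numpy()
        hc = (dmap.groups == "HC_test").to_numpy()
        with pytest.raises(ValueError, match="circuit matrix"):
            h.spatial_null_test(dmap.z, small_scheme, cases, hc,
                                downstream="circuit", n_perm=50, gpd=False)


class TestCrossScale:
    def test_identical_levels_give_zero_contrast(self):
        rng = np.random.default_rng(8)
        maps = pd.DataFrame(rng.random((20, 10)) < 0.3)
        res = h.crossscale_contrast(maps, maps, np.arange(20) < 10,
                                    np.arange(20) >= 10, n_perm=200, seed=0, gpd=False)
        assert np.allclose(res.observed, 0.0)
        assert (res.p_unc >= 0.5).all()

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(9)
        E = pd.DataFrame(rng.random((20, 10)) < 0.2)
        U = pd.DataFrame((rng.random((20, 10)) < 0.5) | E.to_numpy())
        cases = np.arange(20) < 10
        a = h.crossscale_contrast(E, U, cases, ~cases, n_perm=100, seed=1, gpd=False)
        b = h.crossscale_contrast(E, U, ~cases, cases, n_perm=100, seed=1, gpd=False)
        assert np.allclose(a.observed, -b.observed)
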