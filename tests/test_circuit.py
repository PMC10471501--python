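"""Circuit mapping: seed FC, group t, graph TFCE (with brute-force oracle),
sign-flip FWE thresholding, parcellation and union maps."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import hetmap as h
from hetmap.circuit import _capped_t
from hetmap.tfce import tfce_enhance


def path_graph(n):
    a = sp.lil_matrix((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a.tocsr()


class TestSeedFC:
    def test_exact_half_correlation(self):
        rng = np.random.default_rng(0)
        T = 400
        a = rng.standard_normal(T)
        b = rng.standard_normal(T)
        a = (a - a.mean()) / a.std()
        # Gram-Schmidt: construct a series with exact correlation 0.5 to a
        b = b - (b @ a) / (a @ a) * a
        b = (b - b.mean()) / b.std()
        y = 0.5 * a + np.sqrt(1 - 0.25) * b
        ts = np.vstack([a, y])
        fz = h.seed_fc_map(ts, seed_grays=np.array([0]))
        assert fz[1] == pytest.approx(np.arctanh(0.5), abs=1e-6)
        assert np.arctanh(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_self_correlation_clamped_not_infinite(self):
        t = np.linspace(0, 1, 100)
        ts = np.vstack([np.sin(7 * t), np.sin(7 * t)])
        with pytest.warns(UserWarning, match="clamped"):
            fz = h.seed_fc_map(ts, seed_grays=np.array([0]))
        assert np.isfinite(fz).all() and fz[1] > 10

    def test_zero_variance_seed_rejected(self):
        ts = np.vstack([np.ones(50), np.random.default_rng(1).standard_normal(50)])
        with pytest.raises(ValueError, match="zero-variance"):
            h.seed_fc_map(ts, seed_grays=np.array([0]))


class TestGroupT:
    def test_hand_computed_value(self):
        t = h.group_t_map(np.array([[1.0], [2.0], [3.0]]))
        assert t[0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-4)
        assert t[0] == pytest.approx(3.4641, abs=1e-4)

    def test_symmetric_values_give_zero(self):
        assert h.group_t_map(np.array([[1.0], [-1.0]]))[0] == 0.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            h.group_t_map(np.array([[1.0, 2.0]]))

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning, match="infinity"):
            t = h.group_t_map(np.array([[1.0, 0.0], [1.0, 0.0]]))
        assert t[0] == np.inf and t[1] == 0.0


class TestTFCE:
    def test_all_zero_map(self):
        out = tfce_enhance(np.zeros(5), path_graph(5))
        assert np.allclose(out, 0.0)

    def test_isolated_node_closed_form(self):
        # dh * sum_{h in .1..1.0} h^2 * 1^0.5 = 0.1 * 3.85 = 0.385
        out = tfce_enhance(np.array([1.0]), sp.csr_matrix((1, 1)), dh=0.1)
        assert out[0] == pytest.approx(0.385, abs=1e-9)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_bruteforce_on_path_graph(self, trial):
        rng = np.random.default_rng(trial)
        stat = rng.uniform(0, 2, size=6)
        dh = 0.05
        got = tfce_enhance(stat, path_graph(6), E=0.5, H=2.0, dh=dh)
        # oracle: explicit component labelling at every height
        expected = np.zeros(6)
        kmax = int(np.floor(stat.max() / dh + 1e-9))
        for k in range(1, kmax + 1):
            hgt = k * dh
            supra = stat >= hgt - 1e-12
            labels = -np.ones(6, int)
            cur = 0
            for i in range(6):
                if supra[i] and labels[i] < 0:
                    j = i
                    while j < 6 and supra[j]:
                        labels[j] = cur
                        j += 1
                    cur += 1
            for i in range(6):
                if supra[i]:
                    ext = (labels == labels[i]).sum()
                    expected[i] += dh * ext ** 0.5 * hgt ** 2
        assert np.allclose(got, expected, atol=1e-9)

    def test_invalid_dh(self):
        with pytest.raises(ValueError):
            tfce_enhance(np.ones(3), path_graph(3), dh=-0.1)


class TestFWE:
    def test_all_zero_maps_nothing_significant(self):
        Z = np.zeros((8, 10))
        res = h.fwe_binarize(Z, path_graph(10), n_perm=100, seed=0)
        assert not res["significant"].any()

    def test_null_maps_control_family_wise_error(self):
        rng = np.random.default_rng(1)
        adj = path_graph(40)
        n_any = 0
        for k in range(20):
            Z = rng.standard_normal((10, 40)) * 0.3
            res = h.fwe_binarize(Z, adj, n_perm=200, seed=k)
            n_any += res["significant"].any()
        # FWE alpha=0.025: P(>=4 families with a hit out of 20) ~ 1e-5
        assert n_any <= 3

    def test_coupled_network_detected_beyond_seed(self, small_scheme):
        atlas = h.make_fc_atlas(small_scheme, n_subjects=15, T=200,
                                community_strength=0.9, seed=2)
        seed_region = int(small_scheme.region_ids[0])
        circ = h.compute_circuit(atlas, small_scheme, seed_region, n_perm=300, seed=3)
        net = small_scheme.regions["network10"]
        members = net[net == net.loc[seed_region]].index
        hits = [r for r in members if r != seed_region
                and circ.regions[small_scheme.regions.index.get_loc(r)]]
        assert circ.regions[small_scheme.regions.index.get_loc(seed_region)] == 1
        assert len(hits) >= 1

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            h.fwe_binarize(np.random.default_rng(0).standard_normal((5, 8)),
                           path_graph(8), n_perm=30, seed=0)


class TestParcellate:
    def test_fraction_rule_is_strict(self):
        lookup = np.array([1, 1, 1, 1])
        gray = np.array([True, True, True, False])  # 3 of 4 survive
        assert h.parcellate_binary(gray, lookup, np.array([1]), frac=0.5)[0] == 1
        assert h.parcellate_binary(gray, lookup, np.array([1]), frac=0.75)[0] == 0

    def test_empty_map_gives_zero_vector(self):
        out = h.parcellate_binary(np.zeros(6, bool), np.repeat([1, 2], 3),
                                  np.array([1, 2]))
        assert out.sum() == 0

    def test_region_without_grayordinates_rejected(self):
        with pytest.raises(ValueError, match="region 9"):
            h.parcellate_binary(np.zeros(3, bool), np.array([1, 1, 1]),
                                np.array([1, 9]))


class TestUnionAndOverlap:
    @staticmethod
    def _cache():
        m = pd.DataFrame(0, index=pd.Index([1, 2, 3], name="seed_region"),
                         columns=[1, 2, 3, 4, 5], dtype=np.int8)
        m.loc[1, [1, 2]] = 1
        m.loc[2, [4, 5]] = 1
        m.loc[3, [1, 5]] = 1
        return h.CircuitCache(m)

    def test_empty_and_identity(self):
        cache = self._cache()
        assert h.union_map([], cache).sum() == 0
        assert np.array_equal(h.union_map([2], cache), cache.circuit(2))

    def test_disjoint_union_size(self):
        u = h.union_map([1, 2], self._cache())
        assert u.sum() == 4  # circuits of sizes 2 and 2, disjoint

    def test_union_monotone_in_seeds(self):
        cache = self._cache()
        u12 = h.union_map([1, 2], cache)
        u123 = h.union_map([1, 2, 3], cache)
        assert (u123 >= u12).all()

    def test_missing_circuit_named(self):
        with pytest.raises(KeyError, match="99"):
            h.union_map([99], self._cache())

    def test_circuit_overlap_mean(self):
        u = pd.DataFrame([[1, 0], [1, 1], [1, 0], [0, 0]], columns=[1, 2])
        omap = h.circuit_overlap(u, "g", "negative")
        assert omap.values.tolist() == [0.75, 0.25]

    def test_cache_determinism(self, small_scheme, small_atlas):
        seeds = small_scheme.region_ids[:4]
        a = h.compute_circuit_cache(small_atlas, small_scheme, seeds, n_perm=150, seed=5)
        b = h.compute_circuit_cache(small_atlas, small_scheme, seeds, n_perm=150, seed=5)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)

    def test_cache_roundtrip(self, tmp_path):
        cache = self._cache()
        cache.write(tmp_path / "cache.tsv")
        back = h.CircuitCache.read(tmp_path / "cache.tsv")
        pd.testing.assert_frame_equal(back.matrix, cache.matrix)

    def test_circuit_overlap_dominates_regional_when_selfcoupled(self, dissociation_bundle):
        """If every circuit contains its own seed, each union map contains the
        extreme-indicator map, so circuit overlap >= regional overlap."""
        b = dissociation_bundle
        cache = b["cache"]
        C = cache.as_array(b["scheme"].region_ids)
        assert np.diagonal(C).all()  # every seed couples to itself
        data = b["circuit_convergent"]
        ext = data["dmap"].neg_extreme
        unions = h.union_maps_for_group(ext, cache)
        assert (unions.to_numpy() >= ext.to_numpy()).all()
        cases = data["case_mask"]
        reg = h.overlap_map(ext[cases]).values
        cir = h.circuit_overlap(unions[cases]).values
        assert (cir >= reg - 1e-12).all()
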