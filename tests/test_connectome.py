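"""Connection-weight construction, re-normalization, nodal metrics,
hemisphere flipping and subnetwork grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from strokeconn.connectome import (
    ROI, ConnectomeSet, Parcellation, build_matrices, flip_hemispheres,
    group_subnetworks, node_metrics, resample_cw,
)
from strokeconn.tracking import Streamline


def fiber(a, b, length, fa=0.5):
    pts = np.array([[0.0, 0, 0], [length, 0.0, 0.0]])
    return Streamline(points=pts, mean_fa=fa, endpoint_labels=(a, b))


class TestBuildMatrices:
    def test_single_fiber_hand_value(self, toy_parcellation):
        cs = build_matrices([fiber(1, 2, 2.0)], toy_parcellation)
        assert cs.cw_matrix[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_two_fiber_hand_value(self):
        parc = Parcellation((
            ROI(1, "a", "L", "cortical", 2.0, "SMA", 2),
            ROI(2, "b", "R", "cortical", 2.0, "SMA", 1),
        ))
        cs = build_matrices([fiber(1, 2, 1.0), fiber(1, 2, 2.0)], parc)
        assert cs.cw_matrix[0, 1] == pytest.approx(0.75, abs=1e-15)

    def test_no_fibers_gives_structural_zero(self, toy_parcellation):
        cs = build_matrices([fiber(1, 2, 2.0)], toy_parcellation)
        assert cs.cw_matrix[2, 3] == 0 and cs.count_matrix[2, 3] == 0

    def test_zero_length_fiber_rejected_and_counted(self, toy_parcellation):
        bad = Streamline(points=np.zeros((2, 3)), endpoint_labels=(1, 2))
        cs = build_matrices([bad, fiber(1, 2, 2.0)], toy_parcellation)
        assert cs.meta["n_zero_length_rejected"] == 1
        assert cs.count_matrix[0, 1] == 1

    def test_brute_force_oracle_agreement(self, toy_parcellation, rng):
        # independent accumulation fiber by fiber
        fibers = []
        for _ in range(200):
            a, b = rng.choice([1, 2, 3, 4], size=2, replace=False)
            fibers.append(fiber(int(a), int(b), float(rng.uniform(0.5, 10)),
                                fa=float(rng.uniform(0.1, 0.9))))
        cs = build_matrices(fibers, toy_parcellation)
        n = 4
        expected = np.zeros((n, n))
        S = toy_parcellation.surface_sizes
        idx = {r.label: i for i, r in enumerate(toy_parcellation.rois)}
        for f in fibers:
            i, j = idx[f.endpoint_labels[0]], idx[f.endpoint_labels[1]]
            expected[i, j] += (2.0 / (S[i] + S[j])) / f.length
            expected[j, i] += (2.0 / (S[i] + S[j])) / f.length
        np.testing.assert_allclose(cs.cw_matrix, expected, rtol=1e-12, atol=0)

    def test_doubling_surfaces_halves_cw(self, rng):
        fibers = [fiber(1, 2, float(l)) for l in rng.uniform(1, 5, size=20)]
        p1 = Parcellation((ROI(1, "a", "L", "cortical", 1.0, "SMA", 2),
                           ROI(2, "b", "R", "cortical", 1.0, "SMA", 1)))
        p2 = Parcellation((ROI(1, "a", "L", "cortical", 2.0, "SMA", 2),
                           ROI(2, "b", "R", "cortical", 2.0, "SMA", 1)))
        c1, c2 = build_matrices(fibers, p1), build_matrices(fibers, p2)
        assert c2.cw_matrix[0, 1] == pytest.approx(c1.cw_matrix[0, 1] / 2, rel=1e-15)

    def test_doubling_lengths_halves_cw(self, toy_parcellation, rng):
        lengths = rng.uniform(1, 5, size=20)
        c1 = build_matrices([fiber(1, 2, float(l)) for l in lengths], toy_parcellation)
        c2 = build_matrices([fiber(1, 2, float(2 * l)) for l in lengths], toy_parcellation)
        assert c2.cw_matrix[0, 1] == pytest.approx(c1.cw_matrix[0, 1] / 2, rel=1e-14)


class TestResampleCW:
    def test_three_value_quantiles(self):
        m = np.zeros((3, 3))
        m[0, 1], m[0, 2], m[1, 2] = 0.1, 5.0, 7.0
        m = m + m.T
        out = resample_cw(m)
        got = np.sort([out[0, 1], out[0, 2], out[1, 2]])
        want = 0.5 + 0.1 * sps.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert got[0] == pytest.approx(0.4033, abs=5e-5)
        assert got[2] == pytest.approx(0.5967, abs=5e-5)

    def test_median_maps_to_half_and_mean_exact(self, rng):
        n = 7   # 21 upper-triangle edges: odd count, so a median exists
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.lognormal(size=len(iu[0]))
        m[iu] = vals
        m = m + m.T
        out = resample_cw(m)
        tv = out[iu]
        assert tv[np.argsort(vals)[len(vals) // 2]] == pytest.approx(0.5, abs=1e-12)
        assert tv.mean() == pytest.approx(0.5, abs=1e-12)

    def test_rank_order_strictly_preserved(self, rng):
        n = 15
        iu = np.triu_indices(n, 1)
        m = np.zeros((n, n))
        m[iu] = rng.lognormal(size=len(iu[0]))
        m = m + m.T
        out = resample_cw(m)
        order_in = np.argsort(m[iu])
        order_out = np.argsort(out[iu])
        assert np.array_equal(order_in, order_out)

    def test_sd_converges_to_point_one(self, rng):
        n = 40   # 780 edges
        iu = np.triu_indices(n, 1)
        m = np.zeros((n, n))
        m[iu] = rng.lognormal(size=len(iu[0]))
        m = m + m.T
        sd = resample_cw(m)[iu].std(ddof=1)
        assert abs(sd - 0.1) / 0.1 < 0.02

    def test_zeros_stay_zero_and_symmetry(self, rng):
        n = 8
        iu = np.triu_indices(n, 1)
        m = np.zeros((n, n))
        vals = rng.lognormal(size=len(iu[0]))
        vals[::3] = 0.0
        m[iu] = vals
        m = m + m.T
        out = resample_cw(m)
        assert np.array_equal(out != 0, m != 0)
        assert np.array_equal(out, out.T)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6,
                              allow_nan=False), min_size=6, max_size=28,
                    unique=True))
    def test_transform_preserves_order_and_centers(self, vals):
        """For any untied positive weights: rank order preserved, values
        symmetric around 0.5, mean exactly 0.5."""
        k = len(vals)
        n = int(np.ceil((1 + np.sqrt(1 + 8 * k)) / 2))
        iu = np.triu_indices(n, 1)
        m = np.zeros((n, n))
        full = np.zeros(len(iu[0]))
        full[:k] = vals
        m[iu] = full
        m = m + m.T
        out = resample_cw(m)[iu][:k]
        assert np.array_equal(np.argsort(out), np.argsort(vals))
        assert out.mean() == pytest.approx(0.5, abs=1e-9)
        assert np.all(out > 0.5 - 0.1 * 6) and np.all(out < 0.5 + 0.1 * 6)

    def test_all_equal_degenerates_to_half(self, caplog):
        m = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        m[iu] = 3.0
        m = m + m.T
        out = resample_cw(m)
        assert np.all(out[iu] == 0.5)

    def test_too_few_edges_raise(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        with pytest.raises(ValueError):
            resample_cw(m)


class TestNodeMetrics:
    def test_row_sums(self, toy_parcellation):
        fa = np.zeros((4, 4))
        fa[0, 1], fa[0, 2] = 0.5, 0.3
        fa = fa + fa.T
        cs = ConnectomeSet("s", fa, (fa != 0).astype(int), (fa != 0) * 1.0,
                           (fa != 0) * 1.0, cw_resampled=(fa != 0) * 0.5)
        t = node_metrics(cs)
        assert t["rfa"][0] == pytest.approx(0.8)
        assert t["rfa"][3] == 0 and t["cs"][3] == 0
        assert t["cs"][0] == pytest.approx(1.0)


class TestFlipHemispheres:
    def make_block_connectome(self):
        m = np.zeros((4, 4))
        m[0, 1] = 10.0       # L-L edge
        m[2, 3] = 20.0       # R-R edge
        m[0, 3] = 5.0        # inter-hemispheric
        m = m + m.T
        return ConnectomeSet("s", m / 100, (m != 0).astype(int),
                             np.where(m != 0, 1.0, 0.0), m,
                             cw_resampled=np.where(m != 0, 0.5, 0.0))

    def test_double_flip_restores_exactly(self, toy_parcellation):
        c = self.make_block_connectome()
        back = flip_hemispheres(flip_hemispheres(c, toy_parcellation, "R"),
                                toy_parcellation, "R")
        np.testing.assert_array_equal(back.cw_matrix, c.cw_matrix)
        assert back.flipped is False

    def test_blocks_exchanged(self, toy_parcellation):
        c = self.make_block_connectome()
        f = flip_hemispheres(c, toy_parcellation, "R")
        assert f.cw_matrix[2, 3] == 10.0 and f.cw_matrix[0, 1] == 20.0
        assert f.cw_matrix[2, 1] == 5.0   # inter-hemispheric block transposed
        assert f.flipped is True

    def test_left_lesion_unchanged(self, toy_parcellation):
        c = self.make_block_connectome()
        f = flip_hemispheres(c, toy_parcellation, "L")
        np.testing.assert_array_equal(f.cw_matrix, c.cw_matrix)
        assert f.flipped is False


class TestParcellationAndSubnetworks:
    def test_default_80_partition_is_exhaustive_and_disjoint(self):
        parc = Parcellation.default_80()
        blocks = group_subnetworks(parc)
        assert len(blocks) == 12
        all_idx = sorted(i for v in blocks.values() for i in v)
        assert all_idx == list(range(80))

    def test_precentral_in_sensorimotor_block(self):
        parc = Parcellation.default_80()
        blocks = group_subnetworks(parc)
        i = parc.names.index("precentral_L")
        assert i in blocks[("SMA", "L")]

    def test_hippocampus_in_subcortical_block(self):
        parc = Parcellation.default_80()
        blocks = group_subnetworks(parc)
        i = parc.names.index("hippocampus_L")
        assert i in blocks[("SN", "L")]

    def test_homotopic_involution_on_default_atlas(self):
        parc = Parcellation.default_80()
        perm = parc.homotopic_permutation()
        assert np.array_equal(perm[perm], np.arange(80))
        assert np.all(perm != np.arange(80))

    def test_broken_involution_rejected(self):
        with pytest.raises(ValueError, match="involution"):
            Parcellation((
                ROI(1, "a", "L", "cortical", 1.0, "SMA", 2),
                ROI(2, "b", "R", "cortical", 1.0, "SMA", 1),
                ROI(3, "c", "L", "cortical", 1.0, "SMA", 1),
            ))
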