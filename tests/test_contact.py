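"""Contact-map container, I/O, masking, KR balancing, decay and O/E."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dinotad.contact import (
    BalancingWeights,
    ContactMap,
    expected_by_distance,
    kr_balance,
    mask_sparse_bins,
    normalize_to_smallest,
    observed_over_expected,
)
from dinotad.errors import CoordinateError, GridMismatchError, ParseError
from dinotad.grid import BinGrid
from dinotad.io import load_contact_map, write_contact_map
from conftest import sinkhorn_oracle


def small_grid(n_bins=5, res=10):
    return BinGrid(["c1"], {"c1": n_bins * res}, res)


def make_map(grid, mat):
    return ContactMap(grid=grid, counts={"c1": np.asarray(mat, dtype=float)})


class TestGrid:
    def test_bin_tiling_and_short_last_bin(self):
        g = BinGrid(["a"], {"a": 1_040}, 100)
        assert g.n_bins("a") == 11
        assert g.bin_span("a", 10) == (1000, 1040)

    def test_off_grid_position_rejected(self):
        g = small_grid()
        with pytest.raises(CoordinateError):
            g.bin_index("c1", 15)
        with pytest.raises(CoordinateError):
            g.bin_index("c1", 60)


class TestIO:
    def test_three_triples_produce_symmetric_cells(self, tmp_path):
        g = small_grid()
        p = tmp_path / "m.tsv"
        p.write_text("c1\t0\tc1\t10\t3\nc1\t10\tc1\t20\t2\nc1\t0\tc1\t0\t5\n")
        cmap, n_trans = load_contact_map(p, g)
        m = cmap.counts["c1"]
        assert n_trans == 0
        assert m[0, 1] == m[1, 0] == 3
        assert m[1, 2] == m[2, 1] == 2
        assert m[0, 0] == 5
        assert np.count_nonzero(m) == 5

    def test_off_resolution_start_is_coordinate_error(self, tmp_path):
        g = small_grid()
        p = tmp_path / "m.tsv"
        p.write_text("c1\t5\tc1\t10\t3\n")
        with pytest.raises(CoordinateError):
            load_contact_map(p, g)

    def test_malformed_line_reports_line_number(self, tmp_path):
        g = small_grid()
        p = tmp_path / "m.tsv"
        p.write_text("c1\t0\tc1\t10\t3\nc1\t0\tnot-enough\n")
        with pytest.raises(ParseError, match=":2"):
            load_contact_map(p, g)

    def test_trans_entries_counted_not_stored(self, tmp_path):
        g = BinGrid(["c1", "c2"], {"c1": 50, "c2": 50}, 10)
        p = tmp_path / "m.tsv"
        p.write_text("c1\t0\tc2\t10\t7\nc1\t0\tc1\t10\t1\n")
        cmap, n_trans = load_contact_map(p, g)
        assert n_trans == 1
        assert cmap.total() == 2  # the cis entry, mirrored

    def test_roundtrip_write_load_exact(self, tmp_path):
        rng = np.random.default_rng(11)
        g = small_grid(n_bins=12)
        m = np.zeros((12, 12))
        iu = np.triu_indices(12)
        vals = rng.integers(0, 6, size=len(iu[0]))
        m[iu] = vals
        m = np.triu(m) + np.triu(m, 1).T
        cmap = make_map(g, m)
        p = tmp_path / "rt.tsv"
        write_contact_map(p, cmap)
        back, _ = load_contact_map(p, g)
        np.testing.assert_array_equal(back.counts["c1"], m)


class TestMasking:
    def test_zero_bin_masked_and_idempotent(self):
        g = small_grid(4)
        m = np.ones((4, 4))
        m[2, :] = m[:, 2] = 0
        cmap = mask_sparse_bins(make_map(g, m), min_marginal=1)
        assert cmap.mask["c1"].tolist() == [False, False, True, False]
        again = mask_sparse_bins(cmap, min_marginal=1)
        assert again.mask["c1"].tolist() == cmap.mask["c1"].tolist()

    def test_zero_threshold_masks_nothing(self):
        g = small_grid(4)
        cmap = mask_sparse_bins(make_map(g, np.ones((4, 4))), min_marginal=0)
        assert not cmap.mask["c1"].any()

    def test_threshold_matches_bruteforce_marginal_scan(self):
        rng = np.random.default_rng(5)
        n = 30
        g = small_grid(n)
        m = rng.integers(0, 3, size=(n, n))
        m = ((m + m.T) // 2).astype(float)
        cmap = mask_sparse_bins(make_map(g, m), min_marginal=10)
        expected = np.array([m[i].sum() < 10 for i in range(n)])
        np.testing.assert_array_equal(cmap.mask["c1"], expected)


class TestKRBalance:
    def test_two_by_two_symmetry_forced(self):
        g = small_grid(2)
        cmap = make_map(g, [[0, 2], [2, 0]])
        kr_balance(cmap)
        b = cmap.balanced("c1")
        np.testing.assert_allclose(b, [[0, 1], [1, 0]], atol=1e-9)

    def test_doubly_stochastic_input_gets_unit_weights(self):
        g = small_grid(2)
        cmap = make_map(g, [[0.5, 0.5], [0.5, 0.5]])
        w = kr_balance(cmap)
        np.testing.assert_allclose(w.for_chrom("c1"), [1.0, 1.0], atol=1e-6)

    def test_3x3_matches_sinkhorn_oracle(self):
        a = np.array([[1.0, 2, 1], [2, 1, 3], [1, 3, 2]])
        g = small_grid(3)
        cmap = make_map(g, a)
        w = kr_balance(cmap, tol=1e-9).for_chrom("c1")
        np.testing.assert_allclose(w, sinkhorn_oracle(a), atol=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_small_matrices_match_sinkhorn_fixed_point(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 6, size=(n, n))
        a = ((m + m.T) / 2).astype(float)
        g = small_grid(n)
        cmap = make_map(g, a)
        w = kr_balance(cmap, tol=1e-9).for_chrom("c1")
        np.testing.assert_allclose(w, sinkhorn_oracle(a), atol=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_row_sum_uniformity_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        m = rng.poisson(3.0, size=(n, n)).astype(float)
        m = m + m.T
        m += np.eye(n)  # guarantee support
        g = small_grid(n)
        cmap = make_map(g, m)
        kr_balance(cmap, tol=1e-8)
        rows = np.nansum(cmap.balanced("c1"), axis=1)
        ok = ~cmap.mask["c1"]
        assert np.max(np.abs(rows[ok] - 1.0)) < 1e-6

    def test_unbalanceable_support_reports_offending_bins(self):
        from dinotad.errors import BalanceError

        # chain-graph support (single off-diagonal) admits no doubly
        # stochastic scaling; the solver must fail loudly, not hang
        n = 10
        m = np.zeros((n, n))
        idx = np.arange(n - 3)
        m[idx, idx + 3] = 1.0
        m[idx + 3, idx] = 1.0
        cmap = make_map(small_grid(n), m)
        with pytest.raises(BalanceError, match="bins"):
            kr_balance(cmap, max_iter=500)

    def test_symmetry_preserved_by_balancing(self, balanced_map):
        b = balanced_map.balanced("chr1")
        finite = np.isfinite(b)
        np.testing.assert_array_equal(finite, finite.T)
        np.testing.assert_allclose(b[finite], b.T[finite], rtol=1e-12)


class TestNormalizeToSmallest:
    def grids_and_maps(self, totals):
        g = small_grid(4)
        maps = []
        for t in totals:
            m = np.full((4, 4), t / 16.0)
            maps.append(make_map(g, m))
        return maps

    def test_equal_totals_unchanged(self):
        maps = self.grids_and_maps([80, 80])
        out = normalize_to_smallest(maps)
        for a, b in zip(maps, out):
            np.testing.assert_allclose(a.counts["c1"], b.counts["c1"])

    def test_totals_scaled_to_minimum(self):
        out = normalize_to_smallest(self.grids_and_maps([200, 100]))
        assert out[0].total() == pytest.approx(100)
        assert out[1].total() == pytest.approx(100)
        out3 = normalize_to_smallest(self.grids_and_maps([300, 150, 600]))
        assert [m.total() for m in out3] == pytest.approx([150, 150, 150])

    def test_grid_mismatch_rejected(self):
        g2 = BinGrid(["c1"], {"c1": 80}, 20)
        maps = self.grids_and_maps([100])
        with pytest.raises(GridMismatchError):
            normalize_to_smallest([maps[0], ContactMap(grid=g2, counts={})])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_cell_ratios_conserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        g = small_grid(6)
        ms = []
        for _ in range(2):
            m = rng.integers(1, 9, size=(6, 6)).astype(float)
            ms.append(make_map(g, m + m.T))
        out = normalize_to_smallest(ms)
        for orig, scaled in zip(ms, out):
            r0 = orig.counts["c1"] / orig.counts["c1"][0, 0]
            r1 = scaled.counts["c1"] / scaled.counts["c1"][0, 0]
            np.testing.assert_allclose(r0, r1, rtol=1e-12)


class TestDecayAndOE:
    def test_constant_matrix_flat_profile_alpha_zero(self):
        g = small_grid(20)
        cmap = make_map(g, np.ones((20, 20)))
        kr_balance(cmap)
        prof = expected_by_distance(cmap)
        assert abs(prof.alpha) < 1e-6
        vals = prof.values[: 20 // 2]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-9)

    def test_single_diagonal_profile_positive_only_there(self):
        g = small_grid(10)
        m = np.zeros((10, 10))
        k = 3
        idx = np.arange(10 - k)
        m[idx, idx + k] = 1.0
        m[idx + k, idx] = 1.0
        cmap = make_map(g, m)
        # such a chain-support matrix has no doubly stochastic scaling;
        # the profile definition is probed with unit weights
        cmap.weights = BalancingWeights({"c1": np.ones(10)})
        prof = expected_by_distance(cmap)
        assert prof.pair_counts[k] > 0
        assert prof.values[k] > 0
        for d in range(1, 10):
            if d != k:
                assert prof.values[d] == 0

    def test_oe_of_own_expectation_is_one(self, balanced_map):
        prof = expected_by_distance(balanced_map)
        oe = observed_over_expected(balanced_map, prof)
        b = oe.balanced("chr1")
        n = b.shape[0]
        for d in range(0, n, 17):
            diag = np.diagonal(b, offset=d)
            diag = diag[np.isfinite(diag)]
            if diag.size:
                assert np.mean(diag) == pytest.approx(1.0, abs=1e-9)

    def test_doubling_one_cell_doubles_its_oe(self):
        g = small_grid(12)
        rng = np.random.default_rng(3)
        m = rng.integers(1, 5, size=(12, 12)).astype(float)
        m = m + m.T
        cmap = make_map(g, m)
        kr_balance(cmap)
        prof = expected_by_distance(cmap)
        oe1 = observed_over_expected(cmap, prof).counts["c1"]
        # same balanced values, one cell doubled, same expectation profile
        cmap2 = make_map(g, m)
        cmap2.counts["c1"][2, 7] *= 2
        cmap2.counts["c1"][7, 2] *= 2
        cmap2.weights = cmap.weights
        oe2 = observed_over_expected(cmap2, prof).counts["c1"]
        assert oe2[2, 7] == pytest.approx(2 * oe1[2, 7])
        assert oe2[0, 1] == pytest.approx(oe1[0, 1])

    def test_planted_domains_have_intra_enrichment_in_oe(self, balanced_map, default_sim):
        _, truth = default_sim
        oe = observed_over_expected(balanced_map)
        b = oe.balanced("chr1")
        res = truth.grid.resolution
        edges = [e // res for e in truth.domain_edges["chr1"]]
        intra, inter = [], []
        for (s0, e0), (s1, e1) in zip(
            zip(edges[:-1], edges[1:]), zip(edges[1:], edges[2:])
        ):
            blk = b[s0:e0, s0:e0]
            intra.append(np.nanmean(blk[np.triu_indices(e0 - s0, 1)]))
            inter.append(np.nanmean(b[s0:e0, s1:e1]))
        assert np.nanmean(intra) > 1 > np.nanmean(inter)
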