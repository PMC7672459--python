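import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadprobe.io_formats import GeneModel, GenomicInterval
from quadprobe.signal_profile import (
    CoverageTrack,
    apply_row_order,
    compare_tracks,
    heatmap_scale,
    reference_point_matrix,
    rpkm_normalize,
    scale_regions_matrix,
    shuffle_intervals,
    sort_rows,
)


def track(values, **kw):
    return CoverageTrack({"c1": np.asarray(values, dtype=float)}, **kw)


class TestRpkm:
    def test_direct_formula(self):
        # 100-bp bin holding 5 read-equivalents of 50-bp reads, 1e6 total reads
        t = track([2.5] * 100, total_mapped_reads=1_000_000, read_length=50)
        out = rpkm_normalize(t, 100)
        assert out.values["c1"][0] == pytest.approx(50.0)

    def test_scale_invariance(self):
        a = track([4.0] * 200, total_mapped_reads=10**6, read_length=50)
        b = track([8.0] * 200, total_mapped_reads=2 * 10**6, read_length=50)
        assert np.allclose(rpkm_normalize(a, 50).values["c1"], rpkm_normalize(b, 50).values["c1"])

    def test_empty_bin_zero(self):
        t = track([0.0] * 100, total_mapped_reads=10**6, read_length=50)
        assert rpkm_normalize(t, 50).values["c1"].sum() == 0

    def test_missing_totals_rejected(self):
        with pytest.raises(ValueError):
            rpkm_normalize(track([1.0] * 10), 5)


class TestCompareTracks:
    def test_subtract(self):
        out = compare_tracks(track([10.0] * 5), track([4.0] * 5), "subtract")
        assert np.all(out.values["c1"] == 6.0)

    def test_ratio_with_pseudocount(self):
        out = compare_tracks(track([10.0] * 5), track([4.0] * 5), "ratio", pseudocount=1.0)
        assert np.allclose(out.values["c1"], 2.2)

    def test_self_subtract_is_zero_and_self_ratio_is_one(self):
        a = track(np.arange(20, dtype=float))
        assert np.all(compare_tracks(a, a, "subtract").values["c1"] == 0)
        assert np.allclose(compare_tracks(a, a, "ratio").values["c1"], 1.0)

    def test_mismatched_chromosomes_rejected(self):
        b = CoverageTrack({"c2": np.zeros(5)})
        with pytest.raises(ValueError):
            compare_tracks(track([1.0] * 5), b, "subtract")


def _anchor(pos, strand, chrom="c1", name="a"):
    if strand == "+":
        return GeneModel(GenomicInterval(chrom, pos, pos + 1000, strand), name)
    return GeneModel(GenomicInterval(chrom, max(0, pos - 999), pos + 1, strand), name)


class TestReferencePointMatrix:
    def test_constant_track_flat_profile(self):
        t = track([3.0] * 4000)
        mat = reference_point_matrix(t, [_anchor(2000, "+")], half_width=500, bin_size=50)
        assert np.allclose(mat.values, 3.0)
        assert np.allclose(mat.column_profile(), 3.0)

    def test_minus_strand_spike_mirrored_downstream(self):
        vals = np.zeros(4000)
        vals[2000 - 100] = 10.0  # 100 bp 5'-ward of a minus-strand TSS at 2000
        t = track(vals)
        mat = reference_point_matrix(t, [_anchor(2000, "-")], half_width=500, bin_size=50)
        # downstream of a minus gene is decreasing coordinate; the base 100 bp
        # downstream (distances 51..100 for its bin) lands right of centre
        nbins = mat.values.shape[1]
        spike_bin = int(np.argmax(mat.values[0]))
        assert spike_bin == nbins // 2 + 1  # bin covering (+50,+100]

    def test_out_of_chromosome_bins_zero_filled(self):
        t = track([5.0] * 1000)
        mat = reference_point_matrix(t, [_anchor(100, "+")], half_width=500, bin_size=100)
        assert np.all(mat.values[0, :4] == 0)
        assert np.all(mat.values[0, 4:] == 5.0)

    def test_bad_bin_size_rejected(self):
        with pytest.raises(ValueError):
            reference_point_matrix(track([1.0] * 100), [], half_width=50, bin_size=0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_bin_means_match_per_base_oracle(self, seed):
        """Matrix values equal direct per-base window means, both strands."""
        rng = np.random.default_rng(seed)
        vals = rng.random(3000) * 10
        t = track(vals)
        pos = int(rng.integers(0, 3000))
        strand = "+" if rng.integers(2) else "-"
        hw, bs = 400, 50
        mat = reference_point_matrix(t, [_anchor(pos, strand)], hw, bs)
        padded = np.zeros(2 * hw)
        lo, hi = max(0, pos - hw), min(3000, pos + hw)
        padded[lo - (pos - hw) : hi - (pos - hw)] = vals[lo:hi]
        expected = padded.reshape(-1, bs).mean(axis=1)
        if strand == "-":
            expected = expected[::-1]
        assert np.array_equal(mat.values[0], expected)

    def test_double_strand_flip_is_involution(self):
        rng = np.random.default_rng(3)
        t = track(rng.random(2000))
        plus = reference_point_matrix(t, [_anchor(1000, "+")], 300, 50)
        minus = reference_point_matrix(t, [_anchor(1000, "-")], 300, 50)
        assert np.array_equal(plus.values[0], minus.values[0][::-1])


class TestScaleRegions:
    def test_indicator_conservation(self):
        vals = np.zeros(5000)
        g = GeneModel(GenomicInterval("c1", 2000, 3100, "+"), "g")
        vals[2000:3100] = 1.0
        mat = scale_regions_matrix(track(vals), [g], body_bins=40, flank=500, bin_size=50)
        fb = 500 // 50
        assert np.allclose(mat.values[0][fb : fb + 40], 1.0)
        assert np.allclose(mat.values[0][:fb], 0.0)
        assert np.allclose(mat.values[0][fb + 40 :], 0.0)

    def test_gene_shorter_than_body_bins_preserves_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.random(1000)
        g = GeneModel(GenomicInterval("c1", 400, 423, "+"), "g")  # 23 bp << 40 bins
        mat = scale_regions_matrix(track(vals), [g], body_bins=40, flank=100, bin_size=50)
        body = mat.values[0][2:42]
        assert body.mean() == pytest.approx(vals[400:423].mean())

    def test_minus_strand_reversed(self):
        vals = np.arange(5000, dtype=float)
        gp = GeneModel(GenomicInterval("c1", 2000, 3000, "+"), "g")
        gm = GeneModel(GenomicInterval("c1", 2000, 3000, "-"), "g")
        mp = scale_regions_matrix(track(vals), [gp], 20, 500, 50)
        mm = scale_regions_matrix(track(vals), [gm], 20, 500, 50)
        assert np.allclose(mp.values[0], mm.values[0][::-1])


class TestHeatmapAndSorting:
    def test_linear_map(self):
        out = heatmap_scale(np.array([[0.0, 5.0], [10.0, 10.0]]))
        assert np.allclose(out, [[0.0, 127.5], [255.0, 255.0]])

    def test_constant_matrix_maps_to_zero(self):
        assert np.all(heatmap_scale(np.full((3, 3), 7.0)) == 0)

    def test_range_endpoints_for_nonconstant_input(self):
        rng = np.random.default_rng(1)
        out = heatmap_scale(rng.random((5, 8)))
        assert out.min() == 0.0 and out.max() == pytest.approx(255.0)

    def _matrix(self, rows):
        from quadprobe.signal_profile import SignalMatrix

        return SignalMatrix(np.asarray(rows, dtype=float), [f"r{i}" for i in range(len(rows))], 50, "reference_point")

    def test_sort_by_mean_descending(self):
        mat = self._matrix([[3, 3], [1, 1], [2, 2]])
        ordered, order = sort_rows(mat, key="mean")
        assert ordered.row_ids == ["r0", "r2", "r1"]

    def test_ties_keep_input_order(self):
        mat = self._matrix([[2, 2], [2, 2], [1, 1]])
        ordered, _ = sort_rows(mat, key="max")
        assert ordered.row_ids == ["r0", "r1", "r2"]

    def test_shared_order_applies_to_other_matrix(self):
        mat = self._matrix([[3, 3], [1, 1], [2, 2]])
        _, order = sort_rows(mat, key="mean")
        other = self._matrix([[10, 10], [20, 20], [30, 30]])
        assert apply_row_order(other, order).row_ids == ["r0", "r2", "r1"]

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            sort_rows(self._matrix([[1, 2]]), key="median")


class TestShuffleIntervals:
    def test_constrained_placement(self):
        iv = GenomicInterval("c1", 10, 25, ".")
        exclusion = [GenomicInterval("c1", 0, 900, ".")]
        for seed in range(40):
            (out,) = shuffle_intervals([iv], {"c1": 1000}, exclusion, seed=seed)
            assert out.start >= 900 and out.end <= 1000
            assert len(out) == 15

    def test_lengths_multiset_conserved(self):
        ivs = [GenomicInterval("c1", s, s + l, ".") for s, l in [(0, 10), (50, 30), (100, 10)]]
        out = shuffle_intervals(ivs, {"c1": 5000}, [], seed=5)
        assert sorted(len(o) for o in out) == sorted(len(i) for i in ivs)

    def test_deterministic_per_seed_and_varies_across_seeds(self):
        ivs = [GenomicInterval("c1", s, s + 20, ".") for s in range(0, 400, 40)]
        a = shuffle_intervals(ivs, {"c1": 100_000}, [], seed=11)
        b = shuffle_intervals(ivs, {"c1": 100_000}, [], seed=11)
        assert [(x.start, x.end) for x in a] == [(x.start, x.end) for x in b]
        starts = {tuple(x.start for x in shuffle_intervals(ivs, {"c1": 100_000}, [], seed=s)) for s in range(100)}
        assert len(starts) == 100

    def test_shuffled_intervals_mutually_disjoint_and_outside_exclusion(self):
        ivs = [GenomicInterval("c1", s, s + 50, ".") for s in range(0, 1000, 100)]
        excl = [GenomicInterval("c1", 2000, 9000, ".")]
        out = shuffle_intervals(ivs, {"c1": 10_000}, excl, seed=0)
        spans = sorted((o.start, o.end) for o in out)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        for s, e in spans:
            assert e <= 2000 or s >= 9000

    def test_infeasible_placement_raises(self):
        iv = GenomicInterval("c1", 0, 50, ".")
        excl = [GenomicInterval("c1", 0, 1000, ".")]
        with pytest.raises(RuntimeError, match="c1:0-50"):
            shuffle_intervals([iv], {"c1": 1000}, excl, seed=0)
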