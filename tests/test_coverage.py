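import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regionoverlap import (
    GenomicRegion,
    OverlapParams,
    RegionSet,
    bin_region,
    coverage_matrix,
    generate_subjects_for,
    matrix_table,
    profile_table,
    tiled_region_set,
)


def _query(start=1, end=1000, strand="+"):
    return RegionSet("q", [GenomicRegion("chr1", start, end, strand, "g")])


def _subjects(*spans):
    return RegionSet("s", [GenomicRegion("chr1", a, b) for a, b in spans])


class TestBinRegion:
    def test_exact_division(self):
        bins = bin_region(GenomicRegion("chr1", 1, 1000), 100)
        assert bins[0] == (1, 10)
        assert bins[-1] == (991, 1000)
        assert all(b - a + 1 == 10 for a, b in bins)

    def test_uneven_width_tiles_exactly(self):
        # floor formula evaluated independently: bin i covers
        # [1 + floor((i-1)*150/100), floor(i*150/100)]
        bins = bin_region(GenomicRegion("chr1", 1, 150), 100)
        expected = [(1 + (i * 150) // 100, ((i + 1) * 150) // 100)
                    for i in range(100)]
        assert bins == expected
        widths = {b - a + 1 for a, b in bins}
        assert widths == {1, 2}
        assert sum(b - a + 1 for a, b in bins) == 150

    def test_too_short_region_rejected(self):
        with pytest.raises(ValueError):
            bin_region(GenomicRegion("chr1", 1, 50), 100)

    @settings(derandomize=True, max_examples=60)
    @given(width=st.integers(min_value=100, max_value=5000),
           start=st.integers(min_value=1, max_value=10_000),
           n_bins=st.sampled_from([1, 7, 100]))
    def test_bins_tile_region_disjointly(self, width, start, n_bins):
        r = GenomicRegion("chr1", start, start + width - 1)
        bins = bin_region(r, n_bins)
        assert bins[0][0] == r.start and bins[-1][1] == r.end
        for (a1, b1), (a2, b2) in zip(bins, bins[1:]):
            assert a2 == b1 + 1  # adjacent, no gap, no overlap
        assert max(b - a for a, b in bins) - min(b - a for a, b in bins) <= 1


class TestCoverageMatrix:
    def test_element_at_five_prime_end(self):
        cm = coverage_matrix(_query(), _subjects((1, 10)), n_bins=100)
        assert cm.matrix[0, 0] == 1 and cm.matrix[0, 1:].sum() == 0

    def test_minus_strand_reverses_bin_order(self):
        # element at genomic start = 3' end of a minus-strand gene -> bin 100
        cm = coverage_matrix(_query(strand="-"), _subjects((1, 10)), n_bins=100)
        assert cm.matrix[0, 99] == 1 and cm.matrix[0, :99].sum() == 0

    def test_spanning_element_counts_in_each_bin(self):
        # 10-bp bins; subject 5..25 touches bins 1-3
        cm = coverage_matrix(_query(end=1000), _subjects((5, 25)), n_bins=100)
        assert cm.matrix[0, :3].tolist() == [1, 1, 1]
        assert cm.matrix[0, 3:].sum() == 0

    def test_short_queries_dropped_and_counted(self):
        q = RegionSet("q", [GenomicRegion("chr1", 1, 1000, "+", "long"),
                            GenomicRegion("chr1", 2000, 2050, "+", "short")])
        cm = coverage_matrix(q, _subjects((1, 10)), n_bins=100)
        assert cm.n_dropped_short == 1
        assert cm.kept_query_indices == [0]
        assert cm.matrix.shape == (1, 100)

    def test_profile_is_column_sum_and_conserved(self):
        q = tiled_region_set(50, width=500, seed=3)
        s, _ = generate_subjects_for(q, rate=3, seed=4)
        cm = coverage_matrix(q, s, n_bins=100)
        assert np.array_equal(cm.profile, cm.matrix.sum(axis=0))
        pt = profile_table(cm)
        assert len(pt) == 100
        assert pt.accumulated_count.sum() == cm.matrix.sum()

    def test_row_sums_bounded_by_hit_counts(self):
        q = tiled_region_set(30, width=400, seed=5)
        s, _ = generate_subjects_for(q, rate=2, seed=6)
        from regionoverlap import count_overlaps_per_query, find_overlaps

        cm = coverage_matrix(q, s, n_bins=50)
        counts = count_overlaps_per_query(find_overlaps(q, s), len(q))
        rows = cm.matrix.sum(axis=1)
        assert np.all(rows >= counts) and np.all(rows <= counts * 50)

    def test_strand_flip_reverses_each_row(self):
        q = tiled_region_set(40, width=600, strands=["+"] * 40, seed=7)
        s, _ = generate_subjects_for(q, rate=3, bias="five_prime", seed=8)
        flipped = q.replace([GenomicRegion(r.chrom, r.start, r.end, "-", r.name)
                             for r in q])
        cm_plus = coverage_matrix(q, s, n_bins=20)
        cm_minus = coverage_matrix(flipped, s, n_bins=20)
        assert np.array_equal(cm_minus.matrix, cm_plus.matrix[:, ::-1])

    def test_orient_false_keeps_genomic_order(self):
        cm = coverage_matrix(_query(strand="-"), _subjects((1, 10)),
                             n_bins=100, orient=False)
        assert cm.matrix[0, 0] == 1

    def test_matrix_table_layout(self):
        cm = coverage_matrix(_query(), _subjects((1, 10)), n_bins=10)
        df = matrix_table(cm)
        assert list(df.columns) == ["query_index"] + [f"bin_{j}"
                                                      for j in range(1, 11)]

    def test_invalid_n_bins(self):
        with pytest.raises(ValueError):
            coverage_matrix(_query(), _subjects((1, 10)), n_bins=0)


class TestProfileShapes:
    def test_five_prime_bias_enriches_first_decile(self):
        q = tiled_region_set(500, width=1000, seed=9)
        s, _ = generate_subjects_for(q, rate=4, bias="five_prime",
                                     lengths=(1, 1), seed=10)
        cm = coverage_matrix(q, s, n_bins=100)
        assert cm.profile[:10].sum() > cm.profile[-10:].sum()
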