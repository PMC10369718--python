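import numpy as np
import pandas as pd
import pytest

from regionoverlap import (
    FixtureSpec,
    GenomicRegion,
    OverlapParams,
    RegionSet,
    annotate_hits,
    brute_force_overlaps,
    find_overlaps,
    generate_region_set,
)

ALL_PARAMS = [
    OverlapParams(min_overlap=m, type=t, ignore_strand=ig)
    for m in (1, 10, 60)
    for t in ("any", "within", "equal")
    for ig in (True, False)
]


def _set(name, *tuples):
    return RegionSet(name, [GenomicRegion(*t) for t in tuples])


def _random_pair(seed, n=200, chrom_size=100_000):
    spec = lambda s: FixtureSpec(
        n_regions=n, chrom_sizes={"chrA": chrom_size, "chrB": chrom_size},
        length_range=(20, 800), strand_probs=(0.45, 0.45, 0.10), seed=s)
    return (generate_region_set(spec(seed), "q"),
            generate_region_set(spec(seed + 5000), "s"))


class TestHitRule:
    def test_partial_overlap_coordinates_and_fractions(self):
        q = _set("q", ("chr1", 100, 200, "+"))
        s = _set("s", ("chr1", 150, 250, "+"))
        ht = find_overlaps(q, s)
        assert len(ht) == 1
        h = ht.hits[0]
        assert (h.ov_start, h.ov_end, h.ov_width) == (150, 200, 51)
        assert h.frac_query == pytest.approx(51 / 101)
        assert h.frac_subject == pytest.approx(51 / 101)

    def test_min_overlap_excludes_short_intersections(self):
        q = _set("q", ("chr1", 100, 200, "+"))
        s = _set("s", ("chr1", 150, 250, "+"))
        assert len(find_overlaps(q, s, OverlapParams(min_overlap=60))) == 0
        assert len(find_overlaps(q, s, OverlapParams(min_overlap=51))) == 1

    def test_within_is_asymmetric_containment(self):
        inner = _set("q", ("chr1", 150, 180, "*"))
        outer = _set("s", ("chr1", 100, 200, "*"))
        assert len(find_overlaps(inner, outer, OverlapParams(type="within"))) == 1
        assert len(find_overlaps(outer, inner, OverlapParams(type="within"))) == 0

    def test_equal_requires_identical_endpoints(self):
        a = _set("q", ("chr1", 10, 50, "+"))
        b = _set("s", ("chr1", 10, 50, "-"))
        ht = find_overlaps(a, b, OverlapParams(type="equal"))
        assert len(ht) == 1 and ht.hits[0].frac_query == 1.0
        c = _set("s2", ("chr1", 10, 51, "+"))
        assert len(find_overlaps(a, c, OverlapParams(type="equal"))) == 0

    def test_strand_compatibility_rule(self):
        q = _set("q", ("chr1", 100, 200, "+"))
        minus = _set("s", ("chr1", 150, 250, "-"))
        star = _set("s", ("chr1", 150, 250, "*"))
        stranded = OverlapParams(ignore_strand=False)
        assert len(find_overlaps(q, minus, stranded)) == 0
        assert len(find_overlaps(q, star, stranded)) == 1
        assert len(find_overlaps(q, minus)) == 1  # default ignores strand

    def test_different_chromosomes_never_hit(self):
        q = _set("q", ("chr1", 100, 200))
        s = _set("s", ("chr2", 100, 200))
        assert len(find_overlaps(q, s)) == 0

    def test_empty_subject_gives_empty_table(self):
        q = _set("q", ("chr1", 1, 10))
        ht = brute_force_overlaps(q, RegionSet("s", []))
        assert len(ht) == 0 and list(ht.df.columns)

    def test_adjacent_but_disjoint_is_no_hit(self):
        q = _set("q", ("chr1", 1, 10))
        s = _set("s", ("chr1", 11, 20))
        assert len(find_overlaps(q, s)) == 0
        s1 = _set("s", ("chr1", 10, 20))
        assert find_overlaps(q, s1).hits[0].ov_width == 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_engine_matches_brute_force_all_params(self, seed):
        q, s = _random_pair(seed)
        for params in ALL_PARAMS:
            fast = find_overlaps(q, s, params).df
            slow = brute_force_overlaps(q, s, params).df
            pd.testing.assert_frame_equal(fast, slow)

    def test_count_symmetry_under_any(self):
        q, s = _random_pair(11)
        for m in (1, 25):
            p = OverlapParams(min_overlap=m)
            assert len(find_overlaps(q, s, p)) == len(find_overlaps(s, q, p))

    def test_min_overlap_monotonicity_and_type_nesting(self):
        q, s = _random_pair(12)
        pairs = lambda params: set(
            map(tuple, find_overlaps(q, s, params).df[
                ["query_index", "subject_index"]].to_numpy()))
        assert pairs(OverlapParams(min_overlap=40)) <= pairs(
            OverlapParams(min_overlap=1))
        assert pairs(OverlapParams(type="equal")) <= pairs(
            OverlapParams(type="within")) <= pairs(OverlapParams(type="any"))

    def test_strand_flip_invariance_when_ignoring_strand(self):
        q, s = _random_pair(13)
        flip = {"+": "-", "-": "+", "*": "*"}
        s_flipped = s.replace([
            GenomicRegion(r.chrom, r.start, r.end, flip[r.strand], r.name)
            for r in s])
        pd.testing.assert_frame_equal(find_overlaps(q, s).df,
                                      find_overlaps(q, s_flipped).df)

    def test_full_query_fraction_iff_contained(self):
        q, s = _random_pair(14)
        df = find_overlaps(q, s).df
        for _, row in df.iterrows():
            contained = (s[row.subject_index].start <= q[row.query_index].start
                         and q[row.query_index].end <= s[row.subject_index].end)
            assert (row.frac_query == 1.0) == contained

    def test_cross_check_against_pyranges(self):
        """Independent interval-join library agrees on the plain hit pairs."""
        pr = pytest.importorskip("pyranges")
        q, s = _random_pair(21)
        to_pr = lambda rs, tag: pr.PyRanges(pd.DataFrame({
            "Chromosome": [r.chrom for r in rs],
            "Start": [r.start - 1 for r in rs],   # to 0-based half-open
            "End": [r.end for r in rs],
            tag: range(len(rs)),
        }))
        joined = to_pr(q, "qi").join(to_pr(s, "si")).df
        expected = set(zip(joined["qi"], joined["si"]))
        got = set(map(tuple, find_overlaps(q, s).df[
            ["query_index", "subject_index"]].to_numpy()))
        assert got == expected


class TestAnnotate:
    def test_names_joined_onto_hits(self):
        q = _set("genes", ("chr1", 100, 200, "+", "GENE1"))
        s = _set("tfbs", ("chr1", 150, 160, "*", "TFBS_7"))
        df = annotate_hits(find_overlaps(q, s), q, s)
        row = df.iloc[0]
        assert (row.query_name, row.subject_name) == ("GENE1", "TFBS_7")
        assert (row.query_start, row.subject_end, row.ov_width) == (100, 160, 11)

    def test_generated_identifiers_for_unnamed_regions(self):
        q = _set("q", ("chr1", 100, 200))
        s = _set("s", ("chr1", 1, 10), ("chr1", 20, 30), ("chr1", 40, 50),
                 ("chr1", 150, 160))
        df = annotate_hits(find_overlaps(q, s), q, s)
        assert df.iloc[0].query_name == "query_0"
        assert df.iloc[0].subject_name == "subject_3"

    def test_empty_table_annotates_to_zero_rows(self):
        q = _set("q", ("chr1", 100, 200))
        s = RegionSet("s", [])
        assert len(annotate_hits(brute_force_overlaps(q, s), q, s)) == 0

    def test_corrupted_indices_rejected(self):
        q = _set("q", ("chr1", 100, 200))
        s = _set("s", ("chr1", 150, 160))
        ht = find_overlaps(q, s)
        with pytest.raises(IndexError):
            annotate_hits(ht, q, RegionSet("s", []))
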