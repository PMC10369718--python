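import pytest
from hypothesis import given, settings, strategies as st

from regionoverlap import (
    GenomicRegion,
    RegionSet,
    ResizeSpec,
    resize_regions,
    subset_regions,
)


def _one(chrom="chr1", start=5000, end=7000, strand="+", **kw):
    return RegionSet("g", [GenomicRegion(chrom, start, end, strand, **kw)])


class TestResize:
    def test_promoter_window_plus_strand(self):
        # 1200 bp upstream of the TSS, anchor base included
        out = resize_regions(_one(strand="+"), ResizeSpec(1200, 0, "tss"))
        assert (out[0].start, out[0].end) == (3800, 5000)

    def test_promoter_window_minus_strand_mirrors(self):
        out = resize_regions(_one(strand="-"), ResizeSpec(1200, 0, "tss"))
        assert (out[0].start, out[0].end) == (7000, 8200)

    def test_left_clip_at_chromosome_start(self):
        out = resize_regions(_one(start=500, end=900), ResizeSpec(1200, 0, "tss"))
        assert (out[0].start, out[0].end) == (1, 500)

    def test_right_clip_with_chrom_sizes(self):
        out = resize_regions(_one(strand="-"), ResizeSpec(1200, 0, "tss"),
                             chrom_sizes={"chr1": 8000})
        assert (out[0].start, out[0].end) == (7000, 8000)

    def test_region_dropped_when_empty_after_clipping(self):
        out = resize_regions(_one(strand="-"), ResizeSpec(1200, 0, "tss"),
                             chrom_sizes={"chr1": 6500})
        assert len(out) == 0

    def test_tes_anchor_other_end(self):
        out = resize_regions(_one(strand="+"), ResizeSpec(0, 300, "tes"))
        assert (out[0].start, out[0].end) == (7000, 7300)
        out = resize_regions(_one(strand="-"), ResizeSpec(0, 300, "tes"))
        assert (out[0].start, out[0].end) == (4700, 5000)

    def test_body_extends_both_ends_strand_aware(self):
        out = resize_regions(_one(strand="+"), ResizeSpec(100, 200, "body"))
        assert (out[0].start, out[0].end) == (4900, 7200)
        out = resize_regions(_one(strand="-"), ResizeSpec(100, 200, "body"))
        assert (out[0].start, out[0].end) == (4800, 7100)

    def test_body_noop(self):
        out = resize_regions(_one(), ResizeSpec(0, 0, "body"))
        assert (out[0].start, out[0].end) == (5000, 7000)

    def test_anchor_base_included_gives_width_1201(self):
        out = resize_regions(_one(), ResizeSpec(1200, 0, "tss"))
        assert out[0].width == 1201

    def test_exclusive_promoter_window(self):
        # pure upstream window without the TSS base itself: width 1200
        out = resize_regions(
            _one(), ResizeSpec(1200, 0, "tss", include_anchor_base=False))
        assert (out[0].start, out[0].end) == (3800, 4999)

    def test_empty_exclusive_window_rejected(self):
        with pytest.raises(ValueError):
            ResizeSpec(0, 0, "tss", include_anchor_base=False)

    @settings(derandomize=True, max_examples=60)
    @given(
        start=st.integers(min_value=5_000, max_value=50_000),
        width=st.integers(min_value=1, max_value=2_000),
        up=st.integers(min_value=0, max_value=1_500),
        down=st.integers(min_value=0, max_value=1_500),
        anchor=st.sampled_from(["tss", "tes"]),
    )
    def test_strand_mirror_property(self, start, width, up, down, anchor):
        """Resizing a region and its strand-flipped copy gives mirror images
        about the region body; widths are equal."""
        end = start + width - 1
        plus = resize_regions(_one(start=start, end=end, strand="+"),
                              ResizeSpec(up, down, anchor))[0]
        minus = resize_regions(_one(start=start, end=end, strand="-"),
                               ResizeSpec(up, down, anchor))[0]
        assert plus.width == minus.width
        # mirror about the body midpoint: distances to body ends swap
        assert plus.start - start == -(minus.end - end)
        assert plus.end - end == -(minus.start - start)


class TestSubset:
    @pytest.fixture
    def tfbs(self):
        return RegionSet("tfbs", [
            GenomicRegion("chr1", 1, 10, "+", "EGR4", 200.0),
            GenomicRegion("chr1", 20, 30, "+", "SOX2", 400.0),
            GenomicRegion("chr2", 1, 10, "-", "EGR4", 600.0),
        ])

    def test_filter_by_name(self, tfbs):
        out = subset_regions(tfbs, name="EGR4")
        assert len(out) == 2 and all(r.name == "EGR4" for r in out)

    def test_filter_by_chromosome(self, tfbs):
        out = subset_regions(tfbs, chroms={"chr1"})
        assert [r.chrom for r in out] == ["chr1", "chr1"]

    def test_filter_by_score_threshold(self, tfbs):
        assert len(subset_regions(tfbs, min_score=400)) == 2

    def test_unknown_attribute_is_error(self, tfbs):
        with pytest.raises(KeyError):
            subset_regions(tfbs, attrs={"cell_type": "spermatogonia"})

    def test_order_preserved(self, tfbs):
        out = subset_regions(tfbs, name="EGR4")
        assert [r.chrom for r in out] == ["chr1", "chr2"]
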