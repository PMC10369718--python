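# Methods

## Coordinate model

Internally every interval is 1-based and closed (GFF-style): `[s, e]`
includes both endpoints, `width = e − s + 1`. Readers normalize on ingest —
BED's 0-based half-open `[chromStart, chromEnd)` becomes
`[chromStart + 1, chromEnd]`, GFF3/GTF coordinates pass through verbatim,
and delimited tables declare their convention in a `ColumnMap`. Writers
convert back on output, so a BED → internal → BED round trip is
bit-stable. The closed convention makes overlap width and region width
follow one formula and keeps single-base features (width 1) unambiguous.

Strand is `+`, `-`, or `*` (unstranded). `*` is *compatible with both
strands* wherever strand matters: in strand-specific overlap mode an
unstranded partner still matches, and in anchoring/orientation contexts
`*` behaves like `+` (with a one-time warning). This is the conventional
range-algebra semantics and keeps unstranded annotation tracks usable in
stranded analyses.

Genome builds are tracked as metadata labels only; differing labels
produce a validation warning, never an automatic liftover.

## Hit definition and the overlap engine

A (query, subject) pair is a hit when the two regions share a chromosome,
their intersection is at least `min_overlap` bases wide (default 1), the
type constraint holds, and strands are compatible. The three types are
`any` (partial or complete), `within`, and `equal`. **`within` means the
query interval lies entirely inside the subject interval**; "full overlap"
is direction-ambiguous in common usage, so this package fixes the
direction to query-inside-subject and the reverse containment is obtained
by swapping the roles. `min_overlap` applies to all types (an `equal` hit
satisfies it trivially); the parameters are orthogonal.

`find_overlaps` builds a per-chromosome interval index (an interval tree,
half-open internally: closed `[s, e]` is inserted as `[s, e + 1)`) over
the subject set and queries it per query region — O((n + m) log m + h)
rather than all-pairs. `brute_force_overlaps` evaluates every pair by
direct vectorized arithmetic and defines the reference semantics; the test
suite asserts field-level equality of the two routes over 20 randomized
1,000 × 1,000 instances across the full parameter grid
(3 types × stranded/unstranded × min_overlap ∈ {1, 10, 60}), and one
instance is additionally cross-checked against an independent interval-join
library. Hits are reported once per index pair — duplicated coordinates in
the inputs produce duplicated hits unless `deduplicate` is applied
upstream — and are ordered by (query_index, subject_index) so all outputs
are byte-stable.

Hit fractions are `ov_width / width(query)` and `ov_width / width(subject)`,
both in (0, 1]; `frac_query == 1` exactly when the query is contained in
the subject (a tested invariant).

## Resizing (promoter windows)

`resize_regions` anchors at the TSS (5′ end), TES (3′ end), or keeps the
body and extends both ends. Anchoring is strand-aware: for `-` regions the
TSS is the higher coordinate and "upstream" extends to the right. The
anchor base counts as position 0 and is included by default, so
`upstream=1200, downstream=0` yields width 1201. Whether the anchor base
itself belongs to the window is a genuine convention choice; the inclusive
default is simple and testable (`width = upstream + downstream + 1`).
`include_anchor_base=False` is honoured for pure one-sided windows
(`[a−U, a−1]` or `[a+1, a+D]`, the usual "1200 bp upstream of the TSS"
promoter definition); when both distances are positive the anchor is
unavoidably interior and the flag is ignored with a warning, rather than
silently splitting the window.

Coordinates are clipped to `[1, chrom_size]` when a chrom.sizes map is
supplied and to `[1, ∞)` otherwise (the workflow never requires a genome
file); clipping is logged and regions that become empty are dropped with a
warning. The tested mirror property: resizing a region and its
strand-flipped copy yields intervals that are mirror images about the
region body, with equal widths.

## Summary statistics

Per-query hit counts are summarized by min, lower quartile, mean, median,
upper quartile, and max. Quartiles use linear interpolation between order
statistics: at probability p, `h = (n − 1) p + 1` and the value is
`x_⌊h⌋ + (h − ⌊h⌋)(x_⌊h⌋₊₁ − x_⌊h⌋)` on the sorted vector (the common
"type 7" definition, numpy's default). The definition is stated explicitly
so ports to other ecosystems can match exactly. The workspace summary adds
an `overall` row: queries with at least one hit in *any* subject dataset,
and statistics over the summed per-query counts. Both mean and median are
always emitted; count distributions here are typically skewed, so the two
can differ materially and readers should pick deliberately.

Histograms default to one bin per integer count up to a maximum of 50,
switching to 30 equal-width bins beyond that — readable for the sparse
counts typical of gene-TFBS runs without degenerating on heavy tails.
Custom edges follow numpy histogram semantics (half-open bins, last bin
closed; out-of-range values dropped). The median of the raw counts is
returned alongside and drawn as a dashed line in the histogram plot.

## Coverage profiles

`bin_region` tiles `[s, e]` into n bins with bin i covering
`[s + ⌊(i−1)W/n⌋, s + ⌊iW/n⌋ − 1]` (W = width): disjoint, exactly
covering, widths differing by at most 1 bp. Regions with `W < n` cannot be
tiled into n non-empty bins and are dropped with a warning and counted in
`n_dropped_short`, rather than padded.

A subject element spanning k bins contributes +1 to **each** of the k bins
(not fractionally, not once per region). Per-bin presence is the simplest
rule that renders edge-enrichment profiles faithfully; the trade-off is
that row sums exceed hit counts for multi-bin elements (bounded by
hit_count × n_bins, a tested invariant). Coverage uses the same
`OverlapParams` hit rule as the main engine — one overlap semantics
everywhere. With `orient=True` (default) the bin order of `-` strand
queries is reversed so bin 1 is always the 5′ end; flipping every query
strand exactly reverses each matrix row (tested).

## Synthetic data generators

The generators make every statistical claim testable against known truth:

- `generate_region_set`: regions uniform over a toy genome, chromosomes
  weighted by size, lengths uniform in a range, strands from
  (p₊, p₋, p\*). Randomized engine-vs-oracle instances use 1,000 regions
  per set on a 1 Mb chromosome with lengths 50–2,000 bp and 10% unstranded
  regions — dense enough for ~2,000 hits per instance, covering all
  predicate branches.
- `tiled_region_set`: n disjoint equal-width regions along one chromosome
  (default 1,000 bp bodies, 500 bp gaps, random strands). Disjointness
  guarantees zero cross-region contamination, so planted counts are
  recovered *exactly*, not just in expectation.
- `generate_subjects_for`: per query region, k ~ Poisson(rate) elements
  placed inside the body. `uniform` draws the 5′ offset uniformly;
  `five_prime` draws it with density f(u) = 2(1 − u) on [0, 1) via the
  inverse CDF u = 1 − √(1 − v), strand-aware. The true per-query counts
  are returned for parameter-recovery tests.

Recovery checks (fixed seeds, n = 2,000 queries, rate 4): the observed
mean is within 3·√(λ/n) ≈ 0.134 of λ = 4; the uniform-placement 100-bin
profile is flat up to multinomial fluctuation, formalized as a chi-square
goodness-of-fit statistic below the 99.9th percentile of χ²₉₉ (≈ 148) —
single-length (1 bp) elements are used here so each element falls in
exactly one bin and the multinomial null is exact; the 5′-biased profile
puts ~19× more mass in the first decile than the last (0.19 vs 0.01 of
the density).

What the generators deliberately do not emulate: realistic genome
composition (GC content, repeats), clustered or overlapping annotation
structure, chromosome-scale heterogeneity, or any sequence content.
Passing tests therefore demonstrate the correctness of the interval
algebra, accounting, and orientation logic under controlled conditions —
not biological realism of any particular annotation release.

## The fixed toy workspace

`make_toy_workspace` pins a 10-gene, 25-subject configuration whose full
hit structure was enumerated independently by hand (fractions
double-checked with exact rational arithmetic) and frozen as golden CSVs
in `tests/data/golden/`. It exercises: partial, contained, single-base,
and exact-coincidence overlaps; a minus-strand gene; an opposite-strand
subject pair (dropped in stranded mode, 4 → 3 CGI hits); a gene shorter
than 100 bp (dropped by coverage); and a chromosome without subjects.
Expected totals: 10 TFBS + 4 CGI + 7 promoter hits, 8 of 10 genes with at
least one hit, mean 2.1 elements per gene.

## Numerical and formatting choices

CSV writers emit RFC-4180-style output with a fixed column order,
`\n` line endings, and floats formatted `%.6g`, so identical inputs give
byte-identical files. Chromosome-name normalization maps canonical
chromosomes (autosomes, X, Y, MT/chrM) between UCSC and Ensembl styles and
leaves unrecognized contigs verbatim with one warning each. Duplicate
detection keys on (chrom, start, end, strand) only — metadata differences
do not rescue a duplicate interval. Plots use the Agg backend with fixed
figure sizes; the track plot's default window is the query region ± 10%
flanks (the flank size is this package's convention; any explicit window
overrides it).

## Scaling against real annotation releases

The library-scale checks above run on synthetic data by design. Runs
against full public annotation releases (e.g. a GENCODE gene set versus
JASPAR TFBS filtered to one factor with `subset_regions(name=...)`, or a
protein-coding gene set overlapped against itself to count overlapping
genes) follow exactly the `examples/04` + CLI pattern once those files are
downloaded locally: genome-wide gene sets are a few×10⁴ regions and
complete in seconds. No hosted-annotation connectivity is built in; inputs
are always local files.

## Known limitations

- No nearest-neighbour/distance queries, overlap-enrichment permutation
  tests, or significance testing of count differences between region sets
  (standard tests apply downstream of the exported counts).
- No liftover; build mismatches are only warned about.
- Coverage has no flanking-window extension and no length normalization
  beyond the equal-bin tiling itself.
- Track plots draw plain boxes/arrows, not exon-aware gene models.
- BED readers cover BED3–BED6; BigBed/BigWig/VCF are out of scope.
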