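"""Synthetic region-set generators.

Every module of this package is testable without downloading any annotation:
:func:`generate_region_set` draws random regions on a toy genome,
:func:`generate_subjects_for` plants Poisson-distributed subject elements
inside query bodies (uniformly or with a 5' bias) so that summary and
coverage results can be checked against known truth, and
:func:`make_toy_workspace` returns a small fixed workspace whose exact hit
counts and fractions are hand-enumerable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GenomicRegion, RegionSet, Workspace


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random region set.

    Regions land uniformly on the genome, chromosomes weighted by size;
    lengths are uniform over ``length_range`` (a == b gives fixed length);
    strands are drawn from ``strand_probs`` = (p_plus, p_minus, p_star).
    """

    n_regions: int = 100
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000}
    )
    length_range: tuple[int, int] = (100, 1000)
    strand_probs: tuple[float, float, float] = (0.5, 0.5, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.strand_probs), 1.0, abs_tol=1e-9):
            raise ValueError("strand_probs must sum to 1")
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if max(self.length_range) > max(self.chrom_sizes.values()):
            raise ValueError("region length exceeds every chromosome size")


def generate_region_set(spec: FixtureSpec, name: str = "random") -> RegionSet:
    """Random region set; a pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    chroms = sorted(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    lo, hi = spec.length_range
    regions = []
    for i in range(spec.n_regions):
        c = rng.choice(len(chroms), p=sizes / sizes.sum())
        size = spec.chrom_sizes[chroms[c]]
        length = int(rng.integers(lo, hi + 1))
        if length > size:
            raise ValueError(
                f"region length {length} exceeds chromosome {chroms[c]} ({size} bp)"
            )
        start = int(rng.integers(1, size - length + 2))
        strand = ("+", "-", "*")[rng.choice(3, p=spec.strand_probs)]
        regions.append(
            GenomicRegion(chroms[c], start, start + length - 1, strand, f"r{i}")
        )
    return RegionSet(name, regions, source={"fixture": "generate_region_set",
                                            "seed": spec.seed})


def tiled_region_set(
    n: int,
    width: int = 1000,
    gap: int = 500,
    chrom: str = "chr1",
    name: str = "tiled",
    strands: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> RegionSet:
    """``n`` disjoint, equally sized regions laid out along one chromosome.

    Guarantees zero cross-region contamination, so subjects planted inside
    one region by :func:`generate_subjects_for` hit exactly that region —
    the clean backdrop for parameter-recovery tests. Strands alternate
    randomly between "+" and "-" unless ``strands`` is given.
    """
    rng = np.random.default_rng(seed)
    if strands is None:
        strands = [("+", "-")[int(b)] for b in rng.integers(0, 2, size=n)]
    regions = []
    for i in range(n):
        start = 1 + i * (width + gap)
        regions.append(
            GenomicRegion(chrom, start, start + width - 1, strands[i], f"q{i}")
        )
    return RegionSet(name, regions, source={"fixture": "tiled_region_set",
                                            "seed": seed})


def generate_subjects_for(
    query: RegionSet,
    rate: float,
    bias: str = "uniform",
    lengths: tuple[int, int] = (10, 30),
    seed: int = 0,
    name: str = "subjects",
) -> tuple[RegionSet, np.ndarray]:
    """Plant subject elements inside query bodies with known counts.

    Per query region, k ~ Poisson(rate) subjects are placed inside the body:
    ``bias="uniform"`` draws the start offset uniformly; ``bias="five_prime"``
    draws it with linearly decaying density from the 5' end (density
    f(u) = 2 (1 - u) on [0, 1), strand-aware, via inverse CDF
    u = 1 - sqrt(1 - v)). Subjects are truncated to fit the region so every
    planted element overlaps exactly its own query (when queries are
    disjoint). Returns the subject set and the true per-query counts.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if bias not in ("uniform", "five_prime"):
        raise ValueError("bias must be 'uniform' or 'five_prime'")
    rng = np.random.default_rng(seed)
    regions = []
    true_counts = np.zeros(len(query), dtype=np.int64)
    j = 0
    for qi, q in enumerate(query):
        k = rng.poisson(rate)
        true_counts[qi] = k
        for _ in range(k):
            if bias == "uniform":
                u = rng.random()
            else:
                u = 1.0 - math.sqrt(1.0 - rng.random())
            offset_5p = int(u * q.width)  # offset from the 5' end, in [0, width)
            if q.strand == "-":
                pos = q.end - offset_5p
            else:
                pos = q.start + offset_5p
            length = int(rng.integers(lengths[0], lengths[1] + 1))
            if q.strand == "-":
                start, end = max(q.start, pos - length + 1), pos
            else:
                start, end = pos, min(q.end, pos + length - 1)
            regions.append(
                GenomicRegion(q.chrom, start, end, "*", f"s{j}")
            )
            j += 1
    return (
        RegionSet(name, regions, source={"fixture": "generate_subjects_for",
                                         "rate": rate, "bias": bias, "seed": seed}),
        true_counts,
    )


def make_toy_workspace() -> Workspace:
    """A small fixed workspace with hand-enumerable overlap structure.

    Ten "gene" query regions on three chromosomes (one minus-strand gene,
    one gene shorter than 100 bp to exercise coverage dropping, one gene on
    a subject-free chromosome) against three subject sets: 12 TFBS, 6 CpG
    islands, 7 promoters. Expected hits under the default parameters:
    10 gene-TFBS, 4 gene-CGI, 7 gene-promoter (21 total; 8 of 10 genes with
    at least one hit). One TFBS coincides exactly with gene g3 and one CGI
    spans exactly gene g7 (on the opposite strand), exercising the "equal"
    and "within" types and the stranded mode.
    """
    genes = RegionSet(
        "genes",
        [
            GenomicRegion("chr1", 1000, 2000, "+", "g0"),
            GenomicRegion("chr1", 3000, 3500, "+", "g1"),
            GenomicRegion("chr1", 5000, 7000, "-", "g2"),
            GenomicRegion("chr1", 9000, 9100, "+", "g3"),
            GenomicRegion("chr1", 12000, 15000, "+", "g4"),
            GenomicRegion("chr2", 1000, 2000, "+", "g5"),
            GenomicRegion("chr2", 4000, 4200, "-", "g6"),
            GenomicRegion("chr2", 6000, 9000, "+", "g7"),
            GenomicRegion("chr2", 10000, 10050, "+", "g8"),
            GenomicRegion("chr3", 500, 1500, "+", "g9"),
        ],
        genome_label="toy1",
    )
    tfbs = RegionSet(
        "tfbs",
        [
            GenomicRegion("chr1", 1100, 1110, "*", "t0"),
            GenomicRegion("chr1", 1500, 1520, "*", "t1"),
            GenomicRegion("chr1", 1990, 2010, "*", "t2"),
            GenomicRegion("chr1", 2500, 2600, "*", "t3"),
            GenomicRegion("chr1", 3400, 3600, "*", "t4"),
            GenomicRegion("chr1", 5000, 5050, "*", "t5"),
            GenomicRegion("chr1", 6995, 7005, "*", "t6"),
            GenomicRegion("chr1", 9000, 9100, "*", "t7"),
            GenomicRegion("chr1", 13000, 13100, "*", "t8"),
            GenomicRegion("chr2", 1000, 1000, "*", "t9"),
            GenomicRegion("chr2", 8000, 8100, "*", "t10"),
            GenomicRegion("chr2", 9500, 9600, "*", "t11"),
        ],
        genome_label="toy1",
    )
    cgi = RegionSet(
        "cgi",
        [
            GenomicRegion("chr1", 900, 1200, "*", "c0"),
            GenomicRegion("chr1", 4950, 5100, "*", "c1"),
            GenomicRegion("chr1", 11000, 11500, "*", "c2"),
            GenomicRegion("chr2", 950, 1050, "*", "c3"),
            GenomicRegion("chr2", 6000, 9000, "-", "c4"),
            GenomicRegion("chr3", 2000, 2100, "*", "c5"),
        ],
        genome_label="toy1",
    )
    promoters = RegionSet(
        "promoters",
        [
            GenomicRegion("chr1", 800, 1000, "+", "p0"),
            GenomicRegion("chr1", 2900, 3000, "+", "p1"),
            GenomicRegion("chr1", 6900, 7100, "-", "p2"),
            GenomicRegion("chr1", 8900, 9000, "+", "p3"),
            GenomicRegion("chr1", 11800, 12100, "+", "p4"),
            GenomicRegion("chr2", 5800, 6050, "+", "p5"),
            GenomicRegion("chr2", 9950, 10010, "+", "p6"),
        ],
        genome_label="toy1",
    )
    ws = Workspace(
        datasets={rs.name: rs for rs in (genes, tfbs, cgi, promoters)},
        query_name="genes",
        subject_names=["tfbs", "cgi", "promoters"],
    )
    ws.record("toy workspace: 10 genes vs 12 TFBS + 6 CGI + 7 promoters")
    return ws
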