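"""Strand-aware region resizing and subsetting.

The typical use is carving promoter windows out of gene annotations before
the overlap run, e.g. 1200 bp upstream of each transcription start site
(TSS), honouring the reading orientation: on the "-" strand the TSS is the
higher genomic coordinate and "upstream" extends to the right.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from .core import GenomicRegion, RegionSet

logger = logging.getLogger(__name__)

ANCHORS = ("tss", "tes", "body")


@dataclass(frozen=True)
class ResizeSpec:
    """How to resize each region.

    ``anchor`` picks the reference point: "tss" (5' end), "tes" (3' end) or
    "body" (keep both ends, extend outward). ``upstream`` bases extend 5' of
    the anchor, ``downstream`` bases 3' of it. With an end anchor the anchor
    base itself is position 0 and included by default, so upstream=1200,
    downstream=0 yields a width of 1201. ``include_anchor_base=False``
    excludes it, but only a pure upstream or pure downstream window can do so
    and stay contiguous; with both distances positive the flag is ignored
    with a warning.
    """

    upstream: int = 0
    downstream: int = 0
    anchor: str = "tss"
    include_anchor_base: bool = True

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream/downstream must be >= 0")
        if self.anchor not in ANCHORS:
            raise ValueError(f"anchor must be one of {ANCHORS}")
        if self.anchor != "body" and not self.include_anchor_base:
            if self.upstream == 0 and self.downstream == 0:
                raise ValueError("empty window: no distance and no anchor base")


def _window(r: GenomicRegion, spec: ResizeSpec) -> tuple[int, int]:
    """Unclipped (start, end) of the resized interval."""
    # "*" anchors like "+" (deterministic for unstranded inputs)
    forward = r.strand != "-"
    if spec.anchor == "body":
        if forward:
            return r.start - spec.upstream, r.end + spec.downstream
        return r.start - spec.downstream, r.end + spec.upstream
    if spec.anchor == "tss":
        a = r.start if forward else r.end
    else:  # tes
        a = r.end if forward else r.start
    if forward:
        lo, hi = a - spec.upstream, a + spec.downstream
    else:
        lo, hi = a - spec.downstream, a + spec.upstream
    if not spec.include_anchor_base:
        up, down = spec.upstream, spec.downstream
        if up > 0 and down == 0:
            if forward:
                hi = a - 1
            else:
                lo = a + 1
        elif down > 0 and up == 0:
            if forward:
                lo = a + 1
            else:
                hi = a - 1
        # both positive: anchor unavoidably interior; caller warned once
    return lo, hi


def resize_regions(
    rs: RegionSet,
    spec: ResizeSpec,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> RegionSet:
    """Resize every region of a set per ``spec``, strand-aware.

    Coordinates are clipped to ``[1, chrom_size]`` when sizes are given and
    to ``[1, inf)`` otherwise; clipping is logged. Regions that become empty
    after clipping are dropped with a warning. Unstranded regions anchor
    like "+" (one warning per dataset).
    """
    out: list[GenomicRegion] = []
    n_clipped = n_dropped = 0
    warned_star = warned_anchor = False
    for r in rs:
        if r.strand == "*" and spec.anchor != "body" and not warned_star:
            logger.warning(
                "%s: unstranded regions anchored like '+' strand", rs.name
            )
            warned_star = True
        if (
            not spec.include_anchor_base
            and spec.anchor != "body"
            and spec.upstream > 0
            and spec.downstream > 0
            and not warned_anchor
        ):
            logger.warning(
                "include_anchor_base=False ignored: window spans both sides "
                "of the anchor"
            )
            warned_anchor = True
        lo, hi = _window(r, spec)
        size = chrom_sizes.get(r.chrom) if chrom_sizes else None
        clo = max(lo, 1)
        chi = min(hi, size) if size is not None else hi
        if (clo, chi) != (lo, hi):
            n_clipped += 1
        if chi < clo:
            n_dropped += 1
            logger.warning(
                "%s: region %s empty after clipping, dropped", rs.name, r
            )
            continue
        out.append(
            GenomicRegion(r.chrom, clo, chi, r.strand, r.name, r.score, r.attrs)
        )
    if n_clipped:
        logger.info("%s: clipped %d region(s) to chromosome bounds", rs.name,
                    n_clipped)
    new = rs.replace(out)
    new.source["resize"] = {
        "upstream": spec.upstream,
        "downstream": spec.downstream,
        "anchor": spec.anchor,
        "n_clipped": n_clipped,
        "n_dropped": n_dropped,
    }
    return new


def subset_regions(
    rs: RegionSet,
    name: Optional[str] = None,
    name_pattern: Optional[str] = None,
    chroms: Optional[set[str]] = None,
    strand: Optional[str] = None,
    min_score: Optional[float] = None,
    attrs: Optional[Mapping[str, str]] = None,
) -> RegionSet:
    """Order-preserving filter on region fields.

    Criteria combine with AND: exact ``name``, regex ``name_pattern``,
    chromosome membership, strand, minimum score, and exact-match attribute
    values. Referencing an attribute key absent from every region is an
    error (it is almost certainly a typo). The number of removed regions is
    logged.
    """
    if attrs:
        for key in attrs:
            if not any(r.attrs and key in r.attrs for r in rs):
                raise KeyError(
                    f"attribute {key!r} not present in any region of {rs.name!r}"
                )
    pattern = re.compile(name_pattern) if name_pattern else None
    out = []
    for r in rs:
        if name is not None and r.name != name:
            continue
        if pattern is not None and not pattern.search(r.name or ""):
            continue
        if chroms is not None and r.chrom not in chroms:
            continue
        if strand is not None and r.strand != strand:
            continue
        if min_score is not None and (r.score is None or r.score < min_score):
            continue
        if attrs and not all(
            r.attrs is not None and r.attrs.get(k) == v for k, v in attrs.items()
        ):
            continue
        out.append(r)
    logger.info("subset_regions(%s): kept %d of %d", rs.name, len(out), len(rs))
    return rs.replace(out)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
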