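"""Shared data model: regions, region sets, and workspaces.

All coordinates in this package are 1-based, closed intervals (GFF-style):
a region spanning positions ``start..end`` includes both endpoints and has
width ``end - start + 1``. Format converters in :mod:`regionoverlap.io`
normalize to this convention on read and back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", "*")

#: integer codes used by the vectorized engines: "+" -> 1, "-" -> -1, "*" -> 0
STRAND_CODES = {"+": 1, "-": -1, "*": 0}


@dataclass(frozen=True)
class GenomicRegion:
    """One genomic interval.

    Parameters
    ----------
    chrom
        Chromosome / contig name (any style; see
        :func:`regionoverlap.io.normalize_chrom_names`).
    start, end
        1-based inclusive coordinates, ``1 <= start <= end``.
    strand
        ``"+"``, ``"-"``, or ``"*"`` (unstranded). An unstranded region is
        compatible with both strands in strand-specific operations.
    name, score, attrs
        Optional metadata carried through from the source file.
    """

    chrom: str
    start: int
    end: int
    strand: str = "*"
    name: Optional[str] = None
    score: Optional[float] = None
    attrs: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.attrs is not None and not isinstance(self.attrs, MappingProxyType):
            object.__setattr__(self, "attrs", MappingProxyType(dict(self.attrs)))

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        s = f"{self.chrom}:{self.start}-{self.end}({self.strand})"
        return f"{s} {self.name}" if self.name else s


def region_width(r: GenomicRegion) -> int:
    """Width of a region in base pairs (closed-interval arithmetic)."""
    return r.end - r.start + 1


def infer_chrom_style(chroms: Sequence[str]) -> str:
    """Classify chromosome naming as "ucsc" (chr-prefixed), "ensembl", or "mixed"."""
    if not chroms:
        return "ucsc"
    prefixed = [c.startswith("chr") for c in set(chroms)]
    if all(prefixed):
        return "ucsc"
    if not any(prefixed):
        return "ensembl"
    return "mixed"


class RegionSet:
    """An ordered, named collection of :class:`GenomicRegion`.

    Input order is preserved and the 0-based position of a region in the set
    is its stable identifier (the ``query_index`` / ``subject_index`` used by
    the overlap engine). Serializing and re-reading a set preserves order.
    """

    def __init__(
        self,
        name: str,
        regions: Sequence[GenomicRegion],
        genome_label: Optional[str] = None,
        source: Optional[dict] = None,
        chrom_style: Optional[str] = None,
    ) -> None:
        self.name = name
        self.regions: list[GenomicRegion] = list(regions)
        self.genome_label = genome_label
        self.source = dict(source) if source else {}
        self.chrom_style = chrom_style or infer_chrom_style(
            [r.chrom for r in self.regions]
        )
        self._arrays: Optional[dict[str, np.ndarray]] = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionSet({self.name!r}, n={len(self)})"

    # -- vectorized views ---------------------------------------------------

    def arrays(self) -> dict[str, np.ndarray]:
        """Column arrays (chrom, start, end, strand code), cached."""
        if self._arrays is None:
            self._arrays = {
                "chrom": np.array([r.chrom for r in self.regions], dtype=object),
                "start": np.array([r.start for r in self.regions], dtype=np.int64),
                "end": np.array([r.end for r in self.regions], dtype=np.int64),
                "strand": np.array(
                    [STRAND_CODES[r.strand] for r in self.regions], dtype=np.int8
                ),
            }
        return self._arrays

    def to_frame(self) -> pd.DataFrame:
        """Regions as a DataFrame (one row per region, original order)."""
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "strand": [r.strand for r in self.regions],
                "name": [r.name for r in self.regions],
                "score": [r.score for r in self.regions],
            }
        )

    def region_label(self, index: int, role: str = "region") -> str:
        """Display name of region ``index``; generated ``<role>_<i>`` if unnamed."""
        r = self.regions[index]
        return r.name if r.name else f"{role}_{index}"

    def replace(self, regions: Sequence[GenomicRegion], **kw) -> "RegionSet":
        """Copy of this set with new regions (metadata carried over)."""
        out = RegionSet(
            name=kw.pop("name", self.name),
            regions=regions,
            genome_label=kw.pop("genome_label", self.genome_label),
            source=kw.pop("source", dict(self.source)),
            chrom_style=kw.pop("chrom_style", None),
        )
        return out


@dataclass
class Workspace:
    """Named map of region sets with query/subject designations.

    One set is the *query* (the user's regions of interest, e.g. genes or
    DEGs); the remaining sets are *subjects* (annotations such as TFBS, CpG
    islands, promoters). ``log`` accumulates processing messages so a run
    leaves an audit trail.
    """

    datasets: dict[str, RegionSet] = field(default_factory=dict)
    query_name: str = ""
    subject_names: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def add(self, rs: RegionSet) -> None:
        self.datasets[rs.name] = rs

    @property
    def query(self) -> RegionSet:
        return self.datasets[self.query_name]

    def subjects(self) -> list[RegionSet]:
        return [self.datasets[n] for n in self.subject_names]

    def record(self, message: str) -> None:
        self.log.append(message)
        logger.info(message)


def validate_workspace(ws: Workspace) -> list[str]:
    """Scan a workspace for consistency issues; never mutates data.

    Returns warning strings for mixed chromosome naming styles across
    datasets, differing genome labels, and empty datasets. Missing
    query/subject dataset names are a hard error (the workspace is unusable).
    """
    if ws.query_name not in ws.datasets:
        raise KeyError(f"query dataset {ws.query_name!r} not in workspace")
    missing = [n for n in ws.subject_names if n not in ws.datasets]
    if missing:
        raise KeyError(f"subject dataset(s) not in workspace: {missing}")

    issues: list[str] = []
    styles = {name: rs.chrom_style for name, rs in ws.datasets.items()}
    if len(set(styles.values())) > 1:
        issues.append(f"mixed chromosome naming styles across datasets: {styles}")
    labels = {
        name: rs.genome_label
        for name, rs in ws.datasets.items()
        if rs.genome_label is not None
    }
    if len(set(labels.values())) > 1:
        issues.append(f"differing genome labels across datasets: {labels}")
    for name, rs in ws.datasets.items():
        if len(rs) == 0:
            issues.append(f"dataset {name!r} is empty")
    return issues
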