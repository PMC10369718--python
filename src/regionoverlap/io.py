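"""Readers and writers for region sets and result tables.

Input formats and their coordinate conventions:

========  =================================  ==========================
format    convention on disk                 normalization on read
========  =================================  ==========================
BED       0-based, half-open [start, end)    start + 1 .. end
GFF3/GTF  1-based, closed                    verbatim
table     declared per :class:`ColumnMap`    per ``coordinate_convention``
========  =================================  ==========================

Writers emit RFC-4180-style CSV with a fixed column order so outputs are
deterministic and diffable.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import GenomicRegion, RegionSet, Workspace, infer_chrom_style
from .overlap import HitTable, annotate_hits

logger = logging.getLogger(__name__)

#: float formatting used by every CSV writer (fractions etc.)
FLOAT_FORMAT = "%.6g"

_BED_SKIP = re.compile(r"^(#|track\b|browser\b)")


def read_bed(path: str | Path, name: Optional[str] = None) -> RegionSet:
    """Read a BED3-BED6 file into a RegionSet.

    BED's 0-based half-open ``[chromStart, chromEnd)`` is converted to the
    internal 1-based closed convention, ``[chromStart + 1, chromEnd]``.
    Columns 4-6 map to name/score/strand when present; a missing strand (or
    ``"."``) becomes ``"*"``. Malformed lines raise with the line number.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or _BED_SKIP.match(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                cstart, cend = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if cend <= cstart:
                raise ValueError(
                    f"{path.name}:{lineno}: chromEnd ({cend}) must exceed "
                    f"chromStart ({cstart})"
                )
            rname = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    logger.warning("%s:%d: unparseable score %r", path.name, lineno,
                                   fields[4])
            strand = fields[5] if len(fields) > 5 else "*"
            if strand not in ("+", "-"):
                strand = "*"
            regions.append(
                GenomicRegion(chrom, cstart + 1, cend, strand, rname, score)
            )
    return RegionSet(
        name=name or path.stem,
        regions=regions,
        source={"path": str(path), "format": "bed"},
    )


def write_bed(rs: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED6, converting back to 0-based half-open."""
    with open(path, "w") as fh:
        for r in rs:
            score = "." if r.score is None else FLOAT_FORMAT % r.score
            strand = "." if r.strand == "*" else r.strand
            fh.write(
                "\t".join(
                    [r.chrom, str(r.start - 1), str(r.end), r.name or ".",
                     score, strand]
                )
                + "\n"
            )


_GFF3_ATTR = re.compile(r"\s*([^=;\s]+)\s*=\s*([^;]*)")
_GTF_ATTR = re.compile(r'\s*(\S+)\s+"([^"]*)"')


def parse_gff_attributes(text: str) -> dict[str, str]:
    """Parse a column-9 attribute string; GFF3 (k=v;) and GTF (k "v";)."""
    text = text.strip()
    if not text or text == ".":
        return {}
    if '"' in text:
        return {k: v for k, v in _GTF_ATTR.findall(text)}
    return {k: v.strip() for k, v in _GFF3_ATTR.findall(text)}


def read_gff(
    path: str | Path,
    feature_types: Optional[set[str]] = None,
    name_attribute: str = "ID",
    name: Optional[str] = None,
) -> RegionSet:
    """Read a GFF3/GTF file (coordinates taken verbatim: already 1-based closed).

    Rows are filtered to ``feature_types`` when given (column 3). Region
    names come from ``name_attribute`` in column 9 ("ID", "gene_id", ...),
    falling back to a generated ``row<N>`` identifier, where N is the source
    line number.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 9 tab-separated GFF columns"
                )
            chrom, _src, ftype, start, end, score, strand = fields[:7]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                attrs = parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
            except Exception:
                logger.warning("%s:%d: unparseable attribute string", path.name,
                               lineno)
                attrs = {}
            rname = attrs.get(name_attribute) or f"row{lineno}"
            score_f = None if score in (".", "") else float(score)
            regions.append(
                GenomicRegion(
                    chrom,
                    start_i,
                    end_i,
                    strand if strand in ("+", "-") else "*",
                    rname,
                    score_f,
                    attrs or None,
                )
            )
    return RegionSet(
        name=name or path.stem,
        regions=regions,
        source={"path": str(path), "format": "gff",
                "feature_types": sorted(feature_types) if feature_types else None,
                "name_attribute": name_attribute},
    )


@dataclass(frozen=True)
class ColumnMap:
    """How to interpret a generic delimited table of regions.

    ``coordinate_convention`` is ``"onebased"`` (closed, like GFF) or
    ``"bed0"`` (0-based half-open, like BED).
    """

    chrom_col: str
    start_col: str
    end_col: str
    strand_col: Optional[str] = None
    name_col: Optional[str] = None
    score_col: Optional[str] = None
    coordinate_convention: str = "onebased"

    def __post_init__(self) -> None:
        required = (self.chrom_col, self.start_col, self.end_col)
        if any(not c for c in required) or len(set(required)) != 3:
            raise ValueError("chrom/start/end columns must be distinct and non-empty")
        if self.coordinate_convention not in ("onebased", "bed0"):
            raise ValueError("coordinate_convention must be 'onebased' or 'bed0'")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_table(
    path: str | Path,
    colmap: ColumnMap,
    delimiter: Optional[str] = None,
    name: Optional[str] = None,
) -> RegionSet:
    """Read a delimited table (header row required) into a RegionSet.

    The delimiter is auto-detected among ``, ; <tab>`` unless given.
    Coordinates are normalized per ``colmap.coordinate_convention``.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    wanted = [
        c
        for c in (colmap.chrom_col, colmap.start_col, colmap.end_col,
                  colmap.strand_col, colmap.name_col, colmap.score_col)
        if c is not None
    ]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing column(s) {missing}; available: "
            f"{list(df.columns)}"
        )
    offset = 1 if colmap.coordinate_convention == "bed0" else 0
    regions = []
    for _, row in df.iterrows():
        strand = str(row[colmap.strand_col]) if colmap.strand_col else "*"
        if strand not in ("+", "-"):
            strand = "*"
        regions.append(
            GenomicRegion(
                chrom=str(row[colmap.chrom_col]),
                start=int(row[colmap.start_col]) + offset,
                end=int(row[colmap.end_col]),
                strand=strand,
                name=str(row[colmap.name_col]) if colmap.name_col else None,
                score=float(row[colmap.score_col]) if colmap.score_col else None,
            )
        )
    return RegionSet(
        name=name or path.stem,
        regions=regions,
        source={"path": str(path), "format": "table", "delimiter": sep},
    )


_SUFFIX_READERS = {
    ".bed": read_bed,
    ".gff": read_gff,
    ".gff3": read_gff,
    ".gtf": read_gff,
}


def scan_directory(
    directory: str | Path,
    colmap: Optional[ColumnMap] = None,
    query: Optional[str] = None,
    subjects: Optional[Sequence[str]] = None,
) -> Workspace:
    """Scan a directory for region files and assemble a Workspace.

    Every ``*.bed``, ``*.gff/gff3/gtf`` and ``*.csv`` file becomes a dataset
    named after its file stem. The alphabetically first dataset defaults to
    query, the remainder to subjects; both are overridable. CSV files need a
    ``colmap`` (default: chrom/start/end headers, 1-based).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    colmap = colmap or ColumnMap("chrom", "start", "end", strand_col=None)
    ws = Workspace()
    for path in sorted(directory.iterdir(), key=lambda p: p.stem):
        suffix = path.suffix.lower()
        try:
            if suffix in _SUFFIX_READERS:
                rs = _SUFFIX_READERS[suffix](path)
            elif suffix == ".csv":
                rs = read_table(path, colmap)
            else:
                continue
        except Exception as exc:
            logger.warning("skipping unreadable file %s: %s", path.name, exc)
            ws.record(f"skipped {path.name}: {exc}")
            continue
        ws.add(rs)
        ws.record(f"read {len(rs)} regions from {path.name}")
    if not ws.datasets:
        raise FileNotFoundError(f"no region files (*.bed, *.gff*, *.csv) in {directory}")
    names = sorted(ws.datasets)
    ws.query_name = query or names[0]
    ws.subject_names = list(subjects) if subjects else [
        n for n in names if n != ws.query_name
    ]
    return ws


_CANONICAL = {str(i) for i in range(1, 100)} | {"X", "Y"}


def normalize_chrom_names(rs: RegionSet, style: str) -> RegionSet:
    """Convert chromosome names to "ucsc" (chr1, chrM) or "ensembl" (1, MT).

    Canonical chromosomes (autosomes, X, Y, mitochondrion) are mapped;
    unrecognized contigs are kept verbatim with one logged warning each.
    """
    if style not in ("ucsc", "ensembl"):
        raise ValueError("style must be 'ucsc' or 'ensembl'")
    warned: set[str] = set()
    out = []
    for r in rs:
        chrom = r.chrom
        if style == "ucsc":
            if chrom in _CANONICAL:
                chrom = "chr" + chrom
            elif chrom == "MT":
                chrom = "chrM"
            elif not (chrom.startswith("chr")):
                if chrom not in warned:
                    logger.warning("unrecognized contig %r left unchanged", chrom)
                    warned.add(chrom)
        else:
            if chrom.startswith("chr") and chrom[3:] in _CANONICAL:
                chrom = chrom[3:]
            elif chrom == "chrM":
                chrom = "MT"
            elif chrom.startswith("chr"):
                if chrom not in warned:
                    logger.warning("unrecognized contig %r left unchanged", chrom)
                    warned.add(chrom)
        out.append(
            GenomicRegion(chrom, r.start, r.end, r.strand, r.name, r.score, r.attrs)
        )
    new = rs.replace(out)
    new.chrom_style = infer_chrom_style([r.chrom for r in out]) if warned else style
    return new


def deduplicate(rs: RegionSet) -> tuple[RegionSet, int]:
    """Collapse regions identical in (chrom, start, end, strand).

    The first occurrence survives; relative order is preserved. Name and
    score are deliberately ignored: duplicates in annotation dumps differ in
    metadata but represent one interval. Returns the filtered set and the
    number of regions removed.
    """
    seen: set[tuple] = set()
    out = []
    for r in rs:
        key = (r.chrom, r.start, r.end, r.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    n_removed = len(rs) - len(out)
    if n_removed:
        logger.info("deduplicate(%s): removed %d duplicate region(s)", rs.name,
                    n_removed)
    return rs.replace(out), n_removed


# ---------------------------------------------------------------------------
# result tables


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_long_table(
    hits: HitTable | pd.DataFrame,
    path: str | Path,
    query: Optional[RegionSet] = None,
    subject: Optional[RegionSet] = None,
) -> pd.DataFrame:
    """Write the long-format hit table: one CSV row per hit.

    Accepts either an already-annotated DataFrame (from
    :func:`regionoverlap.overlap.annotate_hits`, possibly concatenated over
    several subject sets) or a raw :class:`HitTable` plus its two region
    sets. Rows are sorted by query index then subject index.
    """
    if isinstance(hits, HitTable):
        if query is None or subject is None:
            raise ValueError("query and subject sets required to annotate a HitTable")
        df = annotate_hits(hits, query, subject)
    else:
        df = hits.copy()
    df = df.sort_values(
        ["query_index", "subject_dataset", "subject_index"], kind="stable"
    ).reset_index(drop=True)
    _write_csv(df, path)
    return df


def write_wide_table(
    hit_tables: Sequence[HitTable],
    ws: Workspace,
    path: str | Path,
) -> pd.DataFrame:
    """Write the wide-format table: one CSV row per query region.

    Every input query region is listed (also the hit-less ones). Per subject
    dataset three columns are emitted: a presence flag, the overlap count,
    and a ";"-joined list of overlapping subject region names.
    """
    query = ws.query
    base = pd.DataFrame(
        {
            "query_index": range(len(query)),
            "query_name": [query.region_label(i, "query") for i in range(len(query))],
            "chrom": [r.chrom for r in query],
            "query_start": [r.start for r in query],
            "query_end": [r.end for r in query],
            "query_strand": [r.strand for r in query],
        }
    )
    for ht in hit_tables:
        subject = ws.datasets[ht.subject_name]
        present = [False] * len(query)
        counts = [0] * len(query)
        names: list[list[str]] = [[] for _ in range(len(query))]
        for qi, si in zip(ht.df["query_index"], ht.df["subject_index"]):
            present[qi] = True
            counts[qi] += 1
            names[qi].append(subject.region_label(si, "subject"))
        ds = ht.subject_name
        base[f"{ds}_present"] = present
        base[f"{ds}_count"] = counts
        base[f"{ds}_names"] = [";".join(n) for n in names]
    _write_csv(base, path)
    return base
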