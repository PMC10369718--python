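"""Query-subject overlap engine.

A *hit* is a (query, subject) region pair overlapping in at least one
nucleotide base, subject to three orthogonal parameters:

``min_overlap``
    minimum intersection width in bp (default 1);
``type``
    ``"any"`` (partial or complete), ``"within"`` (query interval entirely
    inside the subject interval — the reverse containment is obtained by
    swapping roles), or ``"equal"`` (identical endpoints);
``ignore_strand``
    when False, hits require equal strands, with ``"*"`` compatible with
    both.

Each hit is annotated with the intersection coordinates, its width, and the
overlapped nucleotide fraction with respect to each original input region.

Two independent routes compute the same hit set: :func:`find_overlaps`
(per-chromosome interval index, sub-quadratic) and
:func:`brute_force_overlaps` (direct evaluation of every pair, the reference
semantics used as a test oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import RegionSet

HIT_COLUMNS = [
    "query_index",
    "subject_index",
    "chrom",
    "ov_start",
    "ov_end",
    "ov_width",
    "frac_query",
    "frac_subject",
]

OVERLAP_TYPES = ("any", "within", "equal")


@dataclass(frozen=True)
class OverlapParams:
    """Parameters of the hit definition (see module docstring)."""

    min_overlap: int = 1
    type: str = "any"
    ignore_strand: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.type not in OVERLAP_TYPES:
            raise ValueError(f"type must be one of {OVERLAP_TYPES}, got {self.type!r}")


@dataclass(frozen=True)
class Hit:
    """One annotated overlap event between a query and a subject region."""

    query_index: int
    subject_index: int
    chrom: str
    ov_start: int
    ov_end: int
    ov_width: int
    frac_query: float
    frac_subject: float


@dataclass
class HitTable:
    """All hits of one query set against one subject set.

    Rows are sorted by ``(query_index, subject_index)`` and each pair occurs
    at most once, so outputs are byte-stable. ``df`` is the tabular form
    (columns :data:`HIT_COLUMNS`); :attr:`hits` materializes :class:`Hit`
    records on demand.
    """

    params: OverlapParams
    query_name: str
    subject_name: str
    df: pd.DataFrame = field(default_factory=lambda: _empty_hit_frame())

    @property
    def hits(self) -> List[Hit]:
        return [Hit(**rec) for rec in self.df.to_dict("records")]

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self.hits)


def _empty_hit_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in HIT_COLUMNS})
    return df.astype(
        {
            "query_index": np.int64,
            "subject_index": np.int64,
            "chrom": object,
            "ov_start": np.int64,
            "ov_end": np.int64,
            "ov_width": np.int64,
            "frac_query": float,
            "frac_subject": float,
        }
    )


def _strand_ok(q_code: np.ndarray, s_code: np.ndarray, ignore_strand: bool):
    """Strand compatibility mask; '*' (code 0) matches both strands."""
    if ignore_strand:
        return np.ones(np.broadcast(q_code, s_code).shape, dtype=bool)
    return (q_code == s_code) | (q_code == 0) | (s_code == 0)


def _build_table(
    query: RegionSet,
    subject: RegionSet,
    params: OverlapParams,
    qi: np.ndarray,
    si: np.ndarray,
) -> HitTable:
    """Annotate accepted (query, subject) index pairs into a HitTable."""
    order = np.lexsort((si, qi))
    qi, si = qi[order], si[order]
    qa, sa = query.arrays(), subject.arrays()
    qs, qe = qa["start"][qi], qa["end"][qi]
    ss, se = sa["start"][si], sa["end"][si]
    ov_start = np.maximum(qs, ss)
    ov_end = np.minimum(qe, se)
    ov_width = ov_end - ov_start + 1
    df = pd.DataFrame(
        {
            "query_index": qi,
            "subject_index": si,
            "chrom": qa["chrom"][qi],
            "ov_start": ov_start,
            "ov_end": ov_end,
            "ov_width": ov_width,
            "frac_query": ov_width / (qe - qs + 1),
            "frac_subject": ov_width / (se - ss + 1),
        }
    )
    if df.empty:
        df = _empty_hit_frame()
    return HitTable(
        params=params, query_name=query.name, subject_name=subject.name, df=df
    )


def _apply_rule(
    params: OverlapParams,
    qs: np.ndarray,
    qe: np.ndarray,
    qstr: np.ndarray,
    ss: np.ndarray,
    se: np.ndarray,
    sstr: np.ndarray,
) -> np.ndarray:
    """Boolean hit mask for aligned coordinate arrays on one chromosome."""
    width = np.minimum(qe, se) - np.maximum(qs, ss) + 1
    ok = width >= params.min_overlap
    if params.type == "within":
        ok &= (qs >= ss) & (qe <= se)
    elif params.type == "equal":
        ok &= (qs == ss) & (qe == se)
    ok &= _strand_ok(qstr, sstr, params.ignore_strand)
    return ok


def find_overlaps(
    query: RegionSet, subject: RegionSet, params: OverlapParams | None = None
) -> HitTable:
    """All hits of ``query`` against ``subject`` under ``params``.

    Uses a per-chromosome interval index over the subject set, so the cost is
    O((n + m) log m + h) rather than all-pairs; the result is identical,
    field for field, to :func:`brute_force_overlaps`.
    """
    params = params or OverlapParams()
    qa, sa = query.arrays(), subject.arrays()

    trees: dict[str, IntervalTree] = {}
    for chrom in np.unique(sa["chrom"]) if len(subject) else []:
        idx = np.flatnonzero(sa["chrom"] == chrom)
        # interval index is half-open: closed [s, e] becomes [s, e + 1)
        trees[chrom] = IntervalTree.from_tuples(
            (sa["start"][j], sa["end"][j] + 1, j) for j in idx
        )

    q_hits: list[int] = []
    s_hits: list[int] = []
    for i in range(len(query)):
        tree = trees.get(qa["chrom"][i])
        if tree is None:
            continue
        for iv in tree.overlap(qa["start"][i], qa["end"][i] + 1):
            q_hits.append(i)
            s_hits.append(iv.data)
    qi = np.array(q_hits, dtype=np.int64)
    si = np.array(s_hits, dtype=np.int64)
    if len(qi):
        ok = _apply_rule(
            params,
            qa["start"][qi],
            qa["end"][qi],
            qa["strand"][qi],
            sa["start"][si],
            sa["end"][si],
            sa["strand"][si],
        )
        qi, si = qi[ok], si[ok]
    return _build_table(query, subject, params, qi, si)


def brute_force_overlaps(
    query: RegionSet, subject: RegionSet, params: OverlapParams | None = None
) -> HitTable:
    """Reference engine: evaluate every (query, subject) pair directly.

    Defines the hit semantics that :func:`find_overlaps` must reproduce;
    intended for small inputs and as the test oracle (numpy broadcasting, so
    memory is O(n * m)).
    """
    params = params or OverlapParams()
    qa, sa = query.arrays(), subject.arrays()
    n, m = len(query), len(subject)
    if n == 0 or m == 0:
        return _build_table(params=params, query=query, subject=subject,
                            qi=np.array([], dtype=np.int64),
                            si=np.array([], dtype=np.int64))
    same_chrom = qa["chrom"][:, None] == sa["chrom"][None, :]
    ok = _apply_rule(
        params,
        qa["start"][:, None],
        qa["end"][:, None],
        qa["strand"][:, None],
        sa["start"][None, :],
        sa["end"][None, :],
        sa["strand"][None, :],
    )
    qi, si = np.nonzero(same_chrom & ok)
    return _build_table(query, subject, params, qi.astype(np.int64), si.astype(np.int64))


def annotate_hits(
    ht: HitTable, query: RegionSet, subject: RegionSet
) -> pd.DataFrame:
    """Join region names and full coordinates of both partners onto the hits.

    Produces the long-table schema consumed by
    :func:`regionoverlap.io.write_long_table`: one row per hit with query
    coordinates, subject coordinates, overlap coordinates, overlap width, and
    the overlapped fraction of each partner. Unnamed regions get generated
    ``query_<i>`` / ``subject_<j>`` identifiers.
    """
    df = ht.df
    if len(df):
        if df["query_index"].max() >= len(query) or df["subject_index"].max() >= len(
            subject
        ):
            raise IndexError("hit table indices out of range for the given sets")
    qi = df["query_index"].to_numpy(dtype=np.int64)
    si = df["subject_index"].to_numpy(dtype=np.int64)
    qa, sa = query.arrays(), subject.arrays()
    strand_of = {1: "+", -1: "-", 0: "*"}
    return pd.DataFrame(
        {
            "query_dataset": ht.query_name,
            "query_index": qi,
            "query_name": [query.region_label(i, "query") for i in qi],
            "chrom": df["chrom"].to_numpy(),
            "query_start": qa["start"][qi],
            "query_end": qa["end"][qi],
            "query_strand": [strand_of[c] for c in qa["strand"][qi]],
            "subject_dataset": ht.subject_name,
            "subject_index": si,
            "subject_name": [subject.region_label(j, "subject") for j in si],
            "subject_start": sa["start"][si],
            "subject_end": sa["end"][si],
            "subject_strand": [strand_of[c] for c in sa["strand"][si]],
            "ov_start": df["ov_start"].to_numpy(),
            "ov_end": df["ov_end"].to_numpy(),
            "ov_width": df["ov_width"].to_numpy(),
            "frac_query": df["frac_query"].to_numpy(),
            "frac_subject": df["frac_subject"].to_numpy(),
        }
    )
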