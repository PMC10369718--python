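"""Per-query overlap counts, dataset-level summary statistics, and histograms.

The headline questions these answer: how many query regions carry at least
one annotation element, how many elements per region (five-number summary
plus mean), and what the count distribution looks like.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import RegionSet, Workspace
from .overlap import HitTable


@dataclass(frozen=True)
class SummaryStats:
    """Summary of the per-query hit-count vector of one subject dataset."""

    n_query: int
    n_query_with_hit: int
    total_hits: int
    min: float
    lower_quartile: float
    mean: float
    median: float
    upper_quartile: float
    max: float


def count_overlaps_per_query(ht: HitTable, n_query: int) -> np.ndarray:
    """Number of hits per query region, zero-filled for hit-less queries."""
    qi = ht.df["query_index"].to_numpy(dtype=np.int64)
    if len(qi) and qi.max() >= n_query:
        raise IndexError("hit table contains query indices >= n_query")
    return np.bincount(qi, minlength=n_query).astype(np.int64)


def summary_stats(counts: Sequence[int]) -> SummaryStats:
    """Six summary statistics of a per-query count vector.

    Quartiles use linear interpolation between order statistics: at
    probability p, h = (n - 1) p + 1 and the value is
    x_floor(h) + (h - floor(h)) (x_(floor(h)+1) - x_floor(h)) on the sorted
    vector (numpy's default "linear" quantile).
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("counts must be non-empty")
    lq, med, uq = np.quantile(c, [0.25, 0.5, 0.75])
    return SummaryStats(
        n_query=int(c.size),
        n_query_with_hit=int((c > 0).sum()),
        total_hits=int(c.sum()),
        min=float(c.min()),
        lower_quartile=float(lq),
        mean=float(c.mean()),
        median=float(med),
        upper_quartile=float(uq),
        max=float(c.max()),
    )


def summarize_workspace(
    ws: Workspace, hit_tables: Sequence[HitTable]
) -> pd.DataFrame:
    """One summary row per subject dataset plus an "overall" row.

    The overall row aggregates across all subject datasets: how many query
    regions carry at least one element of ANY kind, and the mean total
    number of elements per query; its six statistics are computed over the
    summed per-query counts.
    """
    if not hit_tables:
        raise ValueError("no subject hit tables to summarize")
    n_query = len(ws.query)
    rows = []
    total = np.zeros(n_query, dtype=np.int64)
    for ht in hit_tables:
        counts = count_overlaps_per_query(ht, n_query)
        total += counts
        rows.append({"dataset": ht.subject_name, **asdict(summary_stats(counts))})
    rows.append({"dataset": "overall", **asdict(summary_stats(total))})
    return pd.DataFrame(rows)


def subjects_for_query(
    ht: HitTable, query_index: int, subject: RegionSet
) -> pd.DataFrame:
    """Drill-down: all subject regions overlapping one query region.

    Rows come in subject-index order with the overlap coordinates attached.
    """
    sub = ht.df[ht.df["query_index"] == query_index].sort_values("subject_index")
    si = sub["subject_index"].to_numpy(dtype=np.int64)
    return pd.DataFrame(
        {
            "subject_index": si,
            "subject_name": [subject.region_label(j, "subject") for j in si],
            "chrom": [subject[j].chrom for j in si],
            "subject_start": [subject[j].start for j in si],
            "subject_end": [subject[j].end for j in si],
            "subject_strand": [subject[j].strand for j in si],
            "ov_start": sub["ov_start"].to_numpy(dtype=np.int64),
            "ov_end": sub["ov_end"].to_numpy(dtype=np.int64),
            "ov_width": sub["ov_width"].to_numpy(dtype=np.int64),
        }
    )


def histogram_bins(
    counts: Sequence[int], edges: Optional[Sequence[float]] = None
) -> tuple[pd.DataFrame, float]:
    """Group per-query overlap counts into bins.

    Default edges give one bin per integer 0..max(counts) when the maximum
    is <= 50, else 30 equal-width bins. With custom ``edges``, numpy
    histogram semantics apply: bins are half-open except the last, which is
    closed, and values outside the range are dropped. Returns the histogram
    table (bin_label, frequency) and the median of the counts, the marker
    drawn by :func:`regionoverlap.viz.plot_histogram`.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("counts must be non-empty")
    if edges is None:
        cmax = int(c.max())
        if cmax <= 50:
            freq = np.bincount(c.astype(np.int64), minlength=cmax + 1)
            df = pd.DataFrame(
                {"bin_label": [str(i) for i in range(cmax + 1)], "frequency": freq}
            )
            return df, float(np.median(c))
        edges = np.linspace(0, cmax, 31)
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    freq, _ = np.histogram(c, bins=edges)
    labels = [f"[{edges[i]:g}, {edges[i + 1]:g})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:g}, {edges[-1]:g}]")
    df = pd.DataFrame({"bin_label": labels, "frequency": freq})
    return df, float(np.median(c))
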