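"""Static visual outputs: summary bars, count histograms, local track plots,
and UCSC browser links.

All plots are written straight to file (PNG by default, PDF via the file
extension) with the non-interactive Agg backend; identical inputs give
identical figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.colors import is_color_like
from matplotlib.patches import FancyArrow, Rectangle
import numpy as np
import pandas as pd

from .core import GenomicRegion, RegionSet, Workspace

#: stable default palette, assigned by dataset order
PALETTE = ("#4C72B0", "#DD8452", "#55A868", "#C44E52", "#8172B3",
           "#937860", "#DA8BC3", "#8C8C8C", "#CCB974", "#64B5CD")


@dataclass(frozen=True)
class TrackStyle:
    """Appearance of one dataset track in the local genomic view."""

    color: str = PALETTE[0]
    label_mode: str = "name"  # "name" | "none"
    shape: str = "box"  # "box" | "arrow"
    height: float = 0.6

    def __post_init__(self) -> None:
        if not is_color_like(self.color):
            raise ValueError(f"not a valid color: {self.color!r}")
        if self.label_mode not in ("name", "none"):
            raise ValueError("label_mode must be 'name' or 'none'")
        if self.shape not in ("box", "arrow"):
            raise ValueError("shape must be 'box' or 'arrow'")


def plot_summary_bars(summary: pd.DataFrame, path: str | Path) -> None:
    """Grouped bar chart of the per-dataset summary table.

    One group per subject dataset: number of queries, queries with >= 1
    hit, total hits, and mean hits per query.
    """
    if summary is None or len(summary) == 0:
        raise ValueError("summary table is empty")
    fig, ax = plt.subplots(figsize=(1.8 + 1.6 * len(summary), 4.0))
    metrics = ["n_query", "n_query_with_hit", "total_hits", "mean"]
    labels = ["queries", "queries with hit", "total hits", "mean hits/query"]
    x = np.arange(len(summary))
    w = 0.2
    for k, (metric, label) in enumerate(zip(metrics, labels)):
        ax.bar(x + (k - 1.5) * w, summary[metric], width=w,
               color=PALETTE[k % len(PALETTE)], label=label)
    ax.set_xticks(x)
    ax.set_xticklabels(summary["dataset"], rotation=20, ha="right")
    ax.set_ylabel("count")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_histogram(
    hist: pd.DataFrame, median_value: float, path: str | Path
) -> None:
    """Bar chart of the overlap-count distribution with a dashed median line."""
    if hist is None or len(hist) == 0:
        raise ValueError("histogram table is empty")
    fig, ax = plt.subplots(figsize=(6.0, 4.0))
    x = np.arange(len(hist))
    ax.bar(x, hist["frequency"], color=PALETTE[0])
    ax.set_xticks(x)
    ax.set_xticklabels(hist["bin_label"], rotation=45 if len(hist) > 15 else 0,
                       fontsize=8)
    # map the median (in count units) onto the bar axis when bins are integers
    labels = list(hist["bin_label"])
    if all(l.lstrip("-").isdigit() for l in labels):
        pos = median_value - float(labels[0])
    else:
        pos = len(hist) / 2.0
    ax.axvline(pos, color="black", linestyle="--", label=f"median = {median_value:g}")
    ax.set_xlabel("overlaps per region")
    ax.set_ylabel("frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _draw_region(ax, r: GenomicRegion, y: float, style: TrackStyle) -> None:
    if style.shape == "arrow" and r.strand in ("+", "-"):
        width = r.end - r.start + 1
        head = min(0.25 * width, width)
        if r.strand == "+":
            ax.add_patch(FancyArrow(
                r.start, y, width, 0, width=style.height * 0.5,
                head_width=style.height, head_length=head,
                length_includes_head=True, color=style.color))
        else:
            ax.add_patch(FancyArrow(
                r.end, y, -width, 0, width=style.height * 0.5,
                head_width=style.height, head_length=head,
                length_includes_head=True, color=style.color))
    else:
        ax.add_patch(Rectangle(
            (r.start, y - style.height / 2), r.end - r.start + 1, style.height,
            color=style.color))
    if style.label_mode == "name" and r.name:
        ax.annotate(r.name, ((r.start + r.end) / 2, y + style.height * 0.75),
                    ha="center", fontsize=7)


def plot_region_tracks(
    ws: Workspace,
    query_index: int,
    path: str | Path,
    window: Optional[GenomicRegion] = None,
    styles: Optional[dict[str, TrackStyle]] = None,
    extra_datasets: Optional[Sequence[str]] = None,
) -> None:
    """Local genomic view: one track per dataset within a genome window.

    The window defaults to the chosen query region plus 10% flanks on each
    side. Strand is drawn as an arrowhead where known. Datasets that were
    not part of the overlap run can be layered in via ``extra_datasets``.
    """
    query = ws.query
    if not (0 <= query_index < len(query)):
        raise IndexError(f"query_index {query_index} out of range")
    focus = query[query_index]
    if window is None:
        flank = max(1, focus.width // 10)
        window = GenomicRegion(focus.chrom, max(1, focus.start - flank),
                               focus.end + flank)
    if window.chrom != focus.chrom:
        raise ValueError(
            f"window chromosome {window.chrom!r} differs from query "
            f"{focus.chrom!r}"
        )
    track_names = [ws.query_name] + list(ws.subject_names) + list(extra_datasets or [])
    styles = styles or {}
    fig, ax = plt.subplots(figsize=(8.0, 1.0 + 0.7 * len(track_names)))
    for row, ds_name in enumerate(track_names):
        rs = ws.datasets[ds_name]
        style = styles.get(ds_name) or TrackStyle(
            color=PALETTE[row % len(PALETTE)],
            shape="arrow" if any(r.strand != "*" for r in rs) else "box",
        )
        y = len(track_names) - row
        for r in rs:
            if r.chrom == window.chrom and r.start <= window.end and r.end >= window.start:
                _draw_region(ax, r, y, style)
        ax.annotate(ds_name, (window.start, y + 0.32), fontsize=8,
                    fontweight="bold", annotation_clip=False)
    ax.set_xlim(window.start, window.end)
    ax.set_ylim(0.3, len(track_names) + 0.9)
    ax.set_yticks([])
    ax.set_xlabel(f"{window.chrom} position (bp)")
    ax.ticklabel_format(axis="x", style="plain")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def ucsc_url(r: GenomicRegion, genome: str) -> str:
    """UCSC genome-browser hgTracks URL for one region.

    The chromosome name is normalized to UCSC style ("1" -> "chr1") since
    hgTracks only accepts chr-prefixed names.
    """
    if not genome:
        raise ValueError("genome label must be non-empty (e.g. 'hg38')")
    from .io import normalize_chrom_names  # local import: avoid cycle

    chrom = normalize_chrom_names(
        RegionSet("_tmp", [r]), "ucsc"
    )[0].chrom
    return (
        "https://genome.ucsc.edu/cgi-bin/hgTracks"
        f"?db={genome}&position={chrom}%3A{r.start}-{r.end}"
    )
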