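"""Basic overlap run: genes vs TFBS / CpG-island / promoter annotations.

Builds the small built-in toy workspace (10 genes, 25 annotation regions),
finds every gene-annotation overlap under the default hit rule (any overlap
of >= 1 bp, strand ignored) and prints the per-dataset summary plus the
detailed rows for one gene.
"""

import pandas as pd

from regionoverlap import (
    annotate_hits,
    find_overlaps,
    make_toy_workspace,
    subjects_for_query,
    summarize_workspace,
)

ws = make_toy_workspace()
tables = [find_overlaps(ws.query, s) for s in ws.subjects()]

# one row per subject dataset, plus an "overall" row across all of them
summary = summarize_workspace(ws, tables)
print(summary.to_string(index=False))
# n_query_with_hit = genes carrying at least one element of that kind;
# mean = average number of elements per gene.

# drill down: everything overlapping gene g0
print("\nelements overlapping g0 (TFBS table):")
print(subjects_for_query(tables[0], 0, ws.datasets["tfbs"]).to_string(index=False))

# the long table: one annotated row per hit, for export
long_df = pd.concat(
    [annotate_hits(t, ws.query, ws.datasets[t.subject_name]) for t in tables],
    ignore_index=True,
)
print(f"\nlong table: {len(long_df)} hits, columns: {list(long_df.columns)[:8]}...")
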