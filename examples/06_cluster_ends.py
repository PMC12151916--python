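"""Cluster chromosome ends by telomere-associated features.

Every non-timing column is normalized to mean 1; replication timing is
mapped onto [-1, 1] (early -> -1, late -> +1). Agglomeration is Ward.D2 on
Manhattan distances with merge heights on the unsquared scale.
"""

import numpy as np
import pandas as pd

from telomir import build_end_table, cluster_ends
from telomir.endcluster import linkage_to_newick

rng = np.random.default_rng(0)
ends = [f"chr{i}_{side}" for i in range(1, 5) for side in "pq"]
raw = pd.DataFrame(
    {
        "we_count": rng.poisson(3, 8).astype(float),
        "deg_count": rng.poisson(2, 8).astype(float),
        "its_count": rng.poisson(1, 8).astype(float),
        "replication_timing": rng.uniform(10, 30, 8),
    },
    index=ends,
)
gene_counts = pd.Series(rng.integers(20, 60, 8).astype(float), index=ends)

table, meta = build_end_table(raw, gene_counts=gene_counts)
print("normalized feature table (non-timing column means are exactly 1):")
print(table.round(3).to_string())

Z, labels = cluster_ends(table, k=3)
print("\ncluster labels:")
print(labels.to_string())
print("\ndendrogram:", linkage_to_newick(Z, list(table.index)))
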