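"""Per-chromosome-end feature tables and Ward.D2/Manhattan clustering.

Chromosome ends are described by telomere-associated features — WE motif
occurrences, DEG counts, the DEG ratio corrected for gene density,
interstitial telomeric sequence content, replication timing and optional
protein ChIP signals. Every non-timing column is normalized to a mean of
exactly 1; the replication-timing column is affinely mapped so its minimum
is -1 (earliest replication) and its maximum +1 (latest).

Agglomeration follows the Ward.D2 rule on a supplied dissimilarity matrix:
the Lance-Williams update is applied to squared dissimilarities and merge
heights are reported on the unsquared scale. Pairing Ward with a Manhattan
metric is a formal application of that recurrence — Ward's variance
optimality argument only holds for squared Euclidean distances — but it is
the combination in routine use by mainstream statistical software, and it
is implemented verbatim here. Ties are broken deterministically by the
lowest row index.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd


def build_end_table(
    features: pd.DataFrame,
    gene_counts: pd.Series | None = None,
    deg_col: str = "deg_count",
    timing_col: str = "replication_timing",
) -> tuple[pd.DataFrame, dict]:
    """Normalized feature table for chromosome-end clustering.

    `features` has one row per chromosome end, numeric columns. When
    `gene_counts` is given and `deg_col` exists, a `deg_ratio` column
    (DEG count / gene count, 0 when an end has no genes) is added before
    normalization. Non-timing columns are divided by their mean (columns
    with mean 0 cannot be normalized and are dropped with a warning);
    the timing column is mapped so min -> -1 and max -> +1. Missing values
    are an error: absent data must be dropped as a column, not imputed.

    Returns (normalized table, metadata) where metadata records per-column
    normalization constants and any flags.
    """
    table = features.copy().astype(float)
    meta: dict = {"column_means": {}, "dropped": [], "flags": []}
    if table.isna().any().any():
        raise ValueError("missing values in feature table; drop the column instead")
    if gene_counts is not None and deg_col in table.columns:
        gc = gene_counts.reindex(table.index).astype(float)
        if gc.isna().any():
            raise ValueError("gene_counts missing for some ends")
        ratio = np.where(gc > 0, table[deg_col] / gc.replace(0, np.nan), 0.0)
        if (gc == 0).any():
            meta["flags"].append("deg_ratio_zero_gene_ends")
        table["deg_ratio"] = np.nan_to_num(ratio)
    for col in list(table.columns):
        if col == timing_col:
            lo, hi = table[col].min(), table[col].max()
            if hi == lo:
                table[col] = 0.0
                meta["flags"].append(f"{col}_constant")
            else:
                table[col] = 2 * (table[col] - lo) / (hi - lo) - 1
            meta["column_means"][col] = ("affine", float(lo), float(hi))
            continue
        mean = table[col].mean()
        if mean == 0:
            warnings.warn(f"column {col!r} has mean 0; dropped", stacklevel=2)
            table = table.drop(columns=[col])
            meta["dropped"].append(col)
            continue
        table[col] = table[col] / mean
        meta["column_means"][col] = ("mean", float(mean))
    return table, meta


def manhattan_distances(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)


def ward_d2_linkage(dissimilarity: np.ndarray) -> np.ndarray:
    """Ward.D2 agglomeration of a square dissimilarity matrix.

    The Lance-Williams recurrence
        D2(k, i+j) = [(n_i+n_k) D2(k,i) + (n_j+n_k) D2(k,j) - n_k D2(i,j)]
                     / (n_i + n_j + n_k)
    is applied to squared dissimilarities; reported merge heights are the
    square roots. Returns a linkage matrix in the standard
    (left, right, height, size) encoding with original observations
    numbered 0..n-1 and merged clusters n, n+1, ... in merge order. Ties
    are resolved by the smallest pair of cluster indices.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be symmetric")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    S = D.astype(float) ** 2
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    # index of each active cluster's row in S
    row_of = {i: i for i in range(n)}
    S = S.copy()
    np.fill_diagonal(S, np.inf)
    Z = np.zeros((n - 1, 4))
    ids = list(range(n))
    next_id = n
    for step in range(n - 1):
        # find minimal squared dissimilarity among active clusters,
        # ties to lowest (i, j)
        best = (np.inf, None, None)
        act = sorted(active)
        for ai in range(len(act)):
            for aj in range(ai + 1, len(act)):
                i, j = act[ai], act[aj]
                v = S[row_of[i], row_of[j]]
                if best[1] is None or v < best[0] - 1e-12 * max(1.0, abs(best[0])):
                    best = (v, i, j)
        _, ci, cj = best
        ni, nj = active[ci], active[cj]
        height = float(np.sqrt(S[row_of[ci], row_of[cj]]))
        Z[step] = [ci, cj, height, ni + nj]
        ri, rj = row_of[ci], row_of[cj]
        sij = S[ri, rj]
        for k in act:
            if k in (ci, cj):
                continue
            rk = row_of[k]
            nk = active[k]
            new = ((ni + nk) * S[rk, ri] + (nj + nk) * S[rk, rj] - nk * sij) / (
                ni + nj + nk
            )
            S[ri, rk] = S[rk, ri] = new
        # the merged cluster reuses row ri; retire row rj
        S[rj, :] = np.inf
        S[:, rj] = np.inf
        del active[ci], active[cj], row_of[ci], row_of[cj]
        active[next_id] = ni + nj
        row_of[next_id] = ri
        next_id += 1
    return Z


def cut_tree(Z: np.ndarray, k: int | None = None, height: float | None = None) -> np.ndarray:
    """Flat cluster labels (1..k) from a linkage matrix."""
    from scipy.cluster import hierarchy

    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    n = Z.shape[0] + 1
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        return hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return hierarchy.fcluster(Z, t=height, criterion="distance")


def cluster_ends(
    table: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
    metric: str = "manhattan",
    linkage: str = "ward_d2",
) -> tuple[np.ndarray, pd.Series]:
    """Cluster chromosome ends; returns (linkage matrix, labels by end)."""
    if metric != "manhattan":
        raise ValueError("only the manhattan metric is supported")
    if linkage != "ward_d2":
        raise ValueError("only ward_d2 linkage is supported")
    if table.shape[0] < 2:
        raise ValueError("need at least two chromosome ends")
    D = manhattan_distances(table.to_numpy(dtype=float))
    Z = ward_d2_linkage(D)
    labels = cut_tree(Z, k=k, height=height)
    return Z, pd.Series(labels, index=table.index, name="cluster")


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a linkage matrix as a Newick tree with merge-height branch lengths."""
    n = Z.shape[0] + 1
    nodes: dict[int, tuple[str, float]] = {
        i: (str(leaf_names[i]), 0.0) for i in range(n)
    }
    for step in range(n - 1):
        left, right, h, _ = Z[step]
        ln, lh = nodes.pop(int(left))
        rn, rh = nodes.pop(int(right))
        bl_l = max(0.0, h - lh) / 2
        bl_r = max(0.0, h - rh) / 2
        nodes[n + step] = (f"({ln}:{bl_l:.6g},{rn}:{bl_r:.6g})", h)
    (tree, _), = nodes.values()
    return tree + ";"
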