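"""Network and heatmap reporting utilities.

Betweenness centrality sizes nodes in the thresholded similarity network;
group-mean aggregation emits per-feature means over chunks of at least
``min_group`` patients, mirroring the privacy constraint of federated
cohort databases where individual-level values may never leave the server.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .containers import OmicsBlock

__all__ = ["betweenness_centrality", "group_mean_aggregate", "heatmap_feature_order"]


def betweenness_centrality(A: np.ndarray) -> np.ndarray:
    """Unnormalized shortest-path betweenness of a binary undirected graph."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    G = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(A.shape[0])])


def _chunk_sizes(n: int, min_group: int) -> list[int]:
    """Consecutive chunks of >= min_group patients; the remainder is
    absorbed into the final chunk so no chunk is ever undersized."""
    n_chunks = n // min_group
    if n_chunks == 0:
        raise ValueError(f"group of {n} patients is smaller than min_group={min_group}")
    sizes = [min_group] * (n_chunks - 1)
    sizes.append(n - min_group * (n_chunks - 1))
    return sizes


def group_mean_aggregate(
    block: OmicsBlock, labels, min_group: int = 5
) -> pd.DataFrame:
    """Per-feature means over canonical-order patient chunks of >= min_group.

    Within each cluster, patients (in block order) are split into
    consecutive chunks of at least ``min_group``; every emitted statistic
    therefore aggregates at least ``min_group`` individuals.  Returns a
    long table with cluster, chunk index, chunk size and feature means.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != block.n_patients:
        raise ValueError("labels must align with the block's patients")
    rows = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sizes = _chunk_sizes(idx.size, min_group)
        start = 0
        for chunk_no, size in enumerate(sizes, start=1):
            members = idx[start : start + size]
            start += size
            means = block.values[members].mean(axis=0)
            row = {"cluster": int(lab), "chunk": chunk_no, "n_patients": size}
            row.update(dict(zip(block.feature_ids, means)))
            rows.append(row)
    return pd.DataFrame(rows)


def heatmap_feature_order(group_means: pd.DataFrame) -> list[str]:
    """Feature display order for heatmaps: hierarchical clustering
    (Euclidean, average linkage) of row-z-scored per-chunk means."""
    feats = [c for c in group_means.columns if c not in ("cluster", "chunk", "n_patients")]
    M = group_means[feats].to_numpy(dtype=float).T  # features x chunks
    sd = M.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = (M - M.mean(axis=1, keepdims=True)) / sd[:, None]
    if len(feats) < 3:
        return feats
    order = leaves_list(average(pdist(Z)))
    return [feats[i] for i in order]
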