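"""Spectral clustering of the fused network and silhouette-based model choice.

The spectral variant is Ng-Jordan-Weiss: symmetric normalized Laplacian,
embedding into the k smallest-eigenvalue eigenvectors, row normalization,
then k-means with a fixed seed and 50 restarts so results are deterministic
given (W, k, seed).  Silhouette widths are computed from the similarity
matrix itself after converting it to a dissimilarity with
``d_ij = max(W) - W_ij``; the mean width over candidate k picks the number
of subgroups, with ties broken toward smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .snf import FusedNetwork

__all__ = [
    "ClusterAssignment",
    "spectral_clusters",
    "silhouette_from_similarity",
    "select_k",
    "orient_two_clusters",
]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-patient labels in 1..k
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    seed: int = 0
    patient_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(self.labels)
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}; saw {sorted(present)}")


def _as_matrix(W) -> np.ndarray:
    if isinstance(W, FusedNetwork):
        return W.W_fused
    return np.asarray(W, dtype=float)


def spectral_clusters(W, k: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering into k groups; labels in 1..k.

    Cluster labels are renumbered by first occurrence in patient order, so
    the output is a pure function of (W, k, seed).
    """
    A = _as_matrix(W)
    if k < 2:
        raise ValueError("k must be >= 2")
    n = A.shape[0]
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("zero-degree patient in similarity graph")
    n_comp, _ = connected_components((A > 0).astype(int), directed=False)
    if n_comp > k:
        raise ValueError(
            f"similarity graph has {n_comp} connected components > k={k}; "
            "inspect the input network"
        )
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    U = vecs / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(U)
    raw = km.labels_
    # stable relabelling: cluster of the first patient becomes 1, etc.
    mapping: dict[int, int] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[lab] for lab in raw], dtype=int)


def silhouette_from_similarity(W, labels) -> tuple[np.ndarray, float]:
    """Silhouette widths computed directly from a similarity matrix.

    Similarity is converted to dissimilarity by ``max(W) - W`` with the
    diagonal forced to zero.  Members of singleton clusters get width 0.
    Returns (per-patient widths, mean width).
    """
    A = _as_matrix(W)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = A.max() - A
    np.fill_diagonal(D, 0.0)
    n = A.shape[0]
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def orient_two_clusters(labels, reference) -> np.ndarray:
    """Fix the arbitrary numbering of a two-cluster labelling.

    The cluster whose members have the higher mean ``reference`` value
    (e.g. overall standardized feature level) becomes subgroup 1 — the
    "elevated" phenotype convention — so downstream effect directions such
    as hazard ratios are comparable across runs.
    """
    labels = np.asarray(labels, dtype=int)
    reference = np.asarray(reference, dtype=float)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("orientation is defined for exactly two clusters")
    means = {c: reference[labels == c].mean() for c in uniq}
    high = max(means, key=means.get)
    return np.where(labels == high, 1, 2)


def select_k(
    W, k_min: int = 2, k_max: int = 10, seed: int = 0
) -> ClusterAssignment:
    """Choose the cluster count maximizing mean silhouette width.

    Runs spectral clustering for every k in [k_min, k_max] and scores each
    partition by mean silhouette width from the similarity matrix; ties go
    to the smaller k (parsimony).
    """
    A = _as_matrix(W)
    if k_max >= A.shape[0]:
        raise ValueError("k_max must be smaller than the number of patients")
    if k_min < 2 or k_min > k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    ids = W.patient_ids if isinstance(W, FusedNetwork) else list(range(A.shape[0]))
    sil: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        labels = spectral_clusters(A, k, seed=seed)
        _, mean_width = silhouette_from_similarity(A, labels)
        sil[k] = mean_width
        labelings[k] = labels
    best = max(sil, key=lambda k: (sil[k], -k))
    return ClusterAssignment(
        labels=labelings[best],
        k=best,
        silhouette_by_k=sil,
        seed=seed,
        patient_ids=list(ids),
    )
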