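"""Similarity network fusion: affinity kernels and cross-diffusion.

Per-modality patient similarity matrices are built from squared Euclidean
distances with the locally scaled exponential kernel

    W[i,j] = exp( -D[i,j] / (alpha * eps_ij) ),
    eps_ij = (m_i + m_j + D[i,j]) / 3,

where ``m_i`` is the mean distance from patient i to its K nearest
neighbours.  Fusion iterates the cross-diffusion update

    P_v  <-  S_v @ mean(P_u, u != v) @ S_v.T

for T rounds, where P_v is the full row-stochastic transition matrix of
view v and S_v its K-nearest-neighbour-masked local kernel.  The defaults
K=20, alpha=5, T=20 follow the analysis this package reimplements; note
that alpha=5 is unusually large for this kernel family (0.3-0.8 is typical
in the SNF literature) and is therefore exposed as a knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DistanceMatrix

__all__ = [
    "SNFParams",
    "AffinityMatrix",
    "FusedNetwork",
    "affinity_matrix",
    "full_transition",
    "local_kernel",
    "snf_fuse",
]

_EPS_FLOOR = 1e-12


@dataclass
class SNFParams:
    K: int = 20
    alpha: float = 5.0
    T: int = 20

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class AffinityMatrix:
    W: np.ndarray
    params: SNFParams
    modality: str = "omics"
    patient_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.all(np.isfinite(W)):
            raise ValueError("affinity matrix contains non-finite values")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("affinity matrix must be symmetric within 1e-10")
        if np.any(W < 0):
            raise ValueError("affinities must be nonnegative")
        self.W = W
        if not self.patient_ids:
            self.patient_ids = list(range(W.shape[0]))


@dataclass
class FusedNetwork:
    W_fused: np.ndarray
    params: SNFParams
    convergence: list[float] = field(default_factory=list)
    patient_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patient_ids:
            self.patient_ids = list(range(self.W_fused.shape[0]))

    @property
    def n(self) -> int:
        return self.W_fused.shape[0]


def _knn_mean_distance(D: np.ndarray, K: int) -> np.ndarray:
    """Mean distance from each point to its K nearest neighbours (self
    excluded); ties broken by stable index order."""
    n = D.shape[0]
    m = np.empty(n)
    for i in range(n):
        row = np.delete(D[i], i)
        idx = np.argsort(row, kind="stable")[:K]
        m[i] = row[idx].mean()
    return m


def affinity_matrix(D: DistanceMatrix, params: SNFParams) -> AffinityMatrix:
    """Locally scaled exponential kernel on a squared-distance matrix."""
    n = D.n
    if params.K >= n:
        raise ValueError(f"K={params.K} must be smaller than n_patients={n}")
    Dm = D.values
    m = _knn_mean_distance(Dm, params.K)
    eps = (m[:, None] + m[None, :] + Dm) / 3.0
    eps = np.maximum(eps, _EPS_FLOOR)
    W = np.exp(-Dm / (params.alpha * eps))
    W = (W + W.T) / 2.0
    return AffinityMatrix(W=W, params=params, patient_ids=D.patient_ids)


def full_transition(W: np.ndarray) -> np.ndarray:
    """Full row-stochastic transition matrix.

    Off-diagonal mass is halved so each row keeps probability 1/2 on the
    diagonal: P[i,j] = W[i,j] / (2 * sum_{k!=i} W[i,k]) for j != i and
    P[i,i] = 1/2.  This keeps the diffusion numerically stable.
    """
    W = np.asarray(W, dtype=float)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    if np.any(rowsum <= _EPS_FLOOR):
        raise ValueError("a row has zero off-diagonal similarity mass")
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """KNN-masked row-stochastic kernel carrying local structure.

    Each row keeps only the K most similar other patients (ties broken by
    stable index order) and is renormalized to sum to 1.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be smaller than n={n}")
    S = np.zeros_like(W)
    for i in range(n):
        sim = W[i].copy()
        sim[i] = -np.inf
        idx = np.argsort(-sim, kind="stable")[:K]
        mass = W[i, idx].sum()
        S[i, idx] = W[i, idx] / max(mass, _EPS_FLOOR)
    return S


def snf_fuse(affinities: list[AffinityMatrix], params: SNFParams | None = None) -> FusedNetwork:
    """Fuse per-modality affinity matrices by iterative cross-diffusion.

    After each diffusion step every view is renormalized to a
    row-stochastic transition matrix and symmetrized; the fused network is
    the view average with its diagonal set to the row maximum so that
    self-similarity stays maximal for downstream spectral clustering.
    """
    if len(affinities) < 2:
        raise ValueError(
            "fusion needs >=2 views; with a single view use its affinity directly"
        )
    params = params or affinities[0].params
    ids = affinities[0].patient_ids
    for a in affinities[1:]:
        if list(a.patient_ids) != list(ids):
            raise ValueError("affinity matrices have mismatched patient orderings")
    m = len(affinities)
    P = [full_transition(a.W) for a in affinities]
    S = [local_kernel(a.W, params.K) for a in affinities]

    trace: list[float] = []
    fused_prev = sum(P) / m
    for _ in range(params.T):
        P_next = []
        for v in range(m):
            others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            Q = S[v] @ others @ S[v].T
            # symmetrize, then renormalize so every view stays exactly
            # row-stochastic going into the next diffusion round
            Q = full_transition((Q + Q.T) / 2.0)
            P_next.append(Q)
        P = P_next
        fused = sum(P) / m
        trace.append(float(np.linalg.norm(fused - fused_prev)))
        fused_prev = fused

    W_fused = (fused_prev + fused_prev.T) / 2.0
    np.fill_diagonal(W_fused, 0.0)
    np.fill_diagonal(W_fused, W_fused.max(axis=1))
    return FusedNetwork(
        W_fused=W_fused, params=params, convergence=trace, patient_ids=list(ids)
    )
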