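"""Common Dimensions (ComDim / CCSWA) multiblock analysis.

ComDim extracts global patient scores shared across omics blocks together
with per-block saliences.  For each component the algorithm alternates
between (i) the dominant eigenvector t of the salience-weighted sum of
block cross-product matrices ``G = sum_b lambda_b X_b X_b'`` and (ii) the
salience update ``lambda_b = t' X_b X_b' t`` until the saliences settle,
then deflates every block by projecting out t.  A block whose features
vary strongly along t earns a high salience, so saliences quantify which
modality carries each common dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .containers import OmicsBlock

__all__ = ["ComDimResult", "comdim", "score_separation"]


@dataclass
class ComDimResult:
    global_scores: np.ndarray  # patients x n_components, orthonormal columns
    saliences: np.ndarray  # blocks x n_components, nonnegative
    block_loadings: list[np.ndarray]  # per block: features x n_components
    explained: np.ndarray  # per-component fraction of total block variance
    converged: list[bool] = field(default_factory=list)
    n_iterations: list[int] = field(default_factory=list)
    block_names: list[str] = field(default_factory=list)
    patient_ids: list = field(default_factory=list)


def _dominant_eigvec(G: np.ndarray) -> np.ndarray:
    n = G.shape[0]
    _, vec = eigh(G, subset_by_index=(n - 1, n - 1))
    t = vec[:, 0]
    # deterministic sign: largest-magnitude entry positive
    j = int(np.argmax(np.abs(t)))
    if t[j] < 0:
        t = -t
    return t / np.linalg.norm(t)


def comdim(
    blocks: list[OmicsBlock],
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 200,
    normalize_blocks: bool = False,
) -> ComDimResult:
    """CCSWA common components and saliences across omics blocks.

    Blocks must share one patient ordering and should arrive standardized.
    With ``normalize_blocks=True`` each block is first scaled to unit
    Frobenius norm so modalities of very different width contribute
    comparably (off by default).
    """
    if not blocks:
        raise ValueError("at least one block required")
    ids = blocks[0].patient_ids
    n = blocks[0].n_patients
    for b in blocks[1:]:
        if b.patient_ids != ids:
            raise ValueError("blocks have mismatched patient orderings")
    if n_components > n - 1:
        raise ValueError(f"n_components must be <= n_patients - 1 = {n - 1}")

    X = [b.values.copy() for b in blocks]
    if normalize_blocks:
        X = [x / np.linalg.norm(x) for x in X]
    total_var = sum(float(np.sum(x * x)) for x in X)
    m = len(X)

    scores = np.zeros((n, n_components))
    sal = np.zeros((m, n_components))
    loadings = [np.zeros((x.shape[1], n_components)) for x in X]
    explained = np.zeros(n_components)
    converged: list[bool] = []
    iters: list[int] = []

    for c in range(n_components):
        cross = [x @ x.T for x in X]
        lam = np.ones(m)
        ok = False
        it = 0
        t = None
        for it in range(1, max_iter + 1):
            G = sum(l * C for l, C in zip(lam, cross))
            t = _dominant_eigvec(G)
            lam_new = np.array([float(t @ C @ t) for C in cross])
            # tolerance is relative to the salience scale so convergence is
            # attainable for wide blocks where lambda is numerically large
            if np.max(np.abs(lam_new - lam)) < tol * max(1.0, np.max(np.abs(lam_new))):
                lam = lam_new
                ok = True
                break
            lam = lam_new
        scores[:, c] = t
        sal[:, c] = np.maximum(lam, 0.0)
        for b in range(m):
            loadings[b][:, c] = X[b].T @ t
        explained[c] = float(lam.sum()) / total_var if total_var > 0 else 0.0
        converged.append(ok)
        iters.append(it)
        proj = np.eye(n) - np.outer(t, t)
        X = [proj @ x for x in X]

    return ComDimResult(
        global_scores=scores,
        saliences=sal,
        block_loadings=loadings,
        explained=explained,
        converged=converged,
        n_iterations=iters,
        block_names=[b.modality for b in blocks],
        patient_ids=list(ids),
    )


def score_separation(result: ComDimResult, labels) -> np.ndarray:
    """Cohen's d of global scores between two subgroups, per component.

    Uses the pooled-SD standardized mean difference (group 1 minus the
    other), so the sign flips under a label swap.  The component with the
    largest |d| is the one best separating the subgroups.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("labels must be binary")
    g1 = result.global_scores[labels == uniq[0]]
    g2 = result.global_scores[labels == uniq[1]]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each subgroup needs at least two patients")
    n1, n2 = g1.shape[0], g2.shape[0]
    pooled = np.sqrt(
        ((n1 - 1) * g1.var(axis=0, ddof=1) + (n2 - 1) * g2.var(axis=0, ddof=1))
        / (n1 + n2 - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (g1.mean(axis=0) - g2.mean(axis=0)) / pooled
    return d
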