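"""Complete-case filtering, per-feature standardization and patient distances.

Clustering operates on patients that are complete in every omics block and
in the clinical covariates.  Each feature is centred to mean 0 and scaled to
unit standard deviation (sample SD, n-1 denominator), and pairwise patient
distances are SQUARED Euclidean distances — the convention expected by the
scaled-exponential affinity kernel downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .containers import DistanceMatrix, OmicsBlock

__all__ = ["complete_cases", "standardize", "pairwise_squared_distance"]

#: Clinical covariate columns that must be complete for a patient to be kept.
COVARIATE_COLUMNS = ("age", "sex", "bmi")


def complete_cases(
    blocks: list[OmicsBlock], clinical: pd.DataFrame
) -> tuple[list[OmicsBlock], pd.DataFrame]:
    """Restrict blocks and clinical table to jointly complete patients.

    Keeps the intersection of patients present in every block and the
    clinical table with no missing value in any block or in the covariate
    columns (age, sex, bmi).  All outputs share one canonical patient order
    (sorted IDs).
    """
    if len(blocks) < 2:
        raise ValueError("complete_cases requires at least two omics blocks")
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical

    keep = None
    for block in blocks:
        ok = block.data.index[block.data.notna().all(axis=1)]
        keep = set(ok) if keep is None else keep & set(ok)
    covs = [c for c in COVARIATE_COLUMNS if c in clin.columns]
    ok_clin = clin.index[clin[covs].notna().all(axis=1)] if covs else clin.index
    keep &= set(ok_clin)
    if not keep:
        raise ValueError("no patient is complete across all blocks and covariates")

    order = sorted(keep)
    out_blocks = [
        OmicsBlock(
            data=b.data.loc[order],
            modality=b.modality,
            feature_meta=b.feature_meta,
        )
        for b in blocks
    ]
    out_clin = clin.loc[order].reset_index().rename(columns={"index": "patient_id"})
    return out_blocks, out_clin


def standardize(block: OmicsBlock) -> OmicsBlock:
    """Centre each feature to mean 0 and scale to sample SD 1.

    Zero-variance features are a hard error: silently dropping a feature
    would change downstream distances irreproducibly, so the caller must
    remove such features explicitly.
    """
    X = block.values
    if not np.all(np.isfinite(X)):
        raise ValueError("block contains non-finite values; filter complete cases first")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [block.feature_ids[i] for i in zero[:5]]
        raise ValueError(f"zero-variance feature(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    return OmicsBlock(
        data=pd.DataFrame(Z, index=block.data.index, columns=block.data.columns),
        modality=block.modality,
        feature_meta=block.feature_meta,
    )


def pairwise_squared_distance(block: OmicsBlock) -> DistanceMatrix:
    """Squared Euclidean distance between every pair of patients."""
    X = block.values
    if not np.all(np.isfinite(X)):
        raise ValueError("block contains non-finite values")
    D = squareform(pdist(X, metric="sqeuclidean"))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(values=D, patient_ids=block.patient_ids)
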