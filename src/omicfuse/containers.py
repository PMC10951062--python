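"""Core data containers shared across the pipeline.

An :class:`OmicsBlock` wraps one modality's patient-by-feature matrix as a
pandas DataFrame indexed by patient ID.  A :class:`DistanceMatrix` holds the
squared-Euclidean patient-by-patient distances derived from one block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsBlock", "DistanceMatrix"]


@dataclass
class OmicsBlock:
    """One modality's patient x feature matrix.

    Parameters
    ----------
    data:
        DataFrame with patients in rows (index = patient IDs) and features in
        columns.  Values are real-valued measurements; for mass-spec style
        concentration data the convention throughout the package is to work
        on the log scale.
    modality:
        Free-text tag such as ``"lipidomics"`` or ``"proteomics"``.
    feature_meta:
        Optional per-feature metadata (e.g. lipid class), indexed by feature
        ID.
    """

    data: pd.DataFrame
    modality: str = "omics"
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            raise ValueError(f"duplicate patient_ids in block '{self.modality}'")
        if self.data.columns.has_duplicates:
            raise ValueError(f"duplicate feature_ids in block '{self.modality}'")

    @property
    def patient_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path, concentrations: bool = False) -> None:
        """Write the block as CSV with a patient_id key column.

        With ``concentrations=True`` values are exponentiated back to the
        positive concentration scale.
        """
        df = np.exp(self.data) if concentrations else self.data
        df.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path, modality: str = "omics") -> "OmicsBlock":
        df = pd.read_csv(path, index_col=0)
        return cls(data=df, modality=modality)


@dataclass
class DistanceMatrix:
    """Square matrix of squared Euclidean distances between patients."""

    values: np.ndarray
    patient_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(D)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric within 1e-10")
        if np.any(np.diag(D) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(D < 0):
            raise ValueError("distances must be nonnegative")
        self.values = D
        if not self.patient_ids:
            self.patient_ids = list(range(D.shape[0]))
        elif len(self.patient_ids) != D.shape[0]:
            raise ValueError("patient_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.patient_ids, columns=self.patient_ids
        ).to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(dtype=float), patient_ids=list(df.index))
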