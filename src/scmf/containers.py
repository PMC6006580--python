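"""Core data containers shared across the package.

Drugs index the rows and diseases the columns of the association matrix
throughout; every container carries its identifier lists so that files,
similarity matrices and factor matrices can be aligned by ID rather than
by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "BinaryFeatureTable",
    "as_array",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass
class AssociationMatrix:
    """Binary drug-disease association matrix.

    ``values[i, j] == 1`` records a known association between drug
    ``drug_ids[i]`` and disease ``disease_ids[j]``.
    """

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        if self.values.size == 0:
            raise ValueError("association matrix must be non-empty")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.drug_ids), list(self.disease_ids), self.values.copy()
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    entity_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} identifiers"
            )

    def validated(self, tol: float = 1e-8) -> "SimilarityMatrix":
        """Return a copy with symmetry enforced and negatives clipped.

        Asymmetry beyond ``tol`` and negative entries are repaired
        (symmetrize by averaging, clip to 0) with a warning rather than
        rejected, since externally supplied matrices are often written at
        limited precision.
        """
        v = self.values.copy()
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > tol:
            warnings.warn(
                f"similarity matrix asymmetric (max deviation {asym:.3g}); "
                "symmetrizing by averaging"
            )
        v = 0.5 * (v + v.T)
        if (v < 0).any():
            warnings.warn("negative similarity entries clipped to 0")
            v = np.clip(v, 0.0, None)
        return SimilarityMatrix(list(self.entity_ids), v)


@dataclass
class BinaryFeatureTable:
    """Presence/absence descriptor table (e.g. 881-bit substructure keys)."""

    entity_ids: list[str]
    descriptors: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        self.descriptors = _check_unique(self.descriptors, "descriptor")
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.shape != (len(self.entity_ids), len(self.descriptors)):
            raise ValueError(
                f"feature table shape {self.bits.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.descriptors)} descriptors"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("feature table entries must be 0 or 1")


def as_array(x) -> np.ndarray:
    """Extract the dense numeric payload from a container or pass arrays through."""
    if isinstance(x, (AssociationMatrix, SimilarityMatrix)):
        return x.values
    if isinstance(x, BinaryFeatureTable):
        return x.bits
    return np.asarray(x, dtype=float)
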