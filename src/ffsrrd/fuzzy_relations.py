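"""Fuzzy equivalence-relation matrices and fuzzy entropy.

Every feature induces an ``m × m`` relation matrix grading how similar each
pair of objects is on that feature. Continuous features use the exponential
similarity kernel ``e_ij = exp(-|x_i - x_j|)``; nominal features (and the
class) use the crisp 0/1 equality relation. Feature subsets combine their
relations with the element-wise minimum (the min t-norm realizes fuzzy
intersection). Row ``i`` of a relation matrix is the fuzzy equivalence class
of object ``i``; its cardinality is the row sum.

Logarithms are base 2 throughout, so entropies and mutual informations are
in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model import Dataset

__all__ = [
    "FuzzyRelationMatrix",
    "ClassPartition",
    "feature_relation",
    "class_relation",
    "subset_relation",
    "dataset_relations",
    "cardinalities",
    "fuzzy_entropy",
    "relation_to_tsv",
]


@dataclass(frozen=True)
class FuzzyRelationMatrix:
    """Symmetric, reflexive membership matrix for one source (feature/subset/class)."""

    M: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("relation matrix must be square")
        if not np.all(np.isfinite(M)):
            raise ValueError("relation matrix has non-finite entries")
        if M.min() < -1e-12 or M.max() > 1.0 + 1e-12:
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(M, M.T, atol=1e-12):
            raise ValueError("relation matrix must be symmetric")
        if not np.allclose(np.diag(M), 1.0, atol=1e-12):
            raise ValueError("relation matrix must be reflexive (unit diagonal)")

    @property
    def m(self) -> int:
        return self.M.shape[0]


@dataclass(frozen=True)
class ClassPartition:
    """Crisp indicator vectors for each class value (a partition of the objects)."""

    memberships: np.ndarray  # shape (l, m), rows are 0/1 indicators
    values: tuple

    def __post_init__(self) -> None:
        mu = np.asarray(self.memberships, dtype=float)
        object.__setattr__(self, "memberships", mu)
        if not np.all((mu == 0.0) | (mu == 1.0)):
            raise ValueError("class memberships must be crisp 0/1")
        if not np.allclose(mu.sum(axis=0), 1.0):
            raise ValueError("class indicators must partition the objects")

    @classmethod
    def from_labels(cls, y: np.ndarray) -> "ClassPartition":
        values = np.unique(y)
        mu = np.stack([(y == v).astype(float) for v in values])
        return cls(mu, tuple(values.tolist()))


def feature_relation(values: np.ndarray, kind: str = "continuous",
                     source: str = "") -> FuzzyRelationMatrix:
    """Relation matrix of one feature.

    Continuous: ``exp(-|x_i - x_j|)`` on the raw values. Nominal: 1 where the
    values are equal, 0 otherwise. Full precision is kept internally; any
    rounding is presentational only.
    """
    v = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("feature contains non-finite values")
    if kind == "continuous":
        M = np.exp(-np.abs(v[:, None] - v[None, :]))
    elif kind == "nominal":
        M = (v[:, None] == v[None, :]).astype(float)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return FuzzyRelationMatrix(M, source=source)


def class_relation(y: np.ndarray) -> FuzzyRelationMatrix:
    """Crisp equality relation of the class labels (always nominal)."""
    y = np.asarray(y)
    M = (y[:, None] == y[None, :]).astype(float)
    return FuzzyRelationMatrix(M, source="class")


def subset_relation(matrices: Sequence[FuzzyRelationMatrix]) -> FuzzyRelationMatrix:
    """Element-wise minimum over relation matrices (fuzzy intersection)."""
    if len(matrices) == 0:
        raise ValueError("need at least one relation matrix")
    sizes = {R.m for R in matrices}
    if len(sizes) != 1:
        raise ValueError("relation matrices disagree on object count")
    M = matrices[0].M
    for R in matrices[1:]:
        M = np.minimum(M, R.M)
    src = "&".join(R.source for R in matrices)
    return FuzzyRelationMatrix(M, source=src)


def dataset_relations(dataset: Dataset) -> list[FuzzyRelationMatrix]:
    """Per-feature relation matrices for a whole dataset (cached by callers)."""
    return [
        feature_relation(dataset.X[:, j], dataset.feature_kinds[j],
                         source=dataset.feature_names[j])
        for j in range(dataset.n)
    ]


def cardinalities(R: FuzzyRelationMatrix) -> np.ndarray:
    """Fuzzy cardinality of each equivalence class: the row sums."""
    return R.M.sum(axis=1)


def fuzzy_entropy(R: FuzzyRelationMatrix) -> float:
    """H = (1/m) sum_i log2(m / |[x_i]|), in bits.

    0 for a constant source (all-ones matrix), log2(m) when every object is
    fully distinct (identity matrix). Row sums are >= 1 since the diagonal
    is 1, so the log argument is always defined.
    """
    card = cardinalities(R)
    return float(np.mean(np.log2(R.m / card)))


def relation_to_tsv(R: FuzzyRelationMatrix, decimals: int = 2) -> str:
    """Render a relation matrix as TSV rounded for human diffing."""
    return "\n".join(
        "\t".join(f"{x:.{decimals}f}" for x in row) for row in R.M
    )
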