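"""Fuzzy-rough lower approximation, positive region and dependency degree.

The lower approximation of a crisp class set X under a fuzzy relation R uses
the Łukasiewicz implicator I(a, b) = min(1, 1 - a + b):

    mu_low[i] = min_j I(R[i, j], muX[j])

The positive region takes, per object, the supremum of the lower
approximations over all class sets; its mean over the m objects is the
dependency degree gamma in [0, 1]. The class partition is always crisp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import Dataset
from .fuzzy_relations import (
    ClassPartition,
    FuzzyRelationMatrix,
    dataset_relations,
    subset_relation,
)

__all__ = [
    "DependencyResult",
    "implicator",
    "lower_approximation",
    "positive_region",
    "dependency_degree",
]


@dataclass(frozen=True)
class DependencyResult:
    gamma: float
    pos: np.ndarray
    subset: tuple[int, ...]


def implicator(a: float, b: float) -> float:
    """Łukasiewicz implicator min(1, 1 - a + b), for memberships a, b in [0, 1]."""
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError("implicator arguments must lie in [0, 1]")
    return min(1.0, 1.0 - a + b)


def lower_approximation(Rsub: FuzzyRelationMatrix, muX: np.ndarray) -> np.ndarray:
    """Per-object lower-approximation membership of the crisp set muX."""
    muX = np.asarray(muX, dtype=float)
    if muX.shape != (Rsub.m,):
        raise ValueError("membership vector length must equal object count")
    if not np.all((muX == 0.0) | (muX == 1.0)):
        raise ValueError("class membership must be crisp 0/1")
    # min over j of min(1, 1 - e_ij + muX_j), vectorized row-wise
    vals = np.minimum(1.0, 1.0 - Rsub.M + muX[None, :])
    return vals.min(axis=1)


def positive_region(Rsub: FuzzyRelationMatrix, partition: ClassPartition) -> np.ndarray:
    """Per-object sup over classes of the lower approximation."""
    if partition.memberships.shape[0] == 0:
        raise ValueError("empty class partition")
    lows = np.stack([lower_approximation(Rsub, mu) for mu in partition.memberships])
    return lows.max(axis=0)


def dependency_degree(
    dataset: Dataset,
    subset: Sequence[int],
    relations: list[FuzzyRelationMatrix] | None = None,
) -> DependencyResult:
    """Dependency degree gamma of a feature subset with respect to the class.

    gamma = mean over objects of the positive-region membership under the
    min-combined relation of the subset. Normalized by the object count m.
    """
    subset = tuple(int(j) for j in subset)
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    if any(j < 0 or j >= dataset.n for j in subset):
        raise ValueError("feature index out of range")
    if relations is None:
        relations = dataset_relations(dataset)
    Rsub = subset_relation([relations[j] for j in subset])
    partition = ClassPartition.from_labels(dataset.y)
    pos = positive_region(Rsub, partition)
    return DependencyResult(float(pos.mean()), pos, subset)
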