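"""Fuzzy mutual information: relevancy (feature vs class) and redundancy (feature vs feature).

For relation matrices ``Ra`` and ``Rb`` over the same objects,

    I(a; b) = (1/m) * sum_i log2( m * |min(row_i(Ra), row_i(Rb))|
                                  / (|row_i(Ra)| * |row_i(Rb)|) )

where ``|.|`` is the fuzzy cardinality (row sum) and the intersection is the
element-wise minimum. The measure is symmetric, and I(a; a) collapses to the
fuzzy entropy H(a). Per-object log terms are summed as-is, without clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Dataset
from .fuzzy_relations import (
    FuzzyRelationMatrix,
    class_relation,
    dataset_relations,
)

__all__ = ["MIResult", "fuzzy_mutual_information", "mutual_information_value",
           "relevancy_vector", "redundancy_matrix"]


@dataclass(frozen=True)
class MIResult:
    value: float  # bits
    pair: tuple[str, str]


def mutual_information_value(Ra: FuzzyRelationMatrix, Rb: FuzzyRelationMatrix) -> float:
    if Ra.m != Rb.m:
        raise ValueError("relation matrices disagree on object count")
    a = Ra.M.sum(axis=1)
    b = Rb.M.sum(axis=1)
    ab = np.minimum(Ra.M, Rb.M).sum(axis=1)
    return float(np.mean(np.log2(Ra.m * ab / (a * b))))


def fuzzy_mutual_information(Ra: FuzzyRelationMatrix, Rb: FuzzyRelationMatrix) -> MIResult:
    return MIResult(mutual_information_value(Ra, Rb), (Ra.source, Rb.source))


def relevancy_vector(dataset: Dataset,
                     relations: list[FuzzyRelationMatrix] | None = None) -> np.ndarray:
    """I(f; C) for every feature f, reusing precomputed relation matrices if given."""
    dataset.require_classification()
    if relations is None:
        relations = dataset_relations(dataset)
    Rc = class_relation(dataset.y)
    return np.array([mutual_information_value(R, Rc) for R in relations])


def redundancy_matrix(dataset: Dataset,
                      relations: list[FuzzyRelationMatrix] | None = None) -> np.ndarray:
    """Symmetric n×n matrix of pairwise feature MI; diagonal holds entropies."""
    if relations is None:
        relations = dataset_relations(dataset)
    n = len(relations)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = mutual_information_value(relations[i], relations[j])
    return out
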