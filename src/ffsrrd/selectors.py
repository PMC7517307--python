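"""The three selection procedures and the ensemble driver.

* ``fwrfs_rank`` — greedy full ranking maximizing fuzzy relevancy I(f; C)
  while penalizing weighted fuzzy redundancy to already-ranked features.
* ``lfrfs_select`` — greedy forward subset search maximizing the fuzzy-rough
  dependency degree until no further gain.
* ``min_combine`` — rank aggregation giving each feature the best (minimum)
  position it achieves across the two component rankings.
* ``ffs_rrd`` — runs all three and truncates at the median-position threshold.

All procedures are deterministic; greedy ties are broken by lowest feature
index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data_model import Dataset
from .fuzzy_relations import class_relation, dataset_relations
from .information_measures import mutual_information_value
from .rough_measures import dependency_degree

__all__ = [
    "RankedFeatures",
    "SelectionResult",
    "fwrfs_rank",
    "lfrfs_select",
    "min_combine",
    "median_threshold",
    "ffs_rrd",
]

WeightingMode = Literal["wrfs", "uniform"]

# floating-point slack for "no further gamma gain" in the greedy subset search
DEFAULT_TOL = 1e-12


@dataclass(frozen=True)
class RankedFeatures:
    """An ordered sequence of feature indices with the score each earned."""

    order: tuple[int, ...]
    scores: tuple[float, ...]
    method: str

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranking contains duplicate feature indices")
        if len(self.scores) != len(self.order):
            raise ValueError("scores length must match order length")

    def position(self, feature: int) -> int:
        """1-based rank position of a feature (raises if absent)."""
        return self.order.index(feature) + 1

    def top(self, k: int) -> tuple[int, ...]:
        return self.order[:k]


@dataclass(frozen=True)
class SelectionResult:
    r1: RankedFeatures          # FWRFS full ranking
    r2: RankedFeatures          # L-FRFS dependency subset
    combined: RankedFeatures
    k: int
    selected: tuple[int, ...]


def _argmax_first(values: np.ndarray, candidates: Sequence[int]) -> int:
    """Index of the max among candidates; ties go to the lowest feature index."""
    best, best_val = candidates[0], values[candidates[0]]
    for j in candidates[1:]:
        if values[j] > best_val:
            best, best_val = j, values[j]
    return best


def fwrfs_rank(dataset: Dataset, weighting: WeightingMode = "wrfs") -> RankedFeatures:
    """Greedy relevancy/redundancy ranking of all features.

    First pick maximizes I(f; C). Each later pick maximizes

        J(f) = I(f; C) - (1/|S|) * sum_{s in S} w(f, s) * I(f; s)

    over unranked candidates, where S is the ranked set. In ``"wrfs"`` mode
    the weight w(f, s) = I(s; C) / (I(f; C) + I(s; C)) balances the selected
    and candidate relevancies; ``"uniform"`` uses w = 1 (mRMR-style penalty).
    All informations are fuzzy — continuous features are never discretized.
    """
    dataset.require_classification()
    if weighting not in ("wrfs", "uniform"):
        raise ValueError(f"unknown weighting mode {weighting!r}")
    relations = dataset_relations(dataset)
    Rc = class_relation(dataset.y)
    n = dataset.n
    relevancy = np.array([mutual_information_value(R, Rc) for R in relations])

    remaining = list(range(n))
    first = _argmax_first(relevancy, remaining)
    order = [first]
    scores = [float(relevancy[first])]
    remaining.remove(first)

    # pairwise MI computed lazily and cached: only ranked×candidate pairs needed
    mi_cache: dict[tuple[int, int], float] = {}

    def pair_mi(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in mi_cache:
            mi_cache[key] = mutual_information_value(relations[i], relations[j])
        return mi_cache[key]

    while remaining:
        crit = np.full(n, -np.inf)
        for f in remaining:
            penalty = 0.0
            for s in order:
                red = pair_mi(f, s)
                if weighting == "wrfs":
                    denom = relevancy[f] + relevancy[s]
                    w = relevancy[s] / denom if denom > 0 else 0.5
                else:
                    w = 1.0
                penalty += w * red
            crit[f] = relevancy[f] - penalty / len(order)
        pick = _argmax_first(crit, remaining)
        order.append(pick)
        scores.append(float(crit[pick]))
        remaining.remove(pick)
    return RankedFeatures(tuple(order), tuple(scores), "FWRFS")


def lfrfs_select(dataset: Dataset, tol: float = DEFAULT_TOL) -> RankedFeatures:
    """Greedy forward search for the feature subset maximizing dependency.

    Starting from the empty set (gamma = 0), each round adds the feature
    whose inclusion yields the highest gamma; the search stops when the best
    addition improves gamma by at most ``tol``, or gamma reaches the full-set
    dependency within ``tol``. Scores record the gamma after each addition,
    so the score sequence is non-decreasing.
    """
    dataset.require_classification()
    relations = dataset_relations(dataset)
    n = dataset.n
    gamma_full = dependency_degree(dataset, range(n), relations).gamma

    selected: list[int] = []
    scores: list[float] = []
    gamma_sel = 0.0
    remaining = list(range(n))
    while remaining:
        gains = np.full(n, -np.inf)
        for f in remaining:
            gains[f] = dependency_degree(dataset, selected + [f], relations).gamma
        pick = _argmax_first(gains, remaining)
        if gains[pick] <= gamma_sel + tol:
            break
        selected.append(pick)
        scores.append(float(gains[pick]))
        gamma_sel = float(gains[pick])
        remaining.remove(pick)
        if gamma_sel >= gamma_full - tol:
            break
    return RankedFeatures(tuple(selected), tuple(scores), "L-FRFS")


def min_combine(r1: RankedFeatures, r2: RankedFeatures, n: int) -> RankedFeatures:
    """Combine two rankings by the minimum position each feature achieves.

    ``r1`` must rank all ``n`` features; ``r2`` may be a prefix subset. A
    feature absent from ``r2`` falls back to ``n + pos_r1(f)`` there, so its
    combined score is its ``r1`` position. Ties in the combined score are
    broken by ``r1`` position, then by feature index.
    """
    if len(r1.order) != n:
        raise ValueError("r1 must rank every feature")
    if not set(r2.order) <= set(r1.order):
        raise ValueError("r2 contains features unknown to r1")
    pos1 = {f: i + 1 for i, f in enumerate(r1.order)}
    pos2 = {f: i + 1 for i, f in enumerate(r2.order)}
    scores = {f: min(pos1[f], pos2.get(f, n + pos1[f])) for f in r1.order}
    order = sorted(r1.order, key=lambda f: (scores[f], pos1[f], f))
    return RankedFeatures(
        tuple(order), tuple(float(scores[f]) for f in order), "combined"
    )


def median_threshold(n: int) -> int:
    """Median position of n ranked features: ceil(n/2)."""
    if n < 1:
        raise ValueError("need at least one feature")
    return math.ceil(n / 2)


def ffs_rrd(
    dataset: Dataset,
    k: int | None = None,
    weighting: WeightingMode = "wrfs",
    tol: float = DEFAULT_TOL,
) -> SelectionResult:
    """Full ensemble selection: FWRFS + L-FRFS, MIN-combined, truncated at k.

    ``k`` defaults to the median-position threshold ceil(n/2).
    Deterministic for a fixed dataset.
    """
    r1 = fwrfs_rank(dataset, weighting=weighting)
    r2 = lfrfs_select(dataset, tol=tol)
    combined = min_combine(r1, r2, dataset.n)
    if k is None:
        k = median_threshold(dataset.n)
    k = min(k, dataset.n)
    return SelectionResult(r1, r2, combined, k, combined.top(k))
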