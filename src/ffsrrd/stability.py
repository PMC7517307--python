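"""Noise-injection stability protocol and the Kuncheva stability measure.

A selector is stable if it returns nearly the same feature subset when the
data are perturbed. The protocol perturbs a random 10% of each continuous
feature's values with Normal(0, sigma_f) noise, reruns the selector, keeps
the top-r features, and scores agreement of the resulting subsets with the
chance-corrected Kuncheva index

    Kun(Ri, Rj) = (w*n - r^2) / (r * (n - r)),   w = |Ri ∩ Rj|,

which is 1 for identical subsets and has expectation 0 for random ones.
The aggregate stability is the mean index over all unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .data_model import Dataset
from .selectors import SelectionResult, ffs_rrd, median_threshold

__all__ = [
    "StabilityReport",
    "inject_noise",
    "kuncheva_index",
    "kuncheva_stability",
    "stability_experiment",
    "stability_profile",
]

# selector: Dataset -> ordered feature indices (full or prefix ranking)
Selector = Callable[[Dataset], Sequence[int]]

NoiseMode = Literal["cells", "scaled"]


@dataclass(frozen=True)
class StabilityReport:
    sequences: tuple[tuple[int, ...], ...]  # p subsets, each of size r
    n: int
    pairwise: np.ndarray                    # p×p Kuncheva indices, diag 1
    stability: float
    noise_fraction: float
    seed: int


def inject_noise(
    dataset: Dataset,
    fraction: float,
    seed: int,
    mode: NoiseMode = "cells",
) -> Dataset:
    """Return a noisy copy of the dataset; the original is untouched.

    ``mode="cells"`` (default): for each continuous feature, a uniformly
    random ``ceil(fraction * m)`` subset of its values is perturbed by a draw
    from Normal(0, sigma_f), where sigma_f is the feature's sample standard
    deviation. ``mode="scaled"``: every value of each continuous feature is
    perturbed by Normal(0, fraction * sigma_f). Nominal features and constant
    features (sigma_f = 0) are never changed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if mode not in ("cells", "scaled"):
        raise ValueError(f"unknown noise mode {mode!r}")
    rng = np.random.default_rng(seed)
    X = dataset.X.copy()
    m = dataset.m
    for j, kind in enumerate(dataset.feature_kinds):
        if kind != "continuous":
            continue
        sigma = float(X[:, j].std(ddof=1))
        if sigma == 0.0:
            continue
        if mode == "cells":
            k = ceil(fraction * m)
            rows = rng.choice(m, size=k, replace=False)
            X[rows, j] += rng.normal(0.0, sigma, size=k)
        else:
            X[:, j] += rng.normal(0.0, fraction * sigma, size=m)
    return Dataset(X, dataset.y, dataset.feature_names, dataset.feature_kinds)


def kuncheva_index(Ri: Iterable[int], Rj: Iterable[int], n: int) -> float:
    """Chance-corrected overlap of two equal-size feature subsets."""
    Si, Sj = set(Ri), set(Rj)
    r = len(Si)
    if len(Sj) != r:
        raise ValueError("subsets must have equal size")
    if r == 0 or r >= n:
        raise ValueError("subset size must satisfy 0 < r < n")
    w = len(Si & Sj)
    return (w * n - r * r) / (r * (n - r))


def kuncheva_stability(sequences: Sequence[Iterable[int]], n: int) -> float:
    """Mean Kuncheva index over all unordered pairs of subsets."""
    subsets = [set(s) for s in sequences]
    p = len(subsets)
    if p < 2:
        raise ValueError("need at least 2 sequences")
    total = 0.0
    for i in range(p - 1):
        for j in range(i + 1, p):
            total += kuncheva_index(subsets[i], subsets[j], n)
    return total * 2.0 / (p * (p - 1))


def _pairwise_matrix(subsets: Sequence[set], n: int) -> np.ndarray:
    p = len(subsets)
    M = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            M[i, j] = M[j, i] = kuncheva_index(subsets[i], subsets[j], n)
    return M


def _default_selector(dataset: Dataset) -> Sequence[int]:
    return ffs_rrd(dataset).combined.order


def stability_experiment(
    dataset: Dataset,
    selector: Selector | None = None,
    p: int = 10,
    fraction: float = 0.10,
    r: int | None = None,
    seed: int = 0,
    noise_mode: NoiseMode = "cells",
) -> StabilityReport:
    """Run the noise-perturbation stability protocol.

    ``p`` independent noise injections are drawn from child seeds of the
    master ``seed``; the selector runs on each noisy copy and its top-``r``
    features form one subset. Defaults: p=10 runs, 10% noise, r = median
    threshold ceil(n/2). ``fraction=0`` skips the injection entirely, so a
    deterministic selector scores exactly 1.
    """
    if p < 2:
        raise ValueError("need p >= 2 runs")
    if selector is None:
        selector = _default_selector
    n = dataset.n
    if r is None:
        r = median_threshold(n)
    if not 0 < r < n:
        raise ValueError("subset size must satisfy 0 < r < n")
    child_seeds = np.random.SeedSequence(seed).spawn(p)
    sequences: list[tuple[int, ...]] = []
    for cs in child_seeds:
        run_seed = int(cs.generate_state(1)[0] % (2**31))
        noisy = (
            dataset
            if fraction == 0.0
            else inject_noise(dataset, fraction, run_seed, mode=noise_mode)
        )
        order = list(selector(noisy))
        if len(order) < r:
            raise ValueError(
                f"selector returned {len(order)} features, need at least r={r}"
            )
        sequences.append(tuple(int(f) for f in order[:r]))
    subsets = [set(s) for s in sequences]
    pairwise = _pairwise_matrix(subsets, n)
    stability = kuncheva_stability(sequences, n)
    return StabilityReport(
        tuple(sequences), n, pairwise, float(stability), fraction, seed
    )


def stability_profile(
    dataset: Dataset,
    selector: Selector | None = None,
    p: int = 10,
    fraction: float = 0.10,
    seed: int = 0,
    noise_mode: NoiseMode = "cells",
) -> float:
    """Average stability across the first-half thresholds r = 1 .. ceil(n/2)."""
    vals = [
        stability_experiment(
            dataset, selector, p=p, fraction=fraction, r=r, seed=seed,
            noise_mode=noise_mode,
        ).stability
        for r in range(1, median_threshold(dataset.n) + 1)
    ]
    return float(np.mean(vals))
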