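"""Dataset container, CSV I/O, the worked-example fixture and a synthetic generator.

A :class:`Dataset` holds an ``m × n`` feature matrix, a length-``m`` label
vector and a per-feature kind flag (``"continuous"`` or ``"nominal"``).
Nominal features and the class are compared crisply (equal/not equal);
continuous features enter the fuzzy similarity kernel directly, without
discretization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

FeatureKind = Literal["continuous", "nominal"]

__all__ = [
    "Dataset",
    "SyntheticSpec",
    "load_dataset",
    "write_dataset",
    "table1_fixture",
    "generate_synthetic",
]


@dataclass(frozen=True)
class Dataset:
    """Tabular classification dataset.

    Attributes
    ----------
    X : ndarray of shape (m, n)
        Feature values. Nominal features are stored as integer codes.
    y : ndarray of shape (m,)
        Class labels; always treated as nominal regardless of encoding.
    feature_names : tuple of str
    feature_kinds : tuple of {"continuous", "nominal"}
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    feature_kinds: tuple[FeatureKind, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        m, n = X.shape
        if m < 2:
            raise ValueError(f"need at least 2 instances, got m={m}")
        if n < 1:
            raise ValueError("need at least one feature")
        if len(self.feature_names) != n or len(self.feature_kinds) != n:
            raise ValueError("feature_names/feature_kinds length must equal n")
        if y.shape != (m,):
            raise ValueError("y must be a length-m vector")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        for k in self.feature_kinds:
            if k not in ("continuous", "nominal"):
                raise ValueError(f"unknown feature kind {k!r}")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.y))

    def require_classification(self) -> None:
        """Raise unless at least two distinct class labels are present."""
        if self.n_classes < 2:
            raise ValueError("selection requires at least 2 distinct class labels")

    def scaled_minmax(self) -> "Dataset":
        """Return a copy with continuous features min-max scaled to [0, 1].

        Constant features map to 0. Nominal columns are untouched. Off by
        default everywhere: the similarity kernel is applied to raw values
        unless the caller opts in.
        """
        X = self.X.copy()
        for j, kind in enumerate(self.feature_kinds):
            if kind != "continuous":
                continue
            lo, hi = X[:, j].min(), X[:, j].max()
            X[:, j] = 0.0 if hi == lo else (X[:, j] - lo) / (hi - lo)
        return Dataset(X, self.y, self.feature_names, self.feature_kinds)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a dataset with planted informative/redundant/irrelevant features.

    ``effect_size`` is the separation of class-conditional means in SD units
    for informative features; ``redundancy_rho`` the correlation of each
    redundant copy to its informative parent.
    """

    m: int = 200
    n_informative: int = 2
    n_redundant: int = 1
    n_irrelevant: int = 3
    effect_size: float = 2.0
    redundancy_rho: float = 0.95
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if min(self.n_informative, self.n_redundant, self.n_irrelevant) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_redundant > 0 and self.n_informative < 1:
            raise ValueError("redundant features need an informative parent")
        if not 0.0 <= self.redundancy_rho <= 1.0:
            raise ValueError("redundancy_rho must lie in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def _infer_kind(series: pd.Series) -> FeatureKind:
    return "continuous" if pd.api.types.is_numeric_dtype(series) else "nominal"


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def load_dataset(
    path: str | Path,
    class_column: str = "last",
    kinds: Sequence[FeatureKind] | None = None,
    impute: bool = False,
) -> Dataset:
    """Load a delimited text file (header required) into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV/TSV file; the delimiter (comma, semicolon or tab) is autodetected.
    class_column
        Column name holding the class label, or ``"last"`` for the final column.
    kinds
        Optional per-feature override of the inferred continuous/nominal flags.
    impute
        If True, fill missing continuous values with the column median and
        missing nominal values with the column mode instead of rejecting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if df.shape[0] < 2:
        raise ValueError("dataset must contain at least 2 rows")
    label = df.columns[-1] if class_column == "last" else class_column
    if label not in df.columns:
        raise ValueError(f"class column {label!r} not found")
    y_raw = df[label]
    if y_raw.isna().any():
        raise ValueError("class column contains missing values")
    features = df.drop(columns=[label])
    if features.shape[1] < 1:
        raise ValueError("no feature columns besides the class")

    inferred = tuple(_infer_kind(features[c]) for c in features.columns)
    if kinds is not None:
        if len(kinds) != features.shape[1]:
            raise ValueError("kinds override length must equal feature count")
        inferred = tuple(kinds)  # type: ignore[assignment]

    if features.isna().any().any():
        if not impute:
            bad = [c for c in features.columns if features[c].isna().any()]
            raise ValueError(
                f"missing values in columns {bad}; pass impute=True to fill "
                "with median (continuous) / mode (nominal)"
            )
        for c, kind in zip(features.columns, inferred):
            fill = features[c].median() if kind == "continuous" else features[c].mode().iloc[0]
            features[c] = features[c].fillna(fill)

    X = np.empty(features.shape, dtype=float)
    for j, (c, kind) in enumerate(zip(features.columns, inferred)):
        col = features[c]
        X[:, j] = (
            col.to_numpy(dtype=float)
            if kind == "continuous"
            else pd.factorize(col)[0].astype(float)
        )
    y = pd.factorize(y_raw)[0] if not pd.api.types.is_numeric_dtype(y_raw) else y_raw.to_numpy()
    return Dataset(X, np.asarray(y), tuple(map(str, features.columns)), inferred)


def write_dataset(dataset: Dataset, path: str | Path, class_name: str = "class") -> None:
    """Write a Dataset back to CSV (features then class, header included)."""
    df = pd.DataFrame(dataset.X, columns=list(dataset.feature_names))
    df[class_name] = dataset.y
    df.to_csv(path, index=False)


def table1_fixture() -> Dataset:
    """The 5-object, 2-feature worked example with class labels (1,0,1,0,1)."""
    X = np.array(
        [[0.2, 0.1], [0.8, 0.5], [0.4, 0.3], [0.6, 0.4], [0.2, 0.1]]
    )
    y = np.array([1, 0, 1, 0, 1])
    return Dataset(X, y, ("f1", "f2"), ("continuous", "continuous"))


def generate_synthetic(spec: SyntheticSpec) -> tuple[Dataset, dict[str, list[int]]]:
    """Generate a dataset with known informative/redundant/irrelevant features.

    Informative features are class-conditional gaussians whose class means are
    ``effect_size`` standard deviations apart (classes spread evenly along one
    axis). Each redundant feature is ``rho * parent + sqrt(1 - rho^2) * noise``
    of an informative parent (round-robin). Irrelevant features are standard
    normal, independent of the class.

    Returns the dataset and ground-truth index sets keyed by
    ``"informative"``, ``"redundant"``, ``"irrelevant"``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.m
    y = rng.integers(0, spec.n_classes, size=m)
    # guarantee every class appears so the task is well-posed
    y[: spec.n_classes] = np.arange(spec.n_classes)

    cols: list[np.ndarray] = []
    informative = list(range(spec.n_informative))
    for _ in range(spec.n_informative):
        means = spec.effect_size * np.arange(spec.n_classes)
        cols.append(means[y] + rng.standard_normal(m))
    redundant = list(range(spec.n_informative, spec.n_informative + spec.n_redundant))
    for j in range(spec.n_redundant):
        parent = cols[j % spec.n_informative]
        rho = spec.redundancy_rho
        z = (parent - parent.mean()) / parent.std()
        noise = rng.standard_normal(m)
        cols.append(rho * z + np.sqrt(1.0 - rho**2) * noise)
    first_irr = spec.n_informative + spec.n_redundant
    irrelevant = list(range(first_irr, first_irr + spec.n_irrelevant))
    for _ in range(spec.n_irrelevant):
        cols.append(rng.standard_normal(m))

    n = len(cols)
    if n == 0:
        raise ValueError("spec generates no features")
    X = np.column_stack(cols)
    names = tuple(
        [f"inf{j}" for j in range(spec.n_informative)]
        + [f"red{j}" for j in range(spec.n_redundant)]
        + [f"irr{j}" for j in range(spec.n_irrelevant)]
    )
    dataset = Dataset(X, y, names, ("continuous",) * n)
    truth = {"informative": informative, "redundant": redundant, "irrelevant": irrelevant}
    return dataset, truth
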