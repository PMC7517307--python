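import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from ffsrrd import Dataset, class_relation, feature_relation, table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_relations(table1):
    """(R_f1, R_f2, R_C) for the worked example."""
    R1 = feature_relation(table1.X[:, 0], "continuous", source="f1")
    R2 = feature_relation(table1.X[:, 1], "continuous", source="f2")
    Rc = class_relation(table1.y)
    return R1, R2, Rc


def random_dataset(rng, m, n, n_classes=2):
    """Small random continuous dataset with every class present."""
    X = rng.standard_normal((m, n))
    y = rng.integers(0, n_classes, size=m)
    y[:n_classes] = np.arange(n_classes)
    return Dataset(
        X, y, tuple(f"f{j}" for j in range(n)), ("continuous",) * n
    )
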