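"""Walk through every measure on the built-in 5-object, 2-feature dataset.

Prints the fuzzy relation matrices, entropies, mutual informations, the
positive region and the dependency degree. The numbers show how a feature's
fuzzy similarity structure translates into relevancy (shared information
with the class) and dependency (how certainly objects can be classified).
"""

import numpy as np

from ffsrrd import (
    ClassPartition,
    class_relation,
    dependency_degree,
    feature_relation,
    fuzzy_entropy,
    mutual_information_value,
    positive_region,
    table1_fixture,
)

ds = table1_fixture()
R1 = feature_relation(ds.X[:, 0], "continuous", source="f1")
R2 = feature_relation(ds.X[:, 1], "continuous", source="f2")
Rc = class_relation(ds.y)

print("Relation matrix of f1 (exp(-|xi - xj|)), 2 dp:")
print(np.round(R1.M, 2))
print("\nCrisp class relation:")
print(Rc.M.astype(int))

print(f"\nH(f1)    = {fuzzy_entropy(R1):.2f} bits   (how distinct objects are on f1)")
print(f"H(C)     = {fuzzy_entropy(Rc):.2f} bits   (class label entropy)")
print(f"I(f1;C)  = {mutual_information_value(R1, Rc):.2f} bits   (relevancy of f1)")
print(f"I(f2;C)  = {mutual_information_value(R2, Rc):.2f} bits   (relevancy of f2)")
print(f"I(f1;f2) = {mutual_information_value(R1, R2):.2f} bits   (redundancy between f1, f2)")

pos = positive_region(R1, ClassPartition.from_labels(ds.y))
print("\nPositive region under f1:", np.round(pos, 2))
print("Each entry is how certainly that object's class is determined by f1 alone.")

gamma = dependency_degree(ds, [0]).gamma
print(f"gamma_f1(C) = {gamma:.2f}  (mean positive-region membership)")
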