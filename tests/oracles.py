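"""Naive scalar-loop reference implementations used only for cross-checking.

These deliberately avoid numpy vectorization and any code path from the
package under test: everything is explicit Python loops over floats, so a
bug shared with the vectorized implementation is unlikely.
"""

import math


def relation_continuous(values):
    m = len(values)
    return [
        [math.exp(-abs(values[i] - values[j])) for j in range(m)]
        for i in range(m)
    ]


def relation_crisp(values):
    m = len(values)
    return [
        [1.0 if values[i] == values[j] else 0.0 for j in range(m)]
        for i in range(m)
    ]


def entropy(M):
    m = len(M)
    total = 0.0
    for i in range(m):
        card = sum(M[i][j] for j in range(m))
        total += math.log2(m / card)
    return total / m


def mutual_information(Ma, Mb):
    m = len(Ma)
    total = 0.0
    for i in range(m):
        a = sum(Ma[i])
        b = sum(Mb[i])
        ab = sum(min(Ma[i][j], Mb[i][j]) for j in range(m))
        total += math.log2(m * ab / (a * b))
    return total / m


def lukasiewicz(a, b):
    return min(1.0, 1.0 - a + b)


def lower_approximation(M, muX):
    m = len(M)
    return [
        min(lukasiewicz(M[i][j], muX[j]) for j in range(m)) for i in range(m)
    ]


def positive_region(M, labels):
    m = len(M)
    classes = sorted(set(labels))
    out = []
    for i in range(m):
        best = 0.0
        for c in classes:
            mu = [1.0 if labels[j] == c else 0.0 for j in range(m)]
            best = max(best, lower_approximation(M, mu)[i])
        out.append(best)
    return out


def min_relation(mats):
    m = len(mats[0])
    return [
        [min(M[i][j] for M in mats) for j in range(m)] for i in range(m)
    ]


def dependency(X_cols, kinds, labels, subset):
    """gamma of a feature subset from raw columns, fully scalar."""
    mats = []
    for j in subset:
        rel = (
            relation_continuous(X_cols[j])
            if kinds[j] == "continuous"
            else relation_crisp(X_cols[j])
        )
        mats.append(rel)
    M = min_relation(mats)
    pos = positive_region(M, labels)
    return sum(pos) / len(pos)
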