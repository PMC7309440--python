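"""Independent brute-force oracles used by the test suite.

These deliberately reimplement the statistics by direct enumeration so that
the package's vectorised / polynomial-time implementations are checked
against a different computational route.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_c_index(predictions, outcomes) -> float:
    """O(n^2) pair-counting concordance with the 0.5 tie rule."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    usable = concordant = 0.0
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            if y[i] == y[j]:
                continue
            usable += 1
            prod = (p[i] - p[j]) * (y[i] - y[j])
            if prod > 0:
                concordant += 1
            elif prod == 0:
                concordant += 0.5
    if usable == 0:
        raise ZeroDivisionError("no usable pairs")
    return concordant / usable


def tree_expectation(tree, x, coalition: set[int]) -> float:
    """Tree-conditional expectation: follow x on coalition features, average
    children with cover weights elsewhere."""

    def rec(i: int) -> float:
        if tree.is_leaf(i):
            return float(tree.value[i])
        f = int(tree.feature[i])
        left, right = int(tree.children_left[i]), int(tree.children_right[i])
        if f in coalition:
            return rec(left) if x[f] <= tree.threshold[i] else rec(right)
        wl, wr = tree.cover[left], tree.cover[right]
        return (wl * rec(left) + wr * rec(right)) / (wl + wr)

    return rec(0)


def brute_shapley(ensemble, x, n_features: int) -> np.ndarray:
    """Exact Shapley values by exhaustive coalition enumeration, per tree.

    Features a tree never splits on are dummy players and can be dropped
    from that tree's game without changing the values.
    """
    phi = np.zeros(n_features)
    for tree in ensemble.trees:
        feats = sorted(set(tree.feature[tree.children_left >= 0].tolist()))
        d = len(feats)
        for i in feats:
            others = [f for f in feats if f != i]
            for r in range(d):
                for S in itertools.combinations(others, r):
                    w = math.factorial(r) * math.factorial(d - r - 1) / math.factorial(d)
                    gain = tree_expectation(tree, x, set(S) | {i}) - tree_expectation(
                        tree, x, set(S)
                    )
                    phi[i] += w * gain
    return phi


def univariate_lasso(x, y, lam: float) -> tuple[float, float]:
    """Closed-form single-feature lasso under the 1/(2n) * RSS + lam*|w|
    objective (soft thresholding of the empirical covariance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    sxy = float((xc * yc).mean())
    sxx = float((xc * xc).mean())
    w = np.sign(sxy) * max(abs(sxy) - lam, 0.0) / sxx
    return w, float(y.mean() - w * x.mean())
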