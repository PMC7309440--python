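"""Shapley feature attributions for tree ensembles and their aggregation
into percent-contribution importance reports.

Attributions follow the tree-conditional expectation convention: the value
of a feature coalition is the model output when the coalition's features are
fixed at the subject's values and the remaining splits are averaged with the
training cover weights.  For ensembles in the neutral :class:`TreeEnsemble`
form the attributions are computed here with the polynomial-time
path-dependent algorithm; for fitted LightGBM regressors the library's
native contribution output (the same algorithm in C++) is used.  Both routes
satisfy local accuracy: base value + attributions = prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class Tree:
    """One regression tree in flat array form.

    Leaves have ``children_left[i] == -1``; ``feature``/``threshold`` are
    meaningful at internal nodes only; ``cover`` is the training sample count
    reaching each node; ``value`` holds leaf outputs (internal entries are
    ignored).  Split rule: go left when x[feature] <= threshold.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    cover: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.children_left)
        for name in ("children_right", "feature", "threshold", "cover", "value"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        self.children_left = np.asarray(self.children_left, dtype=int)
        self.children_right = np.asarray(self.children_right, dtype=int)
        self.feature = np.asarray(self.feature, dtype=int)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.cover = np.asarray(self.cover, dtype=float)
        self.value = np.asarray(self.value, dtype=float)

    def is_leaf(self, i: int) -> bool:
        return self.children_left[i] < 0

    def predict_one(self, x: np.ndarray) -> float:
        i = 0
        while not self.is_leaf(i):
            i = self.children_left[i] if x[self.feature[i]] <= self.threshold[i] else self.children_right[i]
        return float(self.value[i])

    def expected_value(self) -> float:
        """Cover-weighted mean leaf output."""

        def rec(i: int) -> float:
            if self.is_leaf(i):
                return float(self.value[i])
            l, r = self.children_left[i], self.children_right[i]
            wl, wr = self.cover[l], self.cover[r]
            return (wl * rec(l) + wr * rec(r)) / (wl + wr)

        return rec(0)

    def decision_path(self, x: np.ndarray) -> list[tuple[int, float, str]]:
        """Root-to-leaf path as (feature, threshold, direction) steps."""
        i, path = 0, []
        while not self.is_leaf(i):
            f, t = int(self.feature[i]), float(self.threshold[i])
            if x[f] <= t:
                path.append((f, t, "left"))
                i = self.children_left[i]
            else:
                path.append((f, t, "right"))
                i = self.children_right[i]
        return path


@dataclass
class TreeEnsemble:
    trees: list[Tree]
    feature_names: Sequence[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        if self.feature_names:
            return len(self.feature_names)
        return int(max((t.feature[t.children_left >= 0].max(initial=-1) for t in self.trees), default=-1)) + 1

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([sum(t.predict_one(x) for t in self.trees) for x in X])

    def expected_value(self) -> float:
        return float(sum(t.expected_value() for t in self.trees))


def _flatten_lgbm_tree(structure: dict) -> Tree:
    cl, cr, feat, thr, cov, val = [], [], [], [], [], []

    def add(node: dict) -> int:
        idx = len(cl)
        is_split = "split_feature" in node
        cl.append(-1)
        cr.append(-1)
        feat.append(int(node["split_feature"]) if is_split else -1)
        thr.append(float(node["threshold"]) if is_split else 0.0)
        cov.append(float(node["internal_count"] if is_split else node.get("leaf_count", 1)))
        val.append(0.0 if is_split else float(node["leaf_value"]))
        if is_split:
            left = add(node["left_child"])
            right = add(node["right_child"])
            cl[idx], cr[idx] = left, right
        return idx

    add(structure)
    return Tree(
        children_left=np.array(cl),
        children_right=np.array(cr),
        feature=np.array(feat),
        threshold=np.array(thr),
        cover=np.array(cov),
        value=np.array(val),
    )


def ensemble_from_lightgbm(model) -> TreeEnsemble:
    """Convert a fitted LGBMRegressor (or Booster) to the neutral form."""
    booster = getattr(model, "booster_", model)
    dump = booster.dump_model()
    trees = [_flatten_lgbm_tree(t["tree_structure"]) for t in dump["tree_info"]]
    return TreeEnsemble(trees=trees, feature_names=list(dump["feature_names"]))


# ---------------------------------------------------------------------------
# Path-dependent TreeSHAP (pure Python, for neutral ensembles)

class _Path:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self) -> None:
        self.d: list[int] = []
        self.z: list[float] = []
        self.o: list[float] = []
        self.w: list[float] = []

    def copy(self) -> "_Path":
        p = _Path()
        p.d, p.z, p.o, p.w = self.d[:], self.z[:], self.o[:], self.w[:]
        return p

    def extend(self, pz: float, po: float, pi: int) -> None:
        l = len(self.d)
        self.d.append(pi)
        self.z.append(pz)
        self.o.append(po)
        self.w.append(1.0 if l == 0 else 0.0)
        for i in range(l - 1, -1, -1):
            self.w[i + 1] += po * self.w[i] * (i + 1) / (l + 1)
            self.w[i] = pz * self.w[i] * (l - i) / (l + 1)

    def unwind(self, i: int) -> None:
        depth = len(self.d) - 1
        o, z = self.o[i], self.z[i]
        n = self.w[depth]
        for j in range(depth - 1, -1, -1):
            if o != 0:
                t = self.w[j]
                self.w[j] = n * (depth + 1) / ((j + 1) * o)
                n = t - self.w[j] * z * (depth - j) / (depth + 1)
            else:
                self.w[j] = self.w[j] * (depth + 1) / (z * (depth - j))
        for j in range(i, depth):
            self.d[j], self.z[j], self.o[j] = self.d[j + 1], self.z[j + 1], self.o[j + 1]
        del self.d[depth], self.z[depth], self.o[depth], self.w[depth]

    def unwound_sum(self, i: int) -> float:
        depth = len(self.d) - 1
        o, z = self.o[i], self.z[i]
        n = self.w[depth]
        total = 0.0
        if o != 0:
            for j in range(depth - 1, -1, -1):
                t = n / ((j + 1) * o)
                total += t
                n = self.w[j] - t * z * (depth - j)
        else:
            for j in range(depth - 1, -1, -1):
                total += self.w[j] / (z * (depth - j))
        return total * (depth + 1)


def _tree_shap_one(tree: Tree, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(node: int, path: _Path, pz: float, po: float, pi: int) -> None:
        path = path.copy()
        path.extend(pz, po, pi)
        if tree.is_leaf(node):
            for i in range(1, len(path.d)):
                w = path.unwound_sum(i)
                phi[path.d[i]] += w * (path.o[i] - path.z[i]) * tree.value[node]
            return
        f, t = int(tree.feature[node]), float(tree.threshold[node])
        left, right = int(tree.children_left[node]), int(tree.children_right[node])
        hot, cold = (left, right) if x[f] <= t else (right, left)
        w = tree.cover[node]
        hot_z = tree.cover[hot] / w
        cold_z = tree.cover[cold] / w
        iz, io = 1.0, 1.0
        k = next((j for j in range(1, len(path.d)) if path.d[j] == f), None)
        if k is not None:
            iz, io = path.z[k], path.o[k]
            path.unwind(k)
        recurse(hot, path, hot_z * iz, io, f)
        recurse(cold, path, cold_z * iz, 0.0, f)

    recurse(0, _Path(), 1.0, 1.0, -1)


@dataclass
class AttributionMatrix:
    """Per-subject, per-feature Shapley attributions plus the base value
    (the model's expected output).  Local accuracy: for every row,
    base_value + sum(attributions) equals the model prediction."""

    values: np.ndarray  # (n_subjects, n_features)
    base_value: float
    feature_names: list[str]
    subject_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        idx = self.subject_ids if self.subject_ids else range(len(self.values))
        return pd.DataFrame(self.values, index=idx, columns=self.feature_names)

    def local_accuracy_error(self, predictions: np.ndarray) -> float:
        recon = self.base_value + self.values.sum(axis=1)
        return float(np.max(np.abs(recon - np.asarray(predictions, dtype=float))))


def tree_shap(model, X, feature_names: Sequence[str] | None = None) -> AttributionMatrix:
    """Shapley attributions for a tree model on a feature matrix.

    ``model`` may be a fitted LGBMRegressor (fast native route) or a
    :class:`TreeEnsemble` (pure-Python route, usable for hand-built trees).
    ``X`` may be a DataFrame (column names become feature names) or array.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        sids = [str(i) for i in X.index]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        if feature_names:
            names = list(feature_names)
        elif isinstance(model, TreeEnsemble) and model.feature_names:
            names = list(model.feature_names)
        else:
            names = [f"f{i}" for i in range(arr.shape[1])]
        sids = []

    if isinstance(model, TreeEnsemble):
        phi = np.zeros((arr.shape[0], arr.shape[1]))
        for tree in model.trees:
            for r, x in enumerate(arr):
                row = np.zeros(arr.shape[1])
                _tree_shap_one(tree, x, row)
                phi[r] += row
        base = model.expected_value()
        return AttributionMatrix(values=phi, base_value=base, feature_names=names, subject_ids=sids)

    booster = getattr(model, "booster_", model)
    contrib = booster.predict(arr, pred_contrib=True)
    return AttributionMatrix(
        values=np.asarray(contrib[:, :-1]),
        base_value=float(contrib[0, -1]),
        feature_names=names,
        subject_ids=sids,
    )


# ---------------------------------------------------------------------------
# Aggregation

@dataclass
class ImportanceReport:
    """Per-feature percent contributions (mean absolute Shapley attribution,
    normalised to sum to 100) and the ordered top of the list."""

    percents: pd.Series  # descending; ties broken by feature name

    def __post_init__(self) -> None:
        total = float(self.percents.sum())
        if not np.isclose(total, 100.0, atol=1e-6):
            raise ValueError(f"percents sum to {total}, expected 100")

    def top(self, k: int = 3) -> list[tuple[str, float]]:
        return [(str(n), float(v)) for n, v in self.percents.head(k).items()]

    def to_dict(self) -> dict[str, float]:
        return {str(k): float(v) for k, v in self.percents.items()}


def aggregate_importance(attributions: AttributionMatrix) -> ImportanceReport:
    """Mean |attribution| per feature as a percentage of the total."""
    mean_abs = np.abs(attributions.values).mean(axis=0)
    total = mean_abs.sum()
    if total == 0:
        raise ValueError("all attributions are zero; importance undefined")
    pct = pd.Series(100.0 * mean_abs / total, index=attributions.feature_names)
    pct = pct.iloc[np.lexsort((np.asarray(pct.index, dtype=object), -pct.to_numpy()))]
    return ImportanceReport(percents=pct)
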