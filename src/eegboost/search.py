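"""Per-symptom boosted-tree model search.

For one HRSD item the search evaluates every valid EEG feature combination
(power type x band subset x region filter x derived-feature flags) crossed
with a grid of tree parameters, scoring each pair by the concordance index
of pooled out-of-fold predictions from stratified k-fold cross-validation,
and returns the maximising pair (first in enumeration order on ties).
Baseline HRSD item scores are appended to the EEG features in the default
input mode; treatment arms enter as three binary indicator features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortDataset, N_ITEMS
from .evaluate import EvalConfig, bootstrap_ci, c_index
from .spectral import BAND_ORDER, FeatureCombination, REGION_FILTERS, features_from_band_powers

INPUT_MODES = ("eeg+hrsd", "hrsd", "eeg")


class DegenerateFitError(ValueError):
    """The outcome is constant (or otherwise unfittable)."""


@dataclass(frozen=True)
class TreeParams:
    n_estimators: int = 100
    max_depth: int = 3
    num_leaves: int = 7
    learning_rate: float = 0.1
    min_child_samples: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1 or self.num_leaves < 2:
            raise ValueError("n_estimators, max_depth >= 1 and num_leaves >= 2 required")
        if self.num_leaves > 2**self.max_depth:
            raise ValueError(
                f"num_leaves {self.num_leaves} exceeds 2^max_depth = {2**self.max_depth}"
            )


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    seed: int = 0
    #: classes smaller than this are merged into the nearest-valued class
    #: before stratification; defaults to k.
    min_class_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def default_grid(seed: int = 0) -> list[TreeParams]:
    """Default tree-parameter grid; pairs violating num_leaves <= 2^depth
    are dropped."""
    grid = []
    for n, d, l in itertools.product((50, 100, 200), (3, 5, 7), (7, 31)):
        if l <= 2**d:
            grid.append(TreeParams(n_estimators=n, max_depth=d, num_leaves=l, seed=seed))
    return grid


# ---------------------------------------------------------------------------
# Feature-combination enumeration

@dataclass(frozen=True)
class SearchSpace:
    power_types: tuple[str, ...] = ("absolute", "relative")
    bands: tuple[str, ...] = BAND_ORDER
    regions: tuple[str, ...] = tuple(REGION_FILTERS)
    #: (include_asymmetry, include_beta_alpha_ratio) option tuples
    extras: tuple[tuple[bool, bool], ...] = ((False, False),)

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band set must be nonempty")


def enumerate_feature_combinations(space: SearchSpace) -> list[FeatureCombination]:
    """Deterministic, duplicate-free enumeration: power type, then band
    subsets (by size, then band order), then regions, then extras."""
    combos = []
    for ptype in space.power_types:
        for r in range(1, len(space.bands) + 1):
            for subset in itertools.combinations(space.bands, r):
                for region in space.regions:
                    for asym, ratio in space.extras:
                        combos.append(
                            FeatureCombination(
                                power_type=ptype,
                                bands=subset,
                                region_filter=region,
                                include_asymmetry=asym,
                                include_beta_alpha_ratio=ratio,
                            )
                        )
    return combos


# ---------------------------------------------------------------------------
# Stratified folds for an integer-valued outcome

def merge_small_classes(values: np.ndarray, min_count: int) -> np.ndarray:
    """Class labels for stratification: one class per distinct value, with
    classes of fewer than ``min_count`` members merged into the class whose
    representative value is nearest (ties toward the smaller value)."""
    values = np.asarray(values)
    classes: list[list] = [[v] for v in np.unique(values)]
    counts = [int((values == c[0]).sum()) for c in classes]

    def rep(cls: list) -> float:  # member-weighted mean value of a class
        members = np.concatenate([values[values == v] for v in cls])
        return float(members.mean())

    while len(classes) > 1 and min(counts) < min_count:
        i = int(np.argmin(counts))
        reps = [rep(c) for c in classes]
        dists = [abs(reps[j] - reps[i]) if j != i else np.inf for j in range(len(classes))]
        j = int(np.argmin(dists))
        a, b = sorted((i, j))
        classes[a] = sorted(classes[a] + classes[b])
        counts[a] += counts[b]
        del classes[b], counts[b]

    label_of = {v: k for k, cls in enumerate(classes) for v in cls}
    return np.array([label_of[v] for v in values])


def stratified_folds(outcomes: np.ndarray, cv: CVConfig) -> list[np.ndarray]:
    """k disjoint, exhaustive validation index sets with sizes differing by
    at most one and approximately proportional class composition."""
    y = np.asarray(outcomes)
    if len(y) < cv.k:
        raise ValueError(f"n={len(y)} subjects < k={cv.k} folds")
    min_count = cv.min_class_size if cv.min_class_size is not None else cv.k
    labels = merge_small_classes(y, min_count)
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    return [test for _, test in skf.split(np.zeros(len(y)), labels)]


# ---------------------------------------------------------------------------
# GBDT fitting and pooled CV prediction

def fit_gbdt(features: pd.DataFrame, outcomes: np.ndarray, params: TreeParams) -> LGBMRegressor:
    """Squared-error gradient-boosted tree ensemble, deterministic given the
    seed, with per-tree structure accessible for Shapley attribution."""
    y = np.asarray(outcomes, dtype=float)
    if np.unique(y).size < 2:
        raise DegenerateFitError("outcome is constant; nothing to fit")
    model = LGBMRegressor(
        objective="regression",
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        num_leaves=params.num_leaves,
        learning_rate=params.learning_rate,
        min_child_samples=params.min_child_samples,
        random_state=params.seed,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(features, y)
    return model


def pooled_cv_predict(
    features: pd.DataFrame,
    outcomes: np.ndarray,
    params: TreeParams,
    cv: CVConfig,
    folds: Optional[Sequence[np.ndarray]] = None,
) -> np.ndarray:
    """Out-of-fold predictions pooled over the k validation folds; each
    subject is predicted by the model whose training set excluded it."""
    y = np.asarray(outcomes, dtype=float)
    if folds is None:
        folds = stratified_folds(y, cv)
    preds = np.full(len(y), np.nan)
    all_idx = np.arange(len(y))
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        model = fit_gbdt(features.iloc[train], y[train], params)
        preds[test] = model.predict(features.iloc[test])
    if np.isnan(preds).any():
        raise RuntimeError("folds did not cover every subject")
    return preds


# ---------------------------------------------------------------------------
# The search itself

@dataclass
class AnalysisDataset:
    """Aligned per-subject inputs for the search: absolute band powers
    (site x band MultiIndex columns), baseline HRSD items, improvements,
    and optional treatment indicator features."""

    band_powers: pd.DataFrame
    baseline: pd.DataFrame
    improvement: pd.DataFrame
    treatment: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        idx = self.band_powers.index
        for name in ("baseline", "improvement"):
            other = getattr(self, name)
            if not idx.equals(other.index):
                raise ValueError(f"{name} index is not aligned with band_powers")
        if self.treatment is not None and not idx.equals(self.treatment.index):
            raise ValueError("treatment index is not aligned with band_powers")

    @classmethod
    def from_cohort(cls, cohort: CohortDataset, band_powers: pd.DataFrame) -> "AnalysisDataset":
        bp = band_powers.loc[cohort.subject_ids]
        return cls(
            band_powers=bp,
            baseline=cohort.baseline_matrix(),
            improvement=cohort.improvement_matrix(),
            treatment=cohort.treatment_dummies(),
        )

    def outcome(self, symptom: int) -> np.ndarray:
        if not 1 <= symptom <= N_ITEMS:
            raise ValueError(f"symptom index {symptom} outside 1..{N_ITEMS}")
        return self.improvement[f"item_{symptom:02d}"].to_numpy()


def build_features(
    dataset: AnalysisDataset,
    combination: Optional[FeatureCombination],
    input_mode: str = "eeg+hrsd",
    with_treatment: bool = False,
) -> pd.DataFrame:
    """Assemble the model input for one (combination, mode) choice."""
    if input_mode not in INPUT_MODES:
        raise ValueError(f"input_mode must be one of {INPUT_MODES}")
    parts = []
    if input_mode in ("eeg+hrsd", "eeg"):
        if combination is None:
            raise ValueError(f"input mode {input_mode!r} needs a feature combination")
        parts.append(features_from_band_powers(dataset.band_powers, combination))
    if input_mode in ("eeg+hrsd", "hrsd"):
        base = dataset.baseline.copy()
        base.columns = [f"baseline {c}" for c in base.columns]
        parts.append(base)
    if with_treatment:
        if dataset.treatment is None:
            raise ValueError("dataset has no treatment arms")
        parts.append(dataset.treatment)
    return pd.concat(parts, axis=1)


@dataclass
class ModelResult:
    symptom: int
    input_mode: str
    with_treatment: bool
    combination: Optional[FeatureCombination]
    params: TreeParams
    predictions: pd.Series  # pooled out-of-fold, aligned to subject ids
    c: float
    ci_low: float
    ci_high: float
    n_evaluated_pairs: int

    def __post_init__(self) -> None:
        if not (0 <= self.c <= 1 and self.ci_low <= self.c <= self.ci_high):
            raise ValueError("C index / CI ordering violated")

    def to_dict(self) -> dict:
        return {
            "symptom": self.symptom,
            "input_mode": self.input_mode + ("+treatment" if self.with_treatment else ""),
            "combination": self.combination.label() if self.combination else None,
            "params": {
                "n_estimators": self.params.n_estimators,
                "max_depth": self.params.max_depth,
                "num_leaves": self.params.num_leaves,
                "learning_rate": self.params.learning_rate,
                "seed": self.params.seed,
            },
            "c_index": self.c,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_evaluated_pairs": self.n_evaluated_pairs,
        }


def search(
    dataset: AnalysisDataset,
    symptom: int,
    combos: Sequence[Optional[FeatureCombination]],
    grid: Sequence[TreeParams],
    cv: CVConfig = CVConfig(),
    input_mode: str = "eeg+hrsd",
    with_treatment: bool = False,
    eval_cfg: EvalConfig = EvalConfig(),
    min_child_samples: Optional[int] = None,
    nested: bool = False,
) -> ModelResult:
    """Evaluate every (combination, params) pair by the pooled out-of-fold
    C index and return the maximiser (earlier pair wins ties).

    In mode "hrsd" the combination axis is ignored (a single None entry is
    evaluated).  Folds are stratified once on the symptom's improvement and
    shared by every pair, so scores are comparable across the search.  By
    default selection and reporting share the same pooled CV (which is
    optimistic); ``nested=True`` instead selects the pair inside each
    training fold and reports honest outer-fold predictions.
    """
    if not combos or not grid:
        raise ValueError("combos and grid must be nonempty")
    if nested:
        return _nested_search(
            dataset, symptom, combos, grid, cv, input_mode, with_treatment, eval_cfg,
            min_child_samples,
        )
    y = dataset.outcome(symptom)
    folds = stratified_folds(y, cv)
    combo_axis: Sequence[Optional[FeatureCombination]]
    combo_axis = [None] if input_mode == "hrsd" else list(combos)

    best: Optional[tuple[float, Optional[FeatureCombination], TreeParams, np.ndarray]] = None
    n_pairs = 0
    for combo in combo_axis:
        features = build_features(dataset, combo, input_mode, with_treatment)
        for params in grid:
            if min_child_samples is not None:
                params = replace(params, min_child_samples=min_child_samples)
            try:
                preds = pooled_cv_predict(features, y, params, cv, folds=folds)
                score = c_index(preds, y)
            except DegenerateFitError:
                continue
            n_pairs += 1
            if best is None or score > best[0]:
                best = (score, combo, params, preds)
    if best is None:
        raise DegenerateFitError(f"symptom {symptom}: every (combination, params) pair degenerate")

    score, combo, params, preds = best
    lo, hi = bootstrap_ci(c_index, preds, y, eval_cfg)
    return ModelResult(
        symptom=symptom,
        input_mode=input_mode,
        with_treatment=with_treatment,
        combination=combo,
        params=params,
        predictions=pd.Series(preds, index=dataset.band_powers.index),
        c=score,
        ci_low=min(lo, score),
        ci_high=max(hi, score),
        n_evaluated_pairs=n_pairs,
    )


def pooled_cv_attributions(
    dataset: AnalysisDataset,
    result: ModelResult,
    cv: CVConfig = CVConfig(),
    min_child_samples: Optional[int] = None,
    refit: bool = False,
):
    """Shapley attributions for a selected model.

    By default each training fold's model attributes its own validation
    fold and the rows are pooled (matching the pooled-prediction
    philosophy); the pooled matrix's base value is the subject-weighted mean
    of the per-fold base values.  ``refit=True`` instead fits one model on
    all subjects and attributes every row with it (exact local accuracy
    against that single model).
    """
    from .shapley import AttributionMatrix, tree_shap

    features = build_features(
        dataset, result.combination, result.input_mode, result.with_treatment
    )
    y = dataset.outcome(result.symptom)
    params = result.params
    if min_child_samples is not None:
        params = replace(params, min_child_samples=min_child_samples)
    sids = [str(i) for i in features.index]

    if refit:
        model = fit_gbdt(features, y, params)
        am = tree_shap(model, features)
        am.subject_ids = sids
        return am

    folds = stratified_folds(y, cv)
    all_idx = np.arange(len(y))
    values = np.zeros(features.shape)
    base_acc = 0.0
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        model = fit_gbdt(features.iloc[train], y[train], params)
        am = tree_shap(model, features.iloc[test])
        values[test] = am.values
        base_acc += am.base_value * len(test)
    return AttributionMatrix(
        values=values,
        base_value=base_acc / len(y),
        feature_names=list(features.columns),
        subject_ids=sids,
    )


def _nested_search(
    dataset: AnalysisDataset,
    symptom: int,
    combos: Sequence[Optional[FeatureCombination]],
    grid: Sequence[TreeParams],
    cv: CVConfig,
    input_mode: str,
    with_treatment: bool,
    eval_cfg: EvalConfig,
    min_child_samples: Optional[int],
) -> ModelResult:
    """Nested variant: the (combination, params) pair is selected by an inner
    pooled CV restricted to each outer training fold, then scored on the
    held-out outer fold; the reported pair is the modal selection."""
    y = dataset.outcome(symptom)
    outer = stratified_folds(y, cv)
    all_idx = np.arange(len(y))
    combo_axis = [None] if input_mode == "hrsd" else list(combos)
    feature_cache = {
        id(combo): build_features(dataset, combo, input_mode, with_treatment)
        for combo in combo_axis
    }

    preds = np.full(len(y), np.nan)
    selections: list[tuple[int, int]] = []
    for test in outer:
        train = np.setdiff1d(all_idx, test)
        y_tr = y[train]
        inner = stratified_folds(y_tr, cv)
        best = None
        for ci_, combo in enumerate(combo_axis):
            feats_tr = feature_cache[id(combo)].iloc[train]
            for pi, params in enumerate(grid):
                if min_child_samples is not None:
                    params = replace(params, min_child_samples=min_child_samples)
                try:
                    inner_preds = pooled_cv_predict(feats_tr, y_tr, params, cv, folds=inner)
                    score = c_index(inner_preds, y_tr)
                except DegenerateFitError:
                    continue
                if best is None or score > best[0]:
                    best = (score, ci_, pi, params)
        if best is None:
            raise DegenerateFitError(f"symptom {symptom}: nested inner search degenerate")
        _, ci_, pi, params = best
        selections.append((ci_, pi))
        feats = feature_cache[id(combo_axis[ci_])]
        model = fit_gbdt(feats.iloc[train], y[train], params)
        preds[test] = model.predict(feats.iloc[test])

    modal_ci, modal_pi = max(set(selections), key=lambda s: (selections.count(s), -s[0], -s[1]))
    score = c_index(preds, y)
    lo, hi = bootstrap_ci(c_index, preds, y, eval_cfg)
    return ModelResult(
        symptom=symptom,
        input_mode=input_mode,
        with_treatment=with_treatment,
        combination=combo_axis[modal_ci],
        params=grid[modal_pi],
        predictions=pd.Series(preds, index=dataset.band_powers.index),
        c=score,
        ci_low=min(lo, score),
        ci_high=max(hi, score),
        n_evaluated_pairs=len(combo_axis) * len(grid),
    )
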