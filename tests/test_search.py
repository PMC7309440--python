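import numpy as np
import pandas as pd
import pytest

from eegboost.evaluate import EvalConfig, c_index
from eegboost.search import (
    AnalysisDataset,
    CVConfig,
    DegenerateFitError,
    SearchSpace,
    TreeParams,
    build_features,
    default_grid,
    enumerate_feature_combinations,
    fit_gbdt,
    merge_small_classes,
    pooled_cv_predict,
    search,
    stratified_folds,
)
from eegboost.simulate import SimulationConfig, calibrated_effect, simulate_cohort
from eegboost.cohort import apply_exclusions

EV_FAST = EvalConfig(B=50, seed=0)


class TestEnumeration:
    def test_full_space_has_248_combinations(self):
        combos = enumerate_feature_combinations(SearchSpace())
        assert len(combos) == 2 * 31 * 4
        assert len(set(combos)) == len(combos)  # no duplicates

    def test_two_band_space_has_24_combinations(self):
        space = SearchSpace(bands=("alpha", "beta"))
        assert len(enumerate_feature_combinations(space)) == 2 * 3 * 4

    def test_singleton_space(self):
        space = SearchSpace(power_types=("absolute",), bands=("alpha",), regions=("occipital",))
        combos = enumerate_feature_combinations(space)
        assert len(combos) == 1
        assert combos[0].bands == ("alpha",)

    def test_enumeration_is_deterministic(self):
        assert enumerate_feature_combinations(SearchSpace()) == enumerate_feature_combinations(
            SearchSpace()
        )

    def test_default_grid_respects_leaf_bound(self):
        for p in default_grid():
            assert p.num_leaves <= 2**p.max_depth

    def test_invalid_leaf_count_rejected(self):
        with pytest.raises(ValueError, match="num_leaves"):
            TreeParams(max_depth=3, num_leaves=31)


class TestStratifiedFolds:
    def test_two_balanced_classes_force_one_each_per_fold(self):
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        folds = stratified_folds(y, CVConfig(k=5, seed=0))
        for f in folds:
            assert len(f) == 2
            assert set(y[f]) == {0, 1}

    def test_fold_sizes_at_518(self):
        rng = np.random.default_rng(0)
        y = np.rint(rng.normal(-1, 1.2, size=518)).astype(int)
        sizes = sorted(len(f) for f in stratified_folds(y, CVConfig(k=5, seed=0)))
        assert sizes == [103, 103, 104, 104, 104]

    def test_folds_partition_the_index_set(self):
        rng = np.random.default_rng(1)
        y = rng.integers(-3, 2, size=87)
        folds = stratified_folds(y, CVConfig(k=5, seed=1))
        combined = np.sort(np.concatenate(folds))
        assert np.array_equal(combined, np.arange(87))
        for i in range(len(folds)):
            for j in range(i + 1, len(folds)):
                assert not set(folds[i]) & set(folds[j])

    def test_class_proportions_approximately_preserved(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1, 2], [60, 30, 15])
        folds = stratified_folds(y, CVConfig(k=5, seed=2))
        for f in folds:
            for cls, total in zip([0, 1, 2], [60, 30, 15]):
                assert abs((y[f] == cls).sum() - total / 5) <= 1

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([0, 1, 0]), CVConfig(k=5))

    def test_small_classes_are_merged_with_nearest_value(self):
        y = np.array([-3] * 2 + [-1] * 20 + [0] * 20)  # class -3 has < 5 members
        labels = merge_small_classes(y, min_count=5)
        assert labels[0] == labels[2]  # -3 merged into -1
        assert labels[2] != labels[-1]


class TestFitAndPredict:
    def test_perfect_monotone_feature_reaches_unit_training_c(self):
        # one feature value per outcome group so histogram binning cannot
        # blur a group boundary
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 20)
        y = np.repeat([0.0, 1.0, 2.0, 3.0], 20)  # perfectly rank-correlated
        X = pd.DataFrame({"x": x})
        params = TreeParams(n_estimators=50, max_depth=4, num_leaves=15, min_child_samples=1)
        model = fit_gbdt(X, y, params)
        assert c_index(model.predict(X), y) == 1.0

    def test_constant_outcome_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_gbdt(pd.DataFrame({"x": [1.0, 2.0]}), np.array([1.0, 1.0]), TreeParams())

    def test_single_stump_yields_at_most_two_prediction_values(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = (X["x"] > 0).astype(float) + rng.normal(0, 0.1, 60)
        params = TreeParams(n_estimators=1, max_depth=1, num_leaves=2, min_child_samples=5)
        model = fit_gbdt(X, y.to_numpy(), params)
        assert np.unique(model.predict(X)).size <= 2

    def test_permuted_outcomes_give_chance_level_oof_c(self):
        rng = np.random.default_rng(7)
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        y = rng.permutation(np.rint(rng.normal(-1, 1, size=n)))
        params = TreeParams(n_estimators=50, max_depth=3, num_leaves=7)
        preds = pooled_cv_predict(X, y, params, CVConfig(k=5, seed=0))
        assert 0.4 <= c_index(preds, y) <= 0.6

    def test_every_subject_predicted_once_and_deterministically(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(0, 0.5, 50)
        params = TreeParams(n_estimators=20, min_child_samples=5)
        p1 = pooled_cv_predict(X, y, params, CVConfig(k=5, seed=3))
        p2 = pooled_cv_predict(X, y, params, CVConfig(k=5, seed=3))
        assert p1.shape == (50,)
        assert not np.isnan(p1).any()
        assert np.array_equal(p1, p2)

    def test_leave_one_out_matches_per_subject_exclusion_oracle(self):
        rng = np.random.default_rng(3)
        n = 12
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.normal(size=n)
        params = TreeParams(n_estimators=5, max_depth=2, num_leaves=3, min_child_samples=1)
        folds = [np.array([i]) for i in range(n)]
        pooled = pooled_cv_predict(X, y, params, CVConfig(k=5), folds=folds)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            model = fit_gbdt(X.iloc[train], y[train], params)
            assert pooled[i] == pytest.approx(model.predict(X.iloc[[i]])[0], abs=1e-12)

    def test_no_leakage_from_validation_outcomes(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(0, 0.5, 60)
        params = TreeParams(n_estimators=10, min_child_samples=5)
        folds = stratified_folds(np.rint(y), CVConfig(k=5, seed=0))
        baseline = pooled_cv_predict(X, y, params, CVConfig(k=5), folds=folds)
        corrupted = y.copy()
        corrupted[folds[0]] = rng.normal(size=len(folds[0])) * 100
        with_corruption = pooled_cv_predict(X, corrupted, params, CVConfig(k=5), folds=folds)
        assert np.array_equal(baseline[folds[0]], with_corruption[folds[0]])


class TestSearch:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SimulationConfig(
            n_subjects=200, effects=(calibrated_effect(),), seed=1, eeg_mode="bandpower"
        )
        sim = simulate_cohort(cfg)
        cohort = apply_exclusions(sim.cohort.subjects)
        return AnalysisDataset.from_cohort(cohort, sim.band_powers)

    def test_single_pair_search_returns_it(self, planted):
        space = SearchSpace(power_types=("absolute",), bands=("alpha",), regions=("occipital",))
        combos = enumerate_feature_combinations(space)
        grid = [TreeParams(n_estimators=30, seed=0)]
        res = search(planted, 7, combos, grid, cv=CVConfig(seed=0), eval_cfg=EV_FAST)
        assert res.combination == combos[0]
        assert res.params == grid[0]
        assert len(res.predictions) == 200
        assert res.ci_low <= res.c <= res.ci_high

    def test_selected_score_dominates_every_evaluated_pair(self, planted):
        space = SearchSpace(
            power_types=("absolute",), bands=("alpha", "delta"), regions=("occipital", "frontal")
        )
        combos = enumerate_feature_combinations(space)
        grid = [TreeParams(n_estimators=30, seed=0), TreeParams(n_estimators=60, seed=0)]
        cv = CVConfig(seed=0)
        res = search(planted, 7, combos, grid, cv=cv, eval_cfg=EV_FAST)
        y = planted.outcome(7)
        from eegboost.search import stratified_folds as sf

        folds = sf(y, cv)
        for combo in combos:
            feats = build_features(planted, combo, "eeg+hrsd")
            for params in grid:
                preds = pooled_cv_predict(feats, y, params, cv, folds=folds)
                assert res.c >= c_index(preds, y) - 1e-12

    def test_planted_alpha_signal_selects_alpha_band(self):
        # signal lives in occipital alpha; the winning combination should
        # include the alpha band in most seeded replicates
        space = SearchSpace(
            power_types=("absolute",), bands=("alpha", "delta"), regions=("occipital",)
        )
        combos = enumerate_feature_combinations(space)
        grid = [TreeParams(n_estimators=50, seed=0)]
        wins = 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_subjects=200, effects=(calibrated_effect(),), seed=100 + seed,
                eeg_mode="bandpower",
            )
            sim = simulate_cohort(cfg)
            ds = AnalysisDataset.from_cohort(
                apply_exclusions(sim.cohort.subjects), sim.band_powers
            )
            res = search(ds, 7, combos, grid, cv=CVConfig(seed=seed), input_mode="eeg",
                         eval_cfg=EV_FAST)
            wins += "alpha" in res.combination.bands
        assert wins >= 4

    def test_hrsd_mode_ignores_combination_axis(self, planted):
        combos = enumerate_feature_combinations(
            SearchSpace(power_types=("absolute",), bands=("alpha",), regions=("occipital",))
        )
        res = search(planted, 7, combos, [TreeParams(n_estimators=30)], cv=CVConfig(seed=0),
                     input_mode="hrsd", eval_cfg=EV_FAST)
        assert res.combination is None
        feats = build_features(planted, None, "hrsd")
        assert feats.shape[1] == 21
        assert all(c.startswith("baseline") for c in feats.columns)

    def test_treatment_mode_appends_three_binary_columns(self, planted):
        feats_base = build_features(planted, None, "hrsd")
        feats_trt = build_features(planted, None, "hrsd", with_treatment=True)
        assert feats_trt.shape[1] == feats_base.shape[1] + 3
        trt = feats_trt.iloc[:, -3:]
        assert set(np.unique(trt.to_numpy())) <= {0, 1}
        assert (trt.sum(axis=1) == 1).all()

    def test_empty_search_inputs_rejected(self, planted):
        with pytest.raises(ValueError):
            search(planted, 7, [], [TreeParams()], cv=CVConfig())
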