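# eegboost

Per-symptom prediction of antidepressant treatment response from
pretreatment resting-state EEG and baseline symptom ratings.

## The problem

Major depression is heterogeneous: two patients with the same total score on
the 21-item Hamilton Rating Scale for Depression (HRSD-21) can have very
different symptom profiles, and those symptoms do not respond uniformly to
medication. `eegboost` models the change in each HRSD-21 item separately.
The outcome for item *i* is the **improvement**

```
improvement_i = week8_i − baseline_i        (negative = the symptom improved)
```

and the predictors are quantitative features of a 2-minute eyes-closed
resting EEG recorded before treatment (26 scalp sites across frontal,
temporal, central, parietal and occipital regions) together with the 21
baseline item scores, and optionally three binary treatment-arm indicators
(escitalopram / sertraline / venlafaxine-XR).

Because no such clinical dataset is public, the package ships a first-class
synthetic cohort generator that emulates the study design — band-structured
EEG spectra, integer item scores on the correct per-item scales (ten items
scored 0–4, eleven scored 0–2), a dropout/missing-data exclusion flow, and
*planted* band-power → symptom-improvement effects with known ground truth —
so every stage of the analysis is testable end to end.

## The method

1. **Spectral features.** Welch power spectral density per site (Hann
   taper, 50% segment overlap), integrated with the Simpson rule over the
   five canonical bands — delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30,
   gamma 30–100 Hz — as absolute power (µV²) and relative power (fraction
   of the five-band total). Derived features: frontal alpha asymmetry
   `alpha(F4) − alpha(F3)` and per-site beta/alpha ratios. Feature names
   follow the `"<site> <band> <absolute|relative>"` convention, e.g.
   `"Fz alpha absolute"`.
2. **Model search.** For each symptom, gradient-boosted decision-tree
   (GBDT) regressions are trained over every valid *feature combination*
   (power type × nonempty band subset × region filter, where the region
   filter optionally restricts to occipital {O1, Oz, O2} and/or frontal
   {F7, F3, Fz, F4, F8} sites) crossed with a grid of tree parameters
   (number of estimators, maximum depth, number of leaves). Each pair is
   scored by stratified 5-fold cross-validation with **pooled out-of-fold
   predictions**, and the maximiser is selected (ties go to the earlier
   pair in enumeration order).
3. **Evaluation.** Discrimination is the concordance index
   `C = P(concordant | usable pair)`: among pairs of subjects with unequal
   outcomes, the fraction whose predictions are ordered like their outcomes
   (prediction ties count ½). Uncertainty comes from the nonparametric
   percentile bootstrap (1000 replicates); two models for the same subjects
   are compared by ΔC with a *paired* bootstrap. Goodness of fit (R², MAE,
   slope, intercept) is reported after a univariate lasso calibration map
   (regularisation coefficient 0.01) fitted on training-mode outputs.
4. **Attribution.** Feature credit uses Shapley values under the
   tree-conditional expectation convention (base value + attributions =
   prediction, exactly), aggregated as mean |attribution| per feature and
   normalised to percent of the total; the top-3 features per symptom are
   reported.

## Worked example

Simulate a 500-subject cohort in which improvement of item 7 (loss of
interest) depends on the baseline score *and* on occipital alpha power
(`O1 alpha absolute`), then ask whether the EEG adds predictive value over
the baseline scores alone:

```python
from eegboost import apply_exclusions
from eegboost.simulate import SimulationConfig, calibrated_effect, simulate_cohort
from eegboost.search import (AnalysisDataset, CVConfig, SearchSpace, TreeParams,
                             enumerate_feature_combinations,
                             pooled_cv_attributions, search)
from eegboost.evaluate import EvalConfig, delta_c_index
from eegboost.shapley import aggregate_importance

cfg = SimulationConfig(n_subjects=500, effects=(calibrated_effect(),), seed=7,
                       eeg_mode="bandpower")
sim = simulate_cohort(cfg)
dataset = AnalysisDataset.from_cohort(apply_exclusions(sim.cohort.subjects),
                                      sim.band_powers)

combos = enumerate_feature_combinations(
    SearchSpace(power_types=("absolute",), bands=("alpha",), regions=("occipital",)))
grid = [TreeParams(n_estimators=100, max_depth=3, num_leaves=7)]
cv, ev = CVConfig(k=5, seed=7), EvalConfig(B=1000, seed=7)

both = search(dataset, 7, combos, grid, cv=cv, input_mode="eeg+hrsd", eval_cfg=ev)
hrsd = search(dataset, 7, combos, grid, cv=cv, input_mode="hrsd", eval_cfg=ev)
delta = delta_c_index(both.predictions.to_numpy(), hrsd.predictions.to_numpy(),
                      dataset.outcome(7), ev)
imp = aggregate_importance(pooled_cv_attributions(dataset, both, cv=cv))
```

Output:

```
C (EEG + baseline scores): 0.791 (95% CI 0.765-0.815)
C (baseline scores only) : 0.714 (95% CI 0.686-0.741)
delta C                  : 0.077 (95% CI 0.053-0.100)
top-3 features by mean |Shapley| %:
  baseline item_07        32.6%
  O1 alpha absolute       28.4%
  Oz alpha absolute        3.8%
```

Reading this: the combined model orders a random unequal-outcome pair of
subjects correctly 79% of the time versus 71% for baseline scores alone;
the paired bootstrap CI for the difference excludes zero, so the EEG adds
discriminative value here; and the attribution recovers the planted driver
— the baseline score of the predicted symptom first (as expected, since it
enters the outcome directly), the planted `O1 alpha absolute` second, with
the correlated neighbouring occipital site picking up a small share.

The same analysis runs from a shell against a YAML config
(`eegboost run-all --config run.yaml`), producing a run directory with
per-symptom model JSONs, pooled predictions, ΔC and importance reports, a
per-patient decision-path explanation with none/low/medium/high improvement
buckets, a markdown summary, and a manifest of SHA-256 hashes — rerunning
with the same config and seed reproduces every file byte for byte.

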