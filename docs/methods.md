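# Methods

This note documents the models, numerical choices, and limitations behind
`eegboost`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Outcome model and data layout

The unit of analysis is one HRSD-21 item per subject. Ten items are scored
0–4 and eleven 0–2 (the standard instrument layout); the outcome is the
signed integer change `week8 − baseline`, negative meaning improvement. A
missing week-8 visit makes the subject a dropout: the package deliberately
does **not** impute single missing items, because the cohort bookkeeping it
emulates operates at visit granularity. The exclusion flow removes, in
order, dropouts, subjects without an EEG, and subjects with incomplete
features, counting each step among the survivors of the previous one; with
disjoint flag groups the final membership is order-insensitive, and the
provenance log always accounts exactly for `roster − retained`.

## Spectral estimation

**Welch PSD.** Hann taper, 50% overlap, per-segment mean removal (so DC
does not leak into delta), one-sided density normalised to the signal
variance (Parseval). Two defaults deserve justification:

- *Window length 4 s* (0.25 Hz resolution, configurable). The shortest
  window resolving the 0.5 Hz delta edge would be 2 s, but window mainlobe
  leakage across band edges then biases a weak band flanked by a strong one
  (beta next to eyes-closed alpha) by ~15–20%, which is scientifically
  material for relative-power features. At 4 s the bias falls below ~8%
  for the synthetic spectra used in testing, while a 2-minute recording
  still provides ~59 averaged segments.
- *Spectral oversampling (nfft = 4 × nperseg)*. Band powers are Simpson
  integrals of the sampled density. Composite Simpson quadrature assumes a
  smooth integrand; on the native Welch grid a line component (e.g. a pure
  10 Hz calibration tone) occupies ~3 bins and the Simpson weights
  misestimate its integral by ~11%. Evaluating the density on a 4× finer
  (zero-padded) grid leaves the integral of the density unchanged but makes
  peaks smooth at the quadrature scale; the Simpson band power of a pure
  tone is then within 2% of the analytic A²/2.

**Bands and features.** Delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30,
gamma 30–100 Hz. Absolute power in µV²; relative power divides by the sum
over the five bands (so relative powers sum to 1 — the most common qEEG
convention; total-spectrum normalisation would differ by the small
out-of-band residue). Frontal alpha asymmetry is `alpha(F4) − alpha(F3)`,
computed on whichever power type the feature combination uses (the source
method does not say which; both are available). The beta/alpha ratio is
computed per site for absolute and relative features consistently; if the
alpha denominator underflows (< 1e-12 µV²) the ratio is set to a large
sentinel (1e9) with a warning rather than failing the cohort — monotone
tree models are insensitive to the sentinel's magnitude. A generic
band-pair ratio helper exists for exploratory use but is not part of the
search space, because only the beta/alpha ratio has a defined place in the
feature families.

**Montage.** A fixed 26-label 10-20/10-10 set covering the five regions,
with the legacy aliases T3→T7, T4→T8, T5→P7, T6→P8 resolved on input.
Region filters: all sites, frontal {F7, F3, Fz, F4, F8}, occipital
{O1, Oz, O2}, or their union.

## Synthetic cohort generator

The generator's purpose is to produce data with the statistical structure
the analysis assumes — not physiologically realistic EEG.

**EEG.** Each channel is a sum over bands of `amplitude × unit-power
band-limited Gaussian noise` (random complex spectrum restricted to the
band, inverse-FFT'd, and normalised to unit sample variance), so the
realised per-band power equals amplitude² exactly and expected band powers
are analytic. Per-subject variation enters through lognormal multiplicative
amplitude modifiers (log-SD 0.4 by default) — a stand-in chosen for
convenience, since no subject-level EEG variance model is given by the
design being emulated. Default sampling rate 250 Hz (Nyquist 125 Hz covers
the full gamma band; a configured band edge above Nyquist is a hard config
error), default duration 120 s. The generator does not model 1/f background,
artifacts, eye blinks, or the eyes-open condition; consequently, passing
tests demonstrate correctness of the pipeline's statistics, not robustness
to real-world EEG contamination.

Two EEG modes exist: `waveform` (default) synthesises full recordings that
flow through Welch estimation; `bandpower` derives the per-site band powers
analytically with configurable multiplicative estimation noise (log-SD 0.05
by default, roughly matching the Welch estimator's dispersion on a
2-minute recording). Model-level simulation studies use `bandpower` to keep
many-seed experiments at n=500 tractable on one CPU; the waveform path is
exercised end to end at smaller n, and the two agree by construction up to
estimation noise.

**Scores.** Baselines are drawn per item from a discretised normal centred
at 60% of the item scale (SD 25% of the scale), truncated to range —
producing realistic nonzero baselines with room to improve. Improvements
follow

```
improvement_i = rint(β0 + β1·baseline_i + β2·z(feature) + ε),   ε ~ N(0, σ)
```

where `z(·)` standardises the *analytic expected* value of the named EEG
feature within the cohort (the extracted feature is a noisy estimate of the
same latent). `rint` rounds half to even. Week-8 scores are clipped to the
item scale; the clipped fraction is tracked and a configuration warning is
raised above 50%. Items without a configured effect default to
β0=0, β1=−0.5, β2=0, σ=0.8, giving mean improvements of roughly −0.6 to
−1.2 points depending on the scale — negative, as observed symptom change
under treatment should be. The generator is byte-reproducible given
(config, seed).

**Calibrated scenario.** The recovery study plants one effect on item 7
driven by `O1 alpha absolute`, calibrated so the pooled out-of-fold C index
is ≈0.80 with EEG + baseline inputs and ≈0.70 with baseline-only inputs at
n=500. Starting values came from the bivariate-normal identity
`C = 1/2 + arcsin(ρ)/π` relating concordance to predictor–outcome
correlation; because integer rounding removes near-ties and the C index
discards tied-outcome pairs, realised concordances run above the continuous
identity, and the final coefficients (β0=0.5, β1=−0.7, β2=−1.1, σ=1.0) were
fixed once by piloting the generator itself against those targets.

## Model search

GBDT regression (squared error) via LightGBM, seeded and single-threaded
for determinism, with per-tree structure exposed for attribution. The
search crosses every feature combination (power type × nonempty band subset
× region filter × derived-feature flags; deterministic enumeration order:
power type, then band subsets by size then band order, then regions) with a
tree-parameter grid. The default grid is n_estimators ∈ {50, 100, 200},
max_depth ∈ {3, 5, 7}, num_leaves ∈ {7, 31} (pairs violating
num_leaves ≤ 2^depth dropped), learning rate 0.1 — the grid axes are part
of the design being emulated but the values are not published, so these are
package defaults. In the default input mode the 21 baseline item scores are
always appended to the EEG features; `hrsd` mode uses the baseline scores
alone (the combination axis collapses); treatment arms enter as three
binary indicators.

**Cross-validation.** Stratified 5-fold with pooled out-of-fold
predictions: each subject is predicted by the model whose training set
excluded it, and the C index is computed once on the pooled vector.
Stratification classes for the integer-valued outcome are one class per
distinct improvement value, with classes smaller than k merged into the
class of nearest (member-weighted mean) value — a natural reading of
"approximately equal percentage of each class" for an integer target. Fold
sizes differ by at most one and per-class composition is proportional
within one member. Folds are stratified once per symptom and shared across
all (combination, parameter) pairs so scores are comparable.

**Selection and honesty.** Selection and reporting share the same pooled
CV — no nesting — mirroring the procedure being emulated; the winner's
pooled C is therefore optimistically biased as an estimate of
generalisation (it is a maximum over the search). This is a deliberate
fidelity choice, stated rather than hidden; `search(..., nested=True)`
provides the honest alternative, selecting the pair inside each outer
training fold and reporting outer-fold predictions. Ties between pairs go
to the earlier pair in enumeration order, making the search fully
deterministic.

## Evaluation

**C index.** Usable pairs have unequal outcomes; concordance means the
prediction differences and outcome differences share a sign; tied
predictions on a usable pair earn 0.5. This is the standard generalisation
of AUROC to ordinal outcomes; the 0.5 tie convention is adopted because the
definition being emulated is silent on ties and this choice makes a
constant predictor score exactly 0.5. The implementation is vectorised
O(n²); tests pin it to an independent pair-enumeration oracle exactly, and
to an established survival-analysis implementation on tie-free data.

**Bootstrap.** Percentile intervals over B=1000 paired resamples of
(prediction, outcome), seeded and bit-reproducible. Resamples on which the
metric is undefined (all outcomes equal) are skipped with their count
tracked; more than 50% degenerate replicates is an error. For ΔC the same
resample indices are applied to both models — the variance-correct choice
for two models evaluated on the same subjects; "significant" means the CI
excludes zero. BCa intervals are deliberately not the default (percentile
is the simplest defensible reading of "nonparametric bootstrap").

**Calibration.** A univariate lasso (L1-penalised least squares,
coefficient 0.01) maps raw training-mode GBDT outputs to outcomes; R² and
MAE are then computed on calibrated predictions. The description this
emulates conflates square-loss regularisation with the lasso acronym; the
package implements the named method (L1) and exposes λ, with λ=0 falling
back to ordinary least squares. The closed-form soft-threshold solution
serves as the test oracle.

## Attribution

Shapley values under the tree-conditional (path-dependent) expectation
convention: the value of a coalition is the tree output with coalition
features fixed at the subject's values and the remaining splits averaged
with training cover weights. Two routes exist behind one surface:
LightGBM's native contribution output for fitted boosters, and a
pure-Python implementation of the polynomial-time path algorithm for
neutral, hand-built tree ensembles. The two agree to machine precision on
converted models, and both match brute-force coalition enumeration on small
ensembles; local accuracy (base value + attributions = prediction) holds
per subject by construction and is asserted per model in tests.

Aggregation uses the mean **absolute** attribution per feature, normalised
to percent of the total. Signed means can cancel to zero, which would make
positive percent contributions meaningless — the absolute convention is the
only reading consistent with reporting every feature's share as a positive
percentage. Attributions are computed by the fold-specific models on their
own validation folds and pooled (matching the pooled-prediction
philosophy); the pooled base value is the subject-weighted mean of per-fold
base values, so exact local accuracy holds per fold rather than for the
pooled matrix as a whole. A `refit=True` alternative attributes all
subjects with a single model fitted on everyone.

## Pipeline and reporting

A YAML config with a mandatory global seed drives the full run: simulate
(or load CSV scores + CSV/EDF recordings) → exclusions → band powers →
per-symptom search in each input mode → evaluation and ΔC → importance →
per-patient explanation → markdown summary. Every artifact a report quotes
is serialised first; the manifest stores SHA-256 hashes, and no timestamps
enter any output, so identical config + seed reproduces every file byte for
byte. Stage failures abort with a stage-tagged error before later stages
run. The none/low/medium/high improvement buckets in patient explanations
are a communication device only; edges default to within-cohort quartiles
of the predicted improvement and are configurable.

## Problem sizes used in validation

Simulation studies in the test suite and acceptance script use: n=500
subjects × 20 seeds (bandpower mode) for planted-effect recovery, n=300 for
permutation-null calibration, n=40–60 with 8–12 s recordings for end-to-end
waveform smoke runs, and 120 s single-site recordings for spectral
contracts. These sizes were chosen to make many-replicate studies
convenient on a single CPU while keeping every statistical check at the
cohort scale the method targets (hundreds of subjects).

## Known limitations

- The synthetic EEG lacks 1/f background, artifacts and nonstationarity;
  spectral results transfer to real recordings only after artifact
  handling, which is out of scope.
- The pooled-CV search reports optimistic C indices by design (see above);
  use `nested=True` for honest estimates.
- Improvements are modelled per item with independent noise; real
  HRSD items are correlated beyond what the shared-baseline structure
  induces.
- EDF export is not supported (reading is, via the optional mne extra);
  the CSV matrix dialect is the native interchange format.
- Attribution percentages depend on the feature set searched; they are
  shares of a model's attention, not causal effect sizes.
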