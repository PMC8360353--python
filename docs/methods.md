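# Methods

## The problem

In sickle-cell disease (SCD), transient surges of sympathetic activity
during sleep — accompanying arousals, apneas and limb movements — cause
episodes of peripheral vasoconstriction. Each episode reduces microvascular
blood flow, prolonging capillary transit of sickled erythrocytes and
raising the odds of a vaso-occlusive crisis (VOC), the painful hallmark of
the disease. The magnitude of these nocturnal vasoconstriction episodes,
read from the finger photoplethysmogram (PPG), is associated with the rate
of *future* hospitalization-requiring pain crises. `vocrisk` implements a
complete pipeline for exploiting that association: it conditions overnight
beat-to-beat PPG-amplitude (PPGa) and R-to-R-interval (RRI) series, detects
and quantifies vasoconstriction episodes, assembles a 20-entry per-subject
feature vector, and trains a two-level stacking classifier to predict the
dichotomized annual pain rate (high ≥ 1.5 episodes/year vs low < 1.5).

Because the sleep database this analysis design targets is not publicly
deposited, the package ships a synthetic cohort generator that reproduces
the *structure* of such a cohort, so every stage is testable end to end.

## Signal conditioning

Input is a per-beat record: beat times (s), RRI (s), and PPGa (pulse
peak-to-trough amplitude, arbitrary units). The chain is:

1. **Ectopic interpolation.** Beats whose RRI deviates from the all-night
   mean by more than 3.5 SD are replaced by linear interpolation between
   neighboring normal beats. Mean and SD are computed once on the raw
   series; no iterative re-estimation (a single stated criterion, applied
   once, is reproducible and avoids convergence questions). A zero-SD
   (constant) series is a no-op.
2. **Uniform resampling at 2 Hz.** The per-beat value is expanded by
   zero-order hold and each 0.5-s output sample is the time-average of the
   held signal over its window (interval-weighted averaging in the style
   of Berger's heart-rate resampler). Implemented through the cumulative
   integral of the step function, so window averages are exact.
3. **Artifact masking.** Corrupted stretches are masked out, never
   deleted: masked samples are excluded from percentiles, window
   statistics and event detection, and the remaining masked-in time is the
   *effective sleep duration* feature.
4. **PPGa normalization.** Valid PPGa samples are divided by their 95th
   percentile over the night (linear interpolation between order
   statistics — the convention must be fixed for bit-reproducibility).
   "Night" means first-to-last valid sample unless an explicit sleep
   interval is supplied.
5. **Low-pass filtering.** A 4th-order Butterworth at 0.18 Hz applied
   forward-backward (zero phase, so event onsets are not shifted). DC gain
   is exactly 1; the effective (squared-response) attenuation at 0.3 Hz is
   ≈ 36 dB, comfortably suppressing respiratory-band fluctuations at
   ~0.25 Hz. The family/order is the package's choice; only the cutoff is
   externally specified.

## Event detection and quantification

A vasoconstriction episode is a transient drop of normalized, filtered
PPGa below its local baseline. The detector (thresholds are exposed
configuration, to be treated as tunable hyper-parameters):

- **Baseline:** mean of the preceding 30 s, which must be fully valid and
  flat (coefficient of variation ≤ 5%). Candidates without such a baseline
  are rejected — this is the documented mechanism by which repetitive,
  closely spaced vasoconstrictions are missed, and it is reproduced
  deliberately. A candidate onset within 30 s of the previous event's end
  is suppressed for the same reason.
- **Onset:** first sample below (1 − d_min) × baseline that stays below
  for ≥ t_min (defaults d_min = 10%, t_min = 10 s), refined by walking
  back to the first sample exceeding a 2% drop.
- **End:** recovery to within 5% of baseline, or 150 s after onset,
  whichever comes first (the vast majority of episodes end well before
  150 s).
- Events are non-overlapping, ordered, never straddle masked samples, and
  events within 30 s of a masked interval are discarded (baseline
  integrity).

Around each onset a fixed **180-s segment** is cut: 30 s pre-onset +
150 s post-onset at 2 Hz = 360 samples per channel, onset at sample 60,
720 values over the two channels. Events without full context are skipped
with the miss logged, not raised.

Per-event metrics (trapezoidal integration at 2 Hz, baselines = mean of
the 30 pre-onset seconds per channel):

- `T_vasoc` — onset-to-end duration (s);
- `A_vasoc` — integral of the percent drop of PPGa below baseline over the
  event (percent·s); excursions above baseline contribute zero;
- `M_vasoc = A_vasoc / T_vasoc` — average percent drop, held as an exact
  identity by construction; percent-of-baseline units were chosen because
  the average percent change from baseline is the quantity's defining
  interpretation;
- `A_RRI−`, `A_RRI+` — areas of RRI below/above its baseline (s·s),
  i.e. cumulative heart-rate increase/decrease during the episode.

Per subject, the pipeline reports the medians of `M_vasoc`, `A_RRI−`,
`A_RRI+` over all detected events plus the event count `N_vasoc`. An
event-free night yields NaN medians that are imputed later, *inside*
cross-validation folds (training-fold median), never globally — global
imputation would leak test-fold information.

## Features and screening

The model input is a fixed 20-entry vector: 10 clinical/subject covariates
(age, sex, hemoglobin, white-cell / reticulocyte / neutrophil counts,
diastolic and systolic blood pressure, BMI, hydroxyurea use), 4 sleep
indices (arousal index, apnea–hypopnea index, limb movements, effective
sleep duration), the median of 5-min RRI means, the median of 5-min PPGa
coefficients of variation, and the 4 vasoconstriction descriptors.
Windowed statistics use consecutive non-overlapping 5-min windows,
dropping windows more than half masked.

The screening procedure that reduces a 44-candidate pool (the 20 retained
features plus documented decoys/alternates in the same five groups) ranks
candidates within each group by the absolute rank-biserial association
with the binary pain category (derived from the Mann-Whitney U statistic)
and accepts them greedily, rejecting candidates whose |Spearman ρ| with an
already-accepted same-group feature exceeds 0.7. Selection stops at
per-group quotas matching the published feature-type counts (10/4/1/1/4);
if redundancy rejections leave a quota unfilled it is topped up from the
deferred candidates. The association statistic, the 0.7 cutoff and the
quota rule are this package's resolutions of a procedure whose original
details are not public; they are configuration, not claims.

## The two-level stacking model

**Level 1 — seven base learners:** logistic regression, linear-kernel SVM,
RBF-kernel SVM, random forest, extremely randomized trees, AdaBoost (all
scikit-learn, library defaults plus fixed seeds), and a 1-D CNN over the
raw (2 × 360) segments. Four further algorithms (polynomial-kernel SVM,
gradient boosting, XGBoost, stand-alone MLP) are available for base-model
comparison but are not part of the stack — the first three because that
model family underperforms in this setting, the MLP because it is promoted
to the meta level. Distance/gradient-based learners receive standardized
features (training-fold mean/SD); tree ensembles receive raw values.

**CNN:** two convolution blocks (8 then 16 filters, kernel 7, stride 1,
ReLU, max-pool 4), global average pooling, a dense-16 ReLU layer and a
sigmoid output; per-channel standardization from training statistics;
class-weighted cross-entropy, Adam (lr 5 × 10⁻³, batch 128), early
stopping on a stratified 20% split (patience 3, minimum 6 epochs, at most
15), training sets subsampled to ≤ 1,000 segments. Every segment carries
its subject's label; subject-level calls are the mean segment score
thresholded at 0.5, with zero-segment subjects receiving the training
fold's majority category. The filter counts are deliberately small: at
roughly 1–2 thousand segments per cohort a larger net only slows the
20-trial evaluation without adding capacity the data can use.

**Level 2 — MLP meta model:** one hidden layer of 32 ReLU units, dropout
0.2, sigmoid output, class-weighted cross-entropy, Adam (lr 10⁻², batch
32), a fixed 150 epochs. Early stopping is not used here: a 20% validation
split of a ~160-subject training fold contains only a handful of positive
subjects, and model selection against such a split is noise (it
occasionally freezes near-initialization weights); dropout plus a fixed
epoch budget regularizes more predictably at this scale.

Both neural models run on a small numpy backend written for this package
(im2col convolution, pooling, dense, dropout, Adam, weighted
binary cross-entropy); its gradients are verified against finite
differences in the test suite.

The meta model's inputs depend on the variant: **A** 20 features + 7 base
calls (27), **B** base calls only (7), **C** features only (20; with no
level 1 this *is* the stand-alone MLP), **D** as A with median `M_vasoc`
removed everywhere (26), **E** as A but labeled with the pre-study pain
category. Base outputs are passed as hard 0/1 calls (a flag enables
probabilities); all sigmoid outputs threshold at 0.5 with ties going to
high pain (favoring recall, the clinically costlier error being a missed
high-pain child). Class imbalance is handled everywhere by
inverse-frequency positive-class weights (176/36 ≈ 4.9 at the default
imbalance).

## Cross-validation and evaluation

Stratified 4-fold CV: subjects are shuffled within class under a seed and
dealt round-robin, so a 212-subject cohort with 36 positives yields four
folds of 53 subjects with exactly 9 high / 44 low each; a rotating
remainder keeps fold sizes within one of each other in the general case.
Level 1 is cross-validated under seed α (shared by all base models),
producing out-of-fold base calls for every subject, re-ordered to the
original roster order; level 2 is cross-validated under an independent
seed β on the variant's inputs. All fold-internal preprocessing
(standardization, imputation) is fitted on training folds only. Pooled
out-of-fold predictions — each subject predicted exactly once — are scored
as TP/FN/FP/TN with precision, recall, specificity, accuracy and
F1 = 2·precision·recall/(precision + recall); precision is defined as 0
when no positives are predicted. The trial is repeated 20 times with
(αᵢ, βᵢ) = (master + 2i, master + 2i + 1); the reported performance is the
mean F1, with a t-distribution 95% interval over trials (the interval
method is the package's choice). Both fold shuffles and model-internal
seeds re-randomize across trials.

**Random-model benchmark.** A coin calling "high pain" with probability p
has expected confusion matrix TP = n₊p, FN = n₊(1−p), FP = n₋p,
TN = n₋(1−p), hence precision n₊/(n₊+n₋) (for p > 0), recall p, and a
closed-form F1(p) that is non-decreasing and maximal at p = 1, where
F1 = 2n₊/(2n₊+n₋) — 0.2903 for 36:176. That value is the floor any model
must beat. (At p = n₊/n = 36/212 the formulas give F1 ≈ 0.1698; a published
figure of 0.1667 for this case disagrees with its own defining formulas,
and this implementation follows the formulas.) ROC/AUC are deliberately
not reported: category outputs from repeatedly retrained models have no
stable score axis, and curve metrics flatter imbalanced data.

## The synthetic cohort generator

The generator's defaults define the study conditions: 212 subjects with
latent high-severity prevalence 36/212, 8-hour nights, and per-class event
statistics — event rates 1.5/h (low) vs 2.5/h (high), mean planted depths
13% vs 27% of baseline PPGa (the depth means follow the published
exemplar subjects; the rates are realistic stand-ins fixed once). Each
event is a raised-cosine onset (10 s) / plateau / recovery (20 s)
transient in PPGa with a coupled negative RRI excursion (fractional RRI
drop = 0.4 × coupling × fractional PPGa drop) and a small positive
rebound afterwards (producing `A_RRI+`). Signals ride on baseline plus a
0.25-Hz respiratory oscillation at 5% amplitude (above the 0.18-Hz cutoff,
so the filter has real work), 2% multiplicative white noise, a slow
autonomic RRI drift, and beat-to-beat RRI jitter; ~2% of each night is
masked as artifact. Beat times are the running sum of the RRI sequence,
computed with two fixed-point passes so PPGa and RRI excursions stay
aligned.

Pain histories are negative-binomial counts (dispersion k = 2) over 2
pre-study and 3 post-study years with expected annual rate
log λ = −2.85 + 0.12 × median planted depth + 0.33 × events/hour — the
simplest monotone link that plants the severity → pain-rate association;
the intercept was calibrated so the expected number of realized high-pain
subjects matches the 36:212 imbalance. Clinical and sleep covariates are
drawn from plausible pediatric-SCD ranges, class-independent except
hemoglobin (lower mean under high severity), plus deliberately
uninformative decoys; the ranges are stand-ins, not estimates of any real
joint distribution. The latent class is logged for recovery tests only and
is never a model input.

**What passing tests do and do not show.** The generator plants a clean,
monotone association, stationary baselines, and a single event morphology;
real nights have drifting gains, apnea clusters, movement artifacts and
far noisier coupling. Tests on this cohort demonstrate that the machinery
is correct and can recover a planted association of realistic size — not
that any particular F1 is attainable on real polysomnograms.

## Numerical choices and degenerate inputs

- Percentiles: linear interpolation between order statistics everywhere.
- Trapezoidal integration at the 2-Hz grid for all event areas.
- Constant-RRI series: zero SD disables ectopic rejection (no-op).
- All-ectopic nights, empty beat lists, non-positive normalization
  references and sub-warm-up filter inputs raise typed processing errors.
- Zero-denominator metric conventions: precision 0 with no predicted
  positives; recall 0 with no true positives (unreachable under
  stratified folds).
- Ties at a 0.5 sigmoid score resolve to high pain.
- Every random draw flows from explicit integer seeds; two runs with the
  same seeds are bit-identical end to end.

## Problem sizes

Default test/evaluation sizes were chosen to keep the full suite and the
acceptance script desk-scale on one CPU: the pipeline-recovery experiment
uses the full default cohort (212 subjects, ≈ 1,700 segments) with 20
trials plus a 10-trial label-permuted control; detector validation uses 10
noise-free nights (≈ 80 planted events); the bit-reproducibility check
uses a 40-subject cohort, the smallest that guarantees ≥ 4 subjects per
class for 4-fold stratification at the default prevalence.

## Known limitations

- The vasoconstriction detector is a re-specification from its published
  description's observable behavior, not a replication of the original
  algorithm's internals; its thresholds are honest hyper-parameters.
- Segment→subject aggregation for the CNN (mean score) is this package's
  choice; the original aggregation is not described.
- The 44-candidate pool reproduces the published group structure and
  retained features, not the original candidate list.
- Raw-waveform processing (R-peak detection, pulse delineation, EDF
  parsing) is out of scope; inputs are beat-level tables.
- Real-data F1 values cannot be reproduced without the original cohort;
  the package's quantitative claims are about synthetic recovery and the
  analytic benchmark only.
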