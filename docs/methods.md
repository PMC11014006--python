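# Methods

This note records the models, algorithms and design choices behind
`hfwave`, in the spirit of a methods appendix: what is computed, under what
assumptions, and which decisions were genuinely open.

## Synthetic waveform model

**RR series.** Beat-to-beat intervals are `RR_t = 60000/HR + x_t` (ms) with
`x_t` a stationary AR(1) Gaussian process. The AR coefficient is chosen so
the distribution of successive differences hits the requested pNN50: for
marginal sd σ (= SDNN) the differences have sd `σ·sqrt(2(1−φ))`, and the
fraction exceeding 50 ms is `2Φ(−50/sd_diff)`; inverting gives φ, clipped
to (−1, 1) when the target is unreachable at that SDNN. The realized path
is affinely standardized so its sample mean is exactly the target mean RR
and its sample sd exactly the SDNN target — the generator's contract is on
realized statistics, not asymptotic ones, which makes downstream recovery
checks sharp. Edge cases: SDNN = 0 yields a metronomic series; the series
is truncated (and, against float round-up, minutely rescaled) so cumulative
beat times never exceed the record duration; a 250 ms physiological floor
guards absurd draws.

**ECG.** Each beat is a sum of raised-cosine (Hann) lobes: a P wave of
configurable duration/amplitude centered 160 ms before R, a QRS lobe whose
*total width* is the QRS-duration parameter, and a T wave (width 0.18 s,
amplitude 0.3) centered 280 ms after R. Hann lobes were chosen over
Gaussians because their support is finite, so "QRS duration" has an exact
meaning and every fiducial is analytically known. At heart rates above
~105 bpm the T wave of one beat begins to overlap the next P window; P
measurements there are mildly biased, which is accepted as realistic.

**PPG.** Each cycle rides on a diastolic baseline: a primary systolic lobe
(amplitude = pulse amplitude) peaking at 20% of the beat period after the
foot with width 40% of the period, plus a reflected lobe scaled by the
augmentation fraction peaking at 55%. The lobes barely overlap, so the
per-beat maximum equals diastolic + pulse amplitude and the true
augmentation index equals the augmentation fraction by construction.
Timings scale with the beat period rather than being fixed in seconds;
this keeps morphology valid across the 50–120 bpm range at the cost of a
reflected-wave delay that is not strictly constant in absolute time.

**Noise.** Three additive seeded components: a mains sinusoid at 50 or
60 Hz with random phase; baseline wander as two sinusoids with random
frequencies in 0.05–0.45 Hz; white Gaussian high-frequency noise. Defaults
(0.05, 0.10, 0.02 signal units against a unit R wave) are moderate
bedside-monitor levels. Not modeled: respiratory amplitude modulation,
motion artifacts with spectral overlap on the signal band, ectopic beats,
12-lead geometry. Passing tests on this generator therefore demonstrate
correctness of the pipeline's logic and its noise rejection for stationary
contamination — not robustness to every artifact class real recordings
contain.

**Cohort draws.** Controls draw parameters inside normal adult ranges
(HR 75 ± 10 bpm, SDNN 65 ± 18 ms, pNN50 10 ± 5%, QRS 95 ± 10 ms, pulse
amplitude 1.0 ± 0.18, augmentation 0.32 ± 0.10); heart-failure subjects
are shifted by roughly 1.5 within-class sd per feature (HR 85 ± 12,
SDNN 40 ± 14, pNN50 3 ± 2.5%, QRS 120 ± 15 ms, pulse amplitude
0.72 ± 0.18, augmentation 0.50 ± 0.12), all clipped to physiological
bands. The shifts are distributional, not deterministic offsets: classes
overlap, single-feature classification is imperfect, and integrating
modalities has something to add. An early draft separated the classes so
strongly that every classifier saturated; the spreads above were widened
once to restore a non-trivial regime and then frozen.

## Preprocessing

All filters are 4th-order Butterworth (2nd-order for the notch biquad)
applied forward–backward, so group delay is zero and fiducial timing is
preserved (verified: R-peak shift ≤ 1 sample). Baseline wander is removed
with a 0.5 Hz high-pass. The source description of this step names a
"150 Hz high-pass" for baseline removal, which is unrealizable at a 125 Hz
sampling rate (above Nyquist) and contradicts the step's stated purpose;
whether it was a typo for 1.50 Hz or a low-pass on a higher-rate source is
undeterminable, so the default implements the stated *intent* (0.5 Hz
high-pass) and both cutoffs are configuration. A 40 Hz low-pass for muscle
noise is on by default in the standard chain and skippable.

Screening: fragments of ≤ 30,000 samples are rejected (`too_short`; at
125 Hz the threshold is exactly 4 minutes); any ≥ 5 s window with sample
range below ε (default 1e−4) is `sensor_off`; a beat-to-beat gap over 3 s
(including record edges) is `missing_peaks`. Pulsus-bisferiens-like double
peaks are handled structurally instead of by exclusion: the PPG detector's
period-scaled refractory prevents double-counting, so such records yield
features rather than being dropped — a deliberate divergence recorded
here because no detector was specified for that exclusion.

## Feature extraction

**R peaks.** Pan–Tompkins-style energy detection: band-pass 5–15 Hz (where
QRS energy lives, P/T energy does not), square, integrate over 150 ms,
pick bursts ≥ 20% of the 99th-percentile energy with a 200 ms refractory,
then refine each R to the waveform maximum within ±100 ms.

**Delineation.** QRS and P boundaries use half-amplitude width doubling:
locate the half-height crossings flanking the peak (sub-sample, linearly
interpolated) and set onset/offset at twice the half-height width about
its midpoint. For unimodal smooth lobes FWHM is half the total width, so
the estimator is exact on the generator and, because the half-height slope
is steep, far more noise-tolerant than near-baseline thresholding. The P
wave is the largest local maximum within 250 ms before QRS onset; below 4%
of the R amplitude it is marked absent (NaN), keeping per-beat arrays
aligned.

**HRV.** SDNN uses the sample (n−1) standard deviation (dominant
convention in HRV tooling; switchable via `ddof`). pNN50's denominator is
the number of successive differences (n−1 for n intervals). Ectopic
rejection (drop intervals > 250 ms from their 5-point local median) exists
but is off by default, so RR = NN on clean data. Risk stratification:
SDNN < 50 ms *or* pNN50 < 3% → high; else SDNN ≤ 100 ms → moderate; else
normal. The verbal rule is internally conflicting when pNN50 > 3% but
SDNN sits in 50–100; the SDNN band decides, since SDNN is the primary
stratifier in that band.

**PPG.** The beat period is first estimated from the autocorrelation peak
in 0.33–2 s; systolic peaks must be ≥ half a period apart, which stops a
prominent reflected (dicrotic) wave from being counted as a beat. The foot
is the *last* minimum between peaks (end of the diastolic run), the
derivative peak the steepest upstroke sample. "Systolic/diastolic
pressure" are uncalibrated waveform levels in arbitrary units, not mmHg —
the PPG carries no pressure calibration, and the unit tag says so. Both a
peak-to-peak *interval* and a peak-to-peak *amplitude* are computed as
distinct features. The augmentation index is the standard reflected/
systolic amplitude ratio above the foot (emitted as a fraction; ×100 for
percent display), searched from a quarter-period past the systolic peak to
the next foot, with a window-maximum fallback when no local maximum
exists; beats whose detected period deviates more than 40% from the record
median are excluded from the average, since those are missed-beat gaps in
which the next systolic peak would masquerade as a reflection. A stiffness
proxy (systolic-to-reflected delay in seconds) is computed but flagged
experimental and excluded from the 13-feature set, which comprises 8 ECG
features (heart rate, RR interval, QRS interval, P-wave duration, SDNN,
RMSSD, NN50, pNN50) and 5 PPG features (systolic level, diastolic level,
pulse pressure, peak-to-peak interval, augmentation index). Per-record
scalars are means over beats.

## Normalization and selection

Min–max normalization is fit on the entire matrix by default — faithful to
the emulated design, which scales before splitting; a leakage-safe mode
(fit on training rows, transform and clip held-out rows) is available via
`FeatureMatrix.transform_rows`. Constant columns map to 0 with a warning.
Re-normalizing is a state error rather than a silent no-op.

ReliefF uses k = 10 neighbors per class (common default; not specified in
the source design), Manhattan distance (matching the accumulated diff
function), and samples all instances, making weights deterministic;
subsampling is seeded. Weight updates follow the standard
prior-reweighted hit/miss rule; correctness is pinned by exact equivalence
(atol 1e−12) to an independent brute-force transcription across 100 random
problems. Selection keeps the top 4 PPG, 6 ECG and 10 integrated features
by weight (ties broken by column order, logged); ranking by |weight| is
available. The source narrative lists eleven feature names for its
ten-feature integrated set; the implementation selects exactly ten by
weight and logs the ranking rather than hard-coding an ambiguous list.

## Classification and metrics

Stratified 75/25 partition with largest-remainder per-class apportionment
(1636 rows → exactly 1227/409). Cross-validation folds are dealt
round-robin over a class-interleaved shuffle, so fold sizes differ by at
most one row and class proportions stay near-equal; `folds == n`
(leave-one-out) is allowed as a degenerate case. The nine families map to
scikit-learn estimators with library defaults (RBF-kernel SVC,
100-tree Random Forest, 5-NN, random-split tree with √p features,
AdaBoost, CART, Gaussian NB, one-hidden-layer-50 MLP capped at 300
iterations); "BayesNet" is an in-repo tree-augmented naive Bayes — Chow–Liu
maximum-spanning tree over class-conditional mutual information on
10-quantile-bin discretized features with Laplace smoothing — the closest
standard analog to the original toolkit's Bayesian-network learner.
Hyperparameter search is deliberately out of scope. Scores for AUC are the
decision function where a family has one, else the positive-class
probability; AUC itself is the tie-corrected Mann–Whitney statistic,
verified against exhaustive pair enumeration. Ratios with zero
denominators are reported as NaN, never silently as 0. The positive class
is heart failure throughout.

## Problem sizes and determinism

Every stochastic step (cohort draws, noise, subsampling, splits, folds,
model seeds) flows from explicit integer seeds; identical seeds give
byte-identical cohorts and reports. The packaged study runs 600 s records
at 125 Hz; the full comparison uses the 682 + 954 cohort, and the examples
use scaled-down cohorts (~150–300 subjects, 300 s) chosen to finish in
about a minute while staying in the same qualitative regime. The
cross-validation machinery is exercised at small n in the test suite,
while the headline integrated-vs-single comparison is evaluated on the
held-out 25% split.

## Known limitations

* The generator's morphology is schematic: no respiratory modulation, no
  arrhythmic ectopy, no pulse-transit-time coupling between channels
  (both channels share beat times exactly).
* PPG "pressure" features are arbitrary-unit levels; any mmHg
  interpretation requires a calibration this pipeline does not model.
* P-wave measurements degrade above ~105 bpm (T–P overlap) and under
  heavy noise; they are marked missing rather than imputed where
  undetectable.
* The high-augmentation + low-amplitude corner (augmentation fraction
  ≳ 0.9) approaches the detector's refractory assumptions; cohort draws
  cap augmentation at 0.92.
* Classifier comparisons on synthetic cohorts demonstrate the pipeline's
  mechanics and the value of integrating modalities under this generative
  model; they say nothing about absolute performance on clinical data.
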