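# Methods

## Overview

`gaitmse` classifies walkers from vertical gait-force (GF) recordings of the
two feet. The pipeline is:

1. **Preprocessing.** Drop the first 20 s of each ~5-min recording (the
   initial interval is not steady gait) and cap at 300 s, leaving 280 s.
   Form the averaged-foot channel AF = (LF + RF)/2, then first differences
   (LF1, RF1, AF1) and second differences (LF2, RF2, AF2), giving nine
   channels. Segment all nine into fixed windows (10/20/30/60 s) with 50%
   overlap, screen for artifacts, and normalize each window's channels.
2. **Features.** Per channel and window: mean, population standard
   deviation, and sample entropy of the coarse-grained series at scales
   s = 1..6 — eight features × nine channels = 72 (F1..F72, where
   F(8·(i−1)+1) is the mean of channel i, F(8·(i−1)+2) its SD, and
   F(8·(i−1)+2+s) its scale-s entropy).
3. **Class balancing (optional).** SMOTE oversampling of minority classes.
4. **Feature selection (optional).** Greedy sequential forward/backward
   search with a cross-validated wrapper criterion.
5. **Classification.** 1-NN with the weighted absolute-difference distance
   d(q,x) = Σ_f w_f |q_f − x_f|, or an SVM (delegated to a standard
   maximum-margin solver, one-vs-one for multi-class), under stratified
   10-fold cross-validation.

## Window-count arithmetic

For a group of T subjects with l seconds of retained signal, window length
TW and step d, the cohort window total is n = floor(((l − TW)/d + 1) · T),
evaluated in exact rational arithmetic (a float evaluation of the PD 60-s
cell yields 124 instead of the exact 125). When (l − TW)/d is fractional
the closed form truncates only at the cohort total; a physical segmentation
necessarily emits floor((l − TW)/d + 1) windows per subject, so the two can
differ by up to T − 1 windows. Both quantities are exposed and the tests
pin down exactly when they coincide.

Differentiation happens on the full series before windowing, so the D1/D2
channels are one and two samples shorter than the raw channels. Windows are
placed over the raw-channel length; in the final window the missing 1–2
trailing difference samples are edge-padded, keeping all nine segments
index-aligned at the full window length and the emitted count equal to the
closed form for integral cases.

## Sample entropy and its multiscale extension

SampEn(m, r) = −ln(A/B), where B counts ordered pairs (i ≠ j) of m-length
templates whose Chebyshev distance is ≤ r and A the same for (m+1)-length
templates; both counts run over the first N − m template start points and
exclude self-matches. Defaults m = 3, r = 0.2. Conventions deliberately
fixed here (the common Richman–Moorman choices):

- **Distance**: Chebyshev (max-norm).
- **Tolerance**: r is a fraction of the *scale-1* window's population SD
  and the absolute tolerance is held fixed across scales. Because windows
  are z-scored per channel by default, the absolute tolerance is simply r.
- **Degenerate cases**: if B = 0 (no template pair matches) or A = 0 the
  entropy is undefined/unbounded; the feature is recorded as NaN and later
  imputed with the training-fold column median (counts are logged). A
  constant window is defined as entropy 0 at every scale (a constant
  extends every match), which also covers windows zeroed by degenerate
  normalization.
- **Coarse-graining**: scale s replaces consecutive non-overlapping blocks
  of s samples by their mean, dropping a trailing remainder; scale 1 is the
  identity. Scales default to 1..6.

The production implementation is a compiled single-pass pair count (B and A
accumulated together with early exit); the test suite checks it to 1e-12
against a naive O(N²) double-loop oracle over random series and against
closed-form degenerate cases.

## Normalization

Both min-max ([0, 1]) and z-score (mean 0, population SD 1) window
normalizations are provided; z-score is the default, which makes the
entropy tolerance exactly r and renders the per-window mean/SD features
constant (0 and 1). Constant segments degenerate to all-zeros with a logged
warning. Min-max is selectable when the mean/SD features should stay
informative.

## Artifact screening

Visual screening is replaced by three automated rules on the raw channels —
flatline (rolling population SD below 1e-6 over any 2-s run), clipping
(≥ 1% of samples exactly at the segment extremes), dropout (any non-finite
value) — plus an optional explicit (subject, window) exclusion list for
manual review. Thresholds are configurable; the defaults are deliberately
conservative so clean synthetic windows pass.

## SMOTE

A synthetic minority row is x + u·(x_k − x) with u ~ U(0,1), x a minority
row and x_k one of its k = 5 nearest minority neighbors by Euclidean
distance — i.e. a point on the segment between two real rows, hence always
inside the minority class's componentwise envelope. Balancing targets the
majority-class count by default. SMOTE is applied inside each training fold
by default (validation folds never contain synthetic rows); a `global` mode
that balances before splitting exists for comparability with
augment-then-validate protocols, at the documented cost of optimistic bias.

## Sequential selection

SFS grows from the empty set, SBS shrinks from the full set; each step
takes the single add/removal that maximizes the criterion, with ties broken
toward the lowest feature index (deterministic). The criterion is the mean
stratified k-fold (default 3) CV accuracy of the configured classifier on
the training data only. Stopping is either at a requested subset size p or
at the first step with no improvement. Like SMOTE, selection runs inside
each outer training fold by default, with a `global` fidelity mode.

## Cross-validation and leakage

Two grouping modes are first-class:

- `window_level` (default): stratified folds over windows. Overlapping
  windows of one subject can span the train/validation split, so a
  nearest-neighbor classifier can match a validation window to its
  overlapping neighbor — accuracies are optimistic. This is the common
  protocol for this pipeline family and reproduces its characteristic
  near-ceiling numbers.
- `subject_level`: stratified group folds keeping every subject's windows
  on one side of each split — the recommended protocol for claims about
  unseen walkers.

The test suite asserts the ordering (window-level ≥ subject-level on
overlapping-window synthetic data) as a documented phenomenon, not a
virtue. Headline accuracy is reported both pooled (trace of the confusion
matrix over total) and as the mean of per-fold accuracies.

## Synthetic gait generator

The generator imitates the *morphology* of force-sensitive-resistor gait
recordings, not disease physiology; class names are arbitrary labels. Each
foot is a train of stance pulses: two overlapping raised-cosine lobes
(heel-strike, then toe-off at 0.9 relative height) spanning 62% of the
stride period, swing near zero, right foot anti-phased by half a period.
Successive stride periods are drawn with configurable mean (1.1 s) and
coefficient of variation — the class-separating knob — and stride
amplitudes with 5% CV. Peak force is coupled to instantaneous cadence
(amplitude × (P̄/P)^1, the impulse–momentum relation: a faster stride loads
harder), so timing variability also expresses itself as loading
variability; lobes are sharpened (exponent 2) to reflect the steep rise of
real heel-strike/toe-off force edges. Additive white noise has SD 0.005 of
peak force (a clean sensor/ADC floor; at larger noise the difference
channels D1/D2, whose per-sample signal increments are small, become
noise-dominated and carry little class information). Per-subject
parameters are jittered by 5% of class means.

Mechanism: with higher stride-period CV, cross-stride template matches fail
more often, so multiscale entropy of the per-foot envelope channels rises
(measured ≈ 0.052 → 0.054 mean profile per foot from CV 0.02 → 0.30 under
default settings, and the differential channels add further separation).
The averaged-foot channel is an exception: its waveform is also driven by
the slowly drifting relative phase of the two feet, which makes its
entropy non-monotone in period CV (≈ 0.23 at CV 0.02 vs ≈ 0.15 at 0.30);
the trend test therefore asserts the per-foot channels only. What passing
the synthetic end-to-end tests shows is that the pipeline recovers a
stride-timing-variability difference from raw force traces; it does not
show clinical validity on real recordings, which differ in waveform
detail, artifact structure and between-subject heterogeneity.

## Problem sizes used by the test suite

End-to-end checks use 300 Hz, 5-min records (the generator defaults):
a recovery cohort of 2 × 8 subjects whose classes differ only in
stride-period CV (0.02 vs 0.20), featurized at the 10-s window (55 windows
per subject), reaching ≈ 92% window-level mean 10-fold CV accuracy with
1-NN on all 72 features across several seeds; and a null cohort (identical
class parameters, 2 × 10 subjects, 150-s records) whose subject-level CV
must be statistically indistinguishable from chance. The null test uses
per-subject majority votes as the binomial unit: windows of one subject are
strongly correlated (50% overlap, shared subject parameters), and a
window-unit binomial test was measured to reject a true null at p < 0.01 —
the subject is the exchangeable unit.

## Known limitations

- The synthetic waveform is smooth and stereotyped; real GF recordings
  contain impact transients, sensor drift, and turning artifacts that the
  automated screening rules only approximate.
- With z-score normalization the 18 mean/SD features are constants by
  construction; they are retained for layout fidelity and become
  informative under min-max normalization.
- The SVM is a delegated standard solver; only its settings (kernel RBF by
  default, C, gamma, one-vs-one) are exposed.
- MSE at coarse scales on 10-s windows rests on few samples (500 at scale
  6) and is a noisy estimate; this is inherent to the windowing choices,
  not to the implementation.
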