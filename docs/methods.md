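# Methods

This note documents the models and procedures implemented in `painpipe`,
the parameter choices that matter, what the synthetic cohort generator
does and does not emulate, and the numerical decisions taken where the
design was genuinely open.

## Signals and preprocessing

Inputs are per-subject multichannel time series: ECG (1 channel) and
facial EMG (5 channels) at 500 Hz, EDA at 4 Hz and PPG at 64 Hz
(wristband defaults, configurable), plus sparse timestamped NRS
self-reports (integers 0–10) and designated baseline (rest) spans.

All IIR filters are Butterworth designs applied zero-phase
(forward–backward), because downstream features are morphology- and
timing-based and must not be phase-shifted. Filter order defaults to 4
and the notch quality factor to 30 (both configurable); neither is
dictated by the problem, they are conventional stable choices.

- **ECG**: band-pass 0.1 Hz – min(250, 0.45·fs) Hz. A nominal 250 Hz
  upper edge coincides with the Nyquist frequency at fs = 500 Hz, so the
  edge is clamped to 0.45·fs (225 Hz) to keep the design well-posed; the
  passband intent (remove baseline wander, keep everything else) is
  preserved.
- **EMG**: 20 Hz high-pass, then notches at the 50 Hz powerline
  fundamental and its 100 Hz harmonic.
- **EDA**: 1 s centered moving average (motion artifacts), then a 1 Hz
  low-pass. The low-pass cutoff is a choice: skin-conductance responses
  have rise times ≥ 0.7 s, so 1 Hz retains all SCR structure. Smoothing
  precedes the tonic/phasic decomposition.
- **PPG**: band-pass 0.4–8 Hz — wide enough for the cardiac fundamental,
  its harmonics, and the amplitude-modulation sidebands that carry
  respiratory information — followed by a 0.25 s moving average.

## Handcrafted features

Windows are 5.5 s or 10 s, non-overlapping by default (`features.step_s`
configurable). All modalities share one window grid so windows align
across modalities for fusion. A window whose features cannot be computed
(too few R-peaks, too few respiratory cycles) carries NaN and is dropped
from the feature matrix with a logged count.

**ECG (19 HRV features).** R-peaks come from a deterministic
Pan–Tompkins-style detector (5–15 Hz band-pass → derivative → squaring →
150 ms integration → adaptive threshold at 0.25 of the 98th percentile,
200 ms refractory, apex refinement), behind a `PeakDetector` protocol so
a learned detector can be swapped in. From the NN intervals (ms) of each
window: least-squares slope, count, mean, min, max, SD; mean/min/max of
successive differences, SDSD, RMSSD, NN20/NN50 counts and pNN20/pNN50;
mean/min/max/SD of the per-interval heart rate 60000/NN. Conventions:
SDs are population SDs (ddof = 0); difference extrema are signed (an
absolute-value variant is behind a flag since toolboxes disagree);
windows with a single interval are sentinel-NaN (no difference
statistics exist), two intervals upward are computed.

**EMG (14 × 5 = 70).** Per channel: peak |x|; peak-to-peak mean,
defined — since "peak-to-peak mean" is underdetermined — as the mean of
(max−min) over 0.5 s sub-frames (configurable); RMS; mean absolute first
and second differences, raw and on the z-scored window; means of local
minima and maxima; mean |x|; variance, SD, range, IQR. Local extrema use
strict neighbor comparison; plateaus contribute their first sample; a
window with no interior extremum falls back to its max/min (hence the
constant value on constant windows).

**EDA (12).** The preprocessed signal is decomposed by convex sparse
deconvolution: phasic = nonnegative sparse driver convolved with the
Bateman impulse response exp(−t/τ1) − exp(−t/τ0) (τ0 = 0.7 s,
τ1 = 2.0 s, the published defaults of the convex-optimization EDA
model); tonic = cubic B-spline with knots every 10 s plus offset and
linear drift. The objective
½‖p⊛h + B·l + C·d − y‖² + α·1ᵀp + ½γ‖l‖² (α = 8·10⁻⁴, γ = 10⁻²)
is solved with L-BFGS-B on the bound-constrained equivalent (the L1 term
is linear for p ≥ 0). Because h ≥ 0 and p ≥ 0 the phasic component is
nonnegative, and the residual is defined as the exact remainder, so
tonic + phasic + residual reproduces the input to machine precision. If
the solver fails, a median-filter tonic with clipped residual phasic is
used and the downgrade logged. Features: number of phasic peaks
(prominence ≥ 0.01 µS), then mean, max, min, range, SD, IQR, RMS, local
extrema means, and mean absolute first/second differences of the clean
window.

**Respiration (10).** The respiration signal is derived from PPG by
empirical mode decomposition (cubic-spline sifting, Cauchy-type stopping
criterion, mirrored boundary extrema). Respiratory information lives
both in additive baseline oscillation and in amplitude modulation of the
cardiac pulse, so two candidate routes are computed: in-band
(0.1–0.5 Hz) IMFs of the filtered PPG itself, and in-band IMFs of its
Hilbert-envelope (amplitude demodulation). Whichever route yields the
stronger in-band component wins; IMFs below 10 % of the PPG's SD are
discarded as sifting artifacts (a pure unmodulated carrier therefore
raises "no respiratory component"). Features per window: inhale-peak
count (prominence ≥ 0.2 of the window range, spacing ≥ 1.5 s — scale-free
choices, configurable), mean, max, min, range, SD, inhale-peak interval
mean/SD/RMSSD, and the SD of inhale durations (preceding trough → peak).

## Automatic features

Each modality gets an unsupervised autoencoder; the latent vector is the
feature vector: 32 dimensions for ECG, EDA, respiration; 6 per EMG
channel (5 channels → 30; a single 30-latent EMG autoencoder is behind a
flag); 126 across modalities. Training: MSE reconstruction loss, Adam at
1e-3, batch size 10, 100 epochs, per-window min–max normalization to
[0, 1] (z-score behind a flag). The whole stack (dense, strided 1-D
convolutions, transposed convolutions, LSTM with full backpropagation
through time, Adam) is implemented in numpy with float64 parameters and
seeded Glorot initialization, so training is bit-reproducible; layer
gradients are verified against finite differences in the test suite.

*Convolutional variant*: linear resampling of the window to the closest
power of two (CP2), three conv layers (channels 16/32/64, kernel 3,
stride 2 — unconstrained by the problem, documented defaults), linear to
the latent; mirrored decoder. When a low-rate channel's window is
shorter than the latent budget (e.g. 40-sample EDA windows vs 32
latents), the first linear layer upsamples to the smallest power of two
that keeps latent < CP2; a latent at least as wide as the raw window is
rejected as no bottleneck. *LSTM variant*: the window is resampled to
CP2/8 steps, encoded by a 64-unit LSTM whose last hidden state projects
to the latent; the decoder repeats the latent across CP2/8 steps through
a second LSTM. This is the smallest recurrent architecture satisfying
the shape contract.

For computational reasons autoencoder inputs from channels faster than
`autoencoder.input_fs` (default 32 Hz) are linearly decimated to that
rate before encoding; handcrafted features always see the native rate.
At 32 Hz the cardiac and respiratory structure the latents need is fully
retained (beat spacing ≥ 300 ms).

Autoencoders are fit inside each training fold only — never on held-out
subjects. Whether the original protocol shared autoencoders across folds
is unknowable from the outside; the stricter leakage-free choice is
deliberate and mechanically audited.

## Labels

NRS → class: BL for 0, PL1 for 1–3, PL2 for 4–6, PL3 for 7–10
(inclusive). The literal mapping in which PL1 spans 0–3 collides with a
separate no-pain class, and the binary tasks BL-vs-PLk need disjoint
classes, so NRS 0 defaults to BL; `labels.strict_paper_ranges` restores
the literal 0–3 mapping. Windows whose midpoint falls inside a baseline
span are BL; otherwise a window takes the class of the nearest
annotation within the labeling threshold (5.5 s or 10 s, matching the
window length; midpoint matching is a documented choice). Equidistant
conflicting annotations discard the window.

Weak supervision trains three members on the strong labels — RBF SVM
(with Platt-style sigmoid calibration, 3-fold, since SVMs emit no native
probabilities), random forest, and uniform-weight 5-NN, all with library
defaults and fixed seeds — and labels each unlabeled instance with the
class of the member whose maximum class-probability is largest, ties
keeping the fixed priority SVM > RF > KNN. The published description of
the label-combination step is this outcome rule, so it is implemented
directly rather than through a generative label model. Weak labeling is
skipped (with a warning) when the strong set has fewer than two classes
or fewer than 10 instances in some class, and it runs inside training
folds only. Evaluation uses strong labels exclusively.

## Augmentation

SMOTE: synthetic minority rows x_i + u·(x_nn − x_i), u ~ U[0,1], with
x_nn among the k = 5 nearest minority neighbors (k auto-reduced with a
warning when the minority is smaller). Neighbor search uses Euclidean
distance after per-feature standardization fit on the data being
oversampled; synthesis happens in the original space. Classes are
equalized to the majority count (ratio configurable); original rows are
preserved verbatim; synthetic rows carry `smote` provenance. SMOTE runs
strictly inside training folds, after feature selection, so synthesis
happens in the selected (≤ 25-dimensional) space.

## Evaluation

Binary tasks BL vs PL1/PL2/PL3 with classifiers SVM (RBF, C = 1,
γ = scale), random forest (100 trees), AdaBoost (50 stumps), k-NN
(k = 5) — hyperparameters are documented library defaults with fixed
seeds. SVM and k-NN sit behind a per-feature standardizer fit on the
training fold; tree ensembles consume raw features. Feature selection
keeps the top 25 columns by random-forest Gini importance fit on the
training fold (ties break to the lower column index for determinism;
fewer than 25 columns are all kept with a warning). Early fusion aligns
windows across modalities by midpoint within the window length and
concatenates in the fixed order ECG, EMG, EDA, RR; late fusion majority-
votes per-modality classifiers, ties broken by mean confidence then
modality order (margin classifiers contribute a logistic squash of
their decision function as confidence).

LOSO: one fold per subject holding out all of that subject's data;
selection, weak labeling, SMOTE, standardization, autoencoder training
and the classifier are all fit on the remaining subjects; the held-out
subject is scored on strong labels only, by balanced accuracy
(TPR + TNR)/2. Folds whose held-out subject lacks one task class are
non-evaluable and excluded from the mean/SD (scoring them 0.5 is behind
a flag). An audit object records, per fold, the subjects seen by fitting
and the provenance of test instances, so leakage is checkable
mechanically rather than by convention.

## Synthetic cohort generator

The generator emulates the *statistical structure* the pipeline assumes
for a postoperative monitoring session: a leading rest span, then
light-activity segments during which pain is felt and sparsely
self-reported (2 reports per segment plus two NRS-0 reports during
rest). Pain of intensity `nrs` shifts physiology monotonically, with
defaults chosen as plausible autonomic effect magnitudes: heart rate
+1.5 bpm per NRS point; inter-beat-interval SD shrinking 5 % per point
(multiplicative) on a 50 ms baseline; EMG burst amplitude +15 % per
point; SCR rate +0.4 per minute per point over a 2/min baseline;
respiration +0.5 breaths/min per point. Per-subject baselines (heart
rate 55–85 bpm, resting respiration 12–16 breaths/min, tonic EDA
2–8 µS) create inter-subject variability so LOSO generalization is
nontrivial. Each subject's default pain profile guarantees one activity
segment per pain class, with any further segments drawn from a mid-heavy
NRS distribution mimicking the label imbalance of real self-reports
(few extreme scores, many moderate ones).

Signal models: ECG as a P–QRS–T Gaussian template train whose inter-beat
intervals follow an AR(1) (φ = 0.8) around the pain-shifted mean, plus
baseline wander, white noise, and random motion bursts; EMG as white
noise with Hanning-windowed bursts during activity; EDA as tonic level,
slow drift and Poisson-arriving Bateman SCRs; PPG as a cardiac
oscillation amplitude-modulated (depth 0.35) at the respiratory
frequency. Ground truth (beat times, SCR times, per-segment respiratory
frequency, true class over time) is returned alongside each recording.

What the generator does **not** emulate: realistic ECG morphology
variation, ectopic beats, electrode pops, sensor dropout, pulse-transit
effects in PPG, EDA drift nonstationarity, or inter-modality artifact
correlation. Passing tests therefore demonstrate that the pipeline
recovers the encoded pain structure under controlled conditions — not
clinical performance on patient data.

## Problem sizes

The replicated evaluation suites run at reduced scale chosen so the full
test suite and the acceptance script each complete in minutes on one
CPU: null-calibration cohorts use 5 subjects × 200 s × 3 activity
segments (20 replicate cohorts, all 3 tasks × 4 classifiers on shared
ECG features); separability cohorts use 6 subjects × 240 s × 4 segments
(20 seeds, respiration features + SVM). These sizes keep ≥ 30 strong
instances per cohort and ≥ 5 evaluable folds per task, which is enough
for the chance-level and separability properties being asserted; the
library itself has no scale assumptions and the generator defaults to
20 subjects × 600 s.

## Known limitations

- The weak-label model calibrates SVM probabilities on the strong set
  with 3-fold sigmoid calibration; with very small strong sets the
  calibration is coarse (the 10-per-class minimum guards the worst case).
- The convex EDA solver is iterative (L-BFGS-B) and returns a numerical,
  not closed-form, optimum; the additivity invariant is exact by
  construction but driver sparsity depends on α.
- EMD mode mixing can split a respiratory component across two IMFs;
  summing all in-band IMFs makes the derived signal robust to this, but
  closely spaced cardiac/respiratory rates (< one octave) would not
  separate.
- The LSTM autoencoder converges more slowly than the convolutional one
  at equal epochs; its latents are nonetheless deterministic and
  shape-correct, and both variants beat the constant predictor on
  synthetic data.
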