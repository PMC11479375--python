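# Methods

## Problem setting

A single triaxial accelerometer worn at the ear (100 Hz, ±16 g, axes
medio-lateral / anterior–posterior / inferior–superior) observes walking.
The package segments the acceleration into gait events — initial contacts
(IC) and final contacts (FC) of the left and right feet — regresses the
spatial geometry of each gait cycle (stride length and width, cm), and
summarizes bouts by the mean, coefficient of variation and left–right
asymmetry of five parameters: stride time, swing time, double support
time, stride length, stride width.

## Temporal event network

Input: standardized 3×200-sample windows (2 s). Standardization is a
robust scaler — per-channel median removal and division by the
interquartile range (type-7 linear-interpolation quartiles) — fitted once
on the pooled training-split samples and frozen thereafter, which
prevents information leaking from validation/test recordings into the
transform.

Architecture: `n_blocks` (default 5) convolution blocks, each a dilated
1-D convolution (kernel 3, stride 1, dilation 2^i in block i,
length-preserving symmetric padding) → batch normalization → ReLU →
dropout (0.2), followed by a position-wise fully connected projection to
two output channels (IC, FC). The default receptive field is
1 + (k−1)·Σ dilations = 63 samples (0.63 s), at least half a gait cycle.
The network emits logits; training minimizes BCE-with-logits (Adam,
default lr 1e-3, batch 64), and the sigmoid is applied at inference only.

Targets: the training target for each channel is a Gaussian bump per
event (peak 1 at the event sample, σ = 5 samples, truncated at 4σ,
overlaps combined by max). Point labels would make the per-sample BCE
nearly uninformative; smeared labels are the standard choice for
sparse-event sequence networks. σ is configurable. Note the attainable
BCE floor is the entropy of these soft labels, not zero.

Inference: windows with 50% overlap (hop 100), per-sample probabilities
averaged across overlapping windows (suppresses window-edge artifacts),
giving a trace aligned to the recording time base. Events are local
maxima above threshold 0.5 with a 0.30 s refractory period (the tallest
peak within the refractory span wins; 0.30 s is below the shortest
plausible fast-walking step). Both knobs are configurable.

Side assignment: a single ear sensor does not observe the feet, so
detected ICs are assigned alternating left/right starting from a
configurable anchor (default: the foot ipsilateral to the sensor ear).
Each FC takes the side contralateral to the nearest preceding IC — in
normal gait phasing a foot's FC falls just after the opposite foot's IC.
If the gap between successive ICs exceeds 1.6× the median step interval,
the number of missed steps is estimated and the alternation parity
advanced, so a single missed detection corrupts only the strides spanning
the gap (flagged invalid downstream) rather than every later stride.
Side-agnostic summaries (means, CVs) are unaffected by the anchor choice;
asymmetry is invariant under a global left/right swap by construction.

## Spatial regressors

From consecutive ipsilateral ICs, the standardized acceleration spanning
the cycle is linearly resampled to a fixed 200-sample segment (durations
outside [0.5 s, 4 s] are outside the human walking range and discarded
with a count). Two independent networks — one for stride length, one for
stride width — share one architecture: residual blocks of two causal
dilated convolutions (left-padded, i.e. pad-and-chomp, so no future
leakage; each followed by ReLU and dropout) with an additive bypass (1×1
convolution when channel counts change), then temporal average pooling
and a linear head to one scalar. The default is 3 blocks of 16 channels —
sized so the dilated receptive field covers the full segment while CPU
training stays cheap.

One model serves both feet; auxiliary input channels accompany the three
standardized acceleration channels. The Euclidean magnitude of the raw
acceleration minus 1 g is appended as a fourth channel (on by default):
it is invariant to the unknown sensor orientation, which varies across
ears and subjects, and without it per-channel amplitude cues confound
stride geometry with mounting angle. The foot side enters as a constant
channel (±0.5, on by default), and the cycle's original duration can be
appended the same way (off by default). Targets are z-scored on the
training split and de-standardized at prediction, which conditions the
MSE optimization independently of the cm scale; training keeps the
best-validation-epoch weights like the temporal network.

Training-time rotation augmentation: each training bout contributes one
extra copy with a fresh random sensor rotation (σ = 10°) applied to the
raw samples before standardization and slicing. Without it the regressor
keys on the training subjects' particular mounting orientations and fails
to generalize across subjects; with it, held-out performance approaches
the ceiling set by a linear model on orientation-invariant energy
features.

## Training protocol

All splitting is at the subject level: an 80/20 train/test split, then
k-fold (k = 5) cross-validation of the training subjects, so no subject's
data appears in two partitions. Stratification deals subjects grouped by
their speed-condition bout counts round-robin across folds. Model
selection within a training run keeps the best-validation-epoch weights.
Hyperparameter search, when used, is a plain grid over batch size
{32, 64, 128}, learning rate {1e-4, 1e-3, 1e-2} and epochs {30, 50, 100},
scored by mean validation loss across folds with ties broken toward the
smaller/cheaper setting.

The networks are implemented directly in NumPy (`mear.nn`) with
hand-written backward passes, verified against central finite differences
in the test suite, and trained in float32 (float64 is available per layer
for numerical checks). Determinism: every stochastic component (subject
draws, bout synthesis, weight init, shuffling, dropout) draws from
generators derived from one master seed.

## Synthetic cohort generator

The generator emulates a walkway protocol: each subject walks a ~6.7 m
walkway 6/8/10 times at slow/preferred/fast instructed speed. Subject
phenotypes are drawn from healthy-adult norms: preferred cadence
110 ± 7 steps/min (slow ≈ 0.82×, fast ≈ 1.15×), preferred stride length
125 ± 10 cm (slow ≈ 0.80×, fast ≈ 1.12×), stride-time CV 2.5 ± 1.0%,
stride-length CV 2.7 ± 1.0%, temporal asymmetry 1.5 ± 1.0%, spatial
asymmetry 0.8 ± 0.6%, stride width 7.2 ± 1.4 cm with 20 ± 8% CV, a random
sensor-orientation rotation (σ = 8°, capped at 25°) standing in for ear
anatomy differences, and white sensor noise (σ = 0.02 g).

Footfalls: left-foot IC times accumulate drawn left stride times; each
right IC sits a step-time fraction into the current left stride, the
fraction set by the temporal asymmetry (larger side gets 1/(2−a)). FC
times sit a stance fraction into each stride — 62/60/58% of the cycle at
slow/preferred/fast speed, matching the qualitative speed dependence of
double support. Per-foot stride lengths are drawn directly (larger foot
at the configured mean, smaller at (1−a)×), so ground-truth asymmetry
follows the printed formula exactly in expectation. Stride width ground
truth is the perpendicular distance of each terminal heel contact to the
line through the two flanking contralateral contacts. Temporal
ground-truth StrideRecords are derived from the emitted events by the
same `strides_from_events` the user-facing pipeline uses, so events and
parameters are mutually consistent by construction — a green
self-consistency test establishes internal coherence, not biomechanical
fidelity.

Acceleration synthesis (the generator's contract; real sensors have no
generative model): gravity on the inferior–superior axis, plus harmonics
locked to the footfall phase (vertical dominant at step frequency with a
second harmonic, AP at step frequency, ML at stride frequency), a damped
~14 Hz impact transient at each IC and a smaller ~8 Hz transient at each
FC, all rotated into the subject's sensor frame, plus Gaussian noise.
Harmonic and IC-transient amplitudes scale with the local walking speed
and stride length — this is what makes stride length recoverable from a
resampled (duration-free) segment. What the simulator does **not**
emulate: turning, stopping, stairs, non-gait activity, pathological gait,
soft-tissue artifacts, or realistic inter-axis cross-talk. A model that
recovers events and stride length here has demonstrated that the
architecture and pipeline can learn footfall-locked structure; it has not
been validated on real recordings.

## Evaluation conventions

- Matching: greedy pairing by ascending |Δt| among all cross pairs with
  |Δt| strictly below 250 ms, each event used once; leftovers are FN/FP.
  On detector-like outputs this attains the optimal assignment (tested
  against maximum bipartite matching); adversarial layouts where greedy
  loses a pair exist but require jitter near the tolerance.
- F1 is reported per event class; a support-weighted aggregate across
  classes is available from the per-class counts.
- Relative RMSE uses the mean of the ground-truth values of the
  comparison group as denominator.
- ICC: two-way single-rater coefficients from ANOVA mean squares. The
  gait literature mixes naming conventions; the default here is
  absolute agreement ICC(A,1) = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n),
  with consistency ICC(C,1) always reported alongside. Interpretation
  bands: <0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, >0.9 excellent.
- Speed dependence: relative RMSE per subject × speed, compared by a
  one-way repeated-measures ANOVA, F = MS_condition/MS_error with
  df = (2, 2(n−1)).
- Degenerate cases are flagged, never silently zeroed: no annotated
  events → recall undefined; zero variance → r and ICC undefined;
  asymmetry with both feet zero → 0, with one foot zero → undefined.

## Known limitations

- The event networks are trained and validated on synthetic signals only;
  thresholds (0.5) and refractory (0.30 s) were chosen a priori, not tuned
  on real data.
- Stride-width recovery is weak by design of the signal model (lateral
  geometry barely modulates the synthesized signal) — mirroring the known
  difficulty of frontal-plane gait characterization from body-worn
  sensors — and is reported but not gated in the acceptance suite.
- The 4-channel (per-foot) event-network variant is not implemented; side
  assignment relies on alternation.
- Batch normalization uses running statistics with momentum 0.1; very
  small training sets can leave them poorly calibrated.
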