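# Methods

`monoseize` implements a patient-specific seizure-detection pipeline for
scalp EEG with progressively reduced channel counts (18 → 4 → 1 bipolar
derivations), aimed at the wearable single-channel setting in which a
clinician designates the one derivation that best captures a patient's
seizures. This note documents the model, the evaluation protocol, the
synthetic data used to exercise it, and the numerical choices made where
the design was genuinely open.

## Signal model and preprocessing

Recordings are multichannel scalp EEG in microvolts at 256 Hz. Referential
inputs are converted to the longitudinal bipolar ("double banana") montage
by simple electrode differences; already-bipolar inputs are passed through.
Three channel policies exist:

- `full18`: the 18 longitudinal derivations Fp1-F3 … Cz-Pz;
- `wearable4`: Fp1-F3, Fp2-F4 (forehead) and P7-O1, P8-O2 (closest to the
  behind-the-ear positions), the four locations where dry wearable
  electrodes attach most easily;
- `single`: one of those four, chosen per patient.

All signals are band-passed 1–30 Hz, which covers delta through beta — the
band where most rhythmic scalp-EEG seizure activity lives. The realization
is a 4th-order Butterworth applied forward–backward (zero phase), so
filtering does not shift annotated onsets relative to the filtered
features; a causal mode is available by configuration. No artifact
rejection is performed, deliberately: the detector must tolerate raw
background.

Windows are 4 s (1024 samples at 256 Hz). A window is labelled ictal iff it
lies entirely inside an annotated seizure interval and interictal iff it
lies entirely outside all intervals; boundary-straddling windows belong to
neither pure class and are excluded (their count is reported). Intervals
are half-open `[onset, offset)` in seconds from file start, with sample
index `floor(t·fs)` — one convention used everywhere.

The training step between window starts is configurable. A one-sample step
(3.996 s overlap) maximizes segment counts but produces ~10⁶ windows per
hour; the default training step is 64 samples (0.25 s), which preserves the
statistical structure at desk scale. Event-level inference always uses the
1-s step.

Ictal windows are outnumbered by interictal ones by roughly 500:1, so
training draws class-balanced batches: each batch holds exactly half ictal,
half interictal windows, the minority class resampled with replacement, the
majority consumed without replacement and reshuffled when exhausted. The
stream is a pure function of (seed, epoch).

## Classifier

The classifier is a two-branch 2-D convolutional network over N × 1024
inputs (N = channels). Branches differ only in kernel length (1×3 vs 1×5)
and each stacks three blocks of convolution → batch normalization → ReLU →
max-pool(3), with 32, 64, 128 filters and temporal strides 2, 2, 1.
Kernels span one electrode row, so convolution never mixes channels;
channel mixing happens only in the head: branch outputs are concatenated on
the feature axis, globally average-pooled over rows and time, and passed
through a 64-unit ReLU layer to a 2-way softmax. With "same" convolution
padding the per-branch temporal trace for a 1024-sample input is
512 → 170 → 85 → 28 → 28 → 9, and the total parameter count is 100,098
(independent of N, because pooling averages over rows).

Open details resolved as follows: both branches use the stride triple
(2, 2, 1); max-pooling is along time with stride equal to pool size and no
padding; batch norm sits between convolution and activation; the head has
one 64-unit hidden layer ("fully connected layers" could mean more — this
is the smallest plural-consistent choice, configurable); ties at the 0.5
decision boundary are classed ictal, favouring sensitivity.

Training uses RMSprop (learning rate 3·10⁻⁴, ρ=0.9), cross-entropy on the
two softmax outputs (binary cross-entropy), and early stopping on
validation loss with patience 15 and best-weight restore. The network,
backpropagation and optimizer are implemented directly in NumPy; inference
uses batch-norm running statistics, so predictions are independent of
batch composition (verified to 10⁻⁵).

## Event-level detection

Sliding 4-s windows at a 1-s step produce an ictal-probability trace
(length ⌊duration⌋−3 for integer durations). Post-processing:

1. **Smoothing** — Savitzky–Golay with window 10, polynomial order 3. A
   10-sample window is even, which standard implementations reject, so the
   local least-squares fit is implemented directly: interior points fit
   over offsets −5…+4 (5 left, 4 right) and evaluate at 0; edge points fit
   over the truncated available window; output clipped to [0, 1]. An
   odd-window mode needs only a config change. The implementation matches a
   brute-force per-point polynomial fit to 10⁻⁹.
2. **Thresholding** — steps with probability strictly above `Th` ("exceeding"
   read literally; the boundary is unit-tested).
3. **Run length** — maximal supra-threshold runs of at least `L` steps
   become events spanning [first window start, last window start + 4 s),
   i.e. the union of window coverage. Events with gaps under 10 s merge
   transitively.

Scoring: an annotated seizure overlapping ≥1 detected event is correct
(latency = earliest overlapping detection onset − annotated onset, signed,
possibly negative); otherwise missed. A detection overlapping no annotation
is a false alarm; one spanning two annotations credits both and is no false
alarm. Sensitivity = 100·correct/annotated, FAR = false alarms per hour of
the test file, latency averaged over correct detections.

`(Th, L)` are tuned on a grid (Th 0.2–0.9 step 0.1, L 5–10) evaluated on
the *training* files' traces only — never the held-out file — maximizing
event sensitivity, tie-broken by minimal FAR, then larger L, then larger
Th (deterministic). The Savitzky–Golay parameters stay fixed at (10, 3) by
default. One caveat worth knowing: after merging, the event *count* is not
monotone in L (removing a middle run can split a merged group), although
the pre-merge run count is; the tests check the property that actually
holds.

## Evaluation protocol

For one case, k = number of files with ≥1 seizure. Each seizure file is
held out once; the classifier trains on ictal windows from the other k−1
seizure files and interictal windows from the seizure-free files, split
7:2:1 into train/validation/test. Segment-level metrics (sensitivity,
specificity, accuracy, rank-based AUC with tie correction) come from the
test split; event-level metrics from the held-out file. Per-case aggregates
are mean ± sample SD (n−1) over folds.

The 7:2:1 split granularity matters: with heavily overlapping windows, a
random per-window split places near-duplicates of training windows in the
test set. The default therefore assigns contiguous time blocks per
same-class run and discards the few windows at block boundaries that would
overlap the previous block, guaranteeing zero cross-part time overlap (the
leakage audit verifies this). The paper-literal random-segment mode remains
available. A side effect of boundary discarding: when a seizure is short
relative to the step, the 10% test block can lose all its ictal windows;
such folds get flagged NaN segment metrics (events are unaffected) rather
than failing or silently leaking.

A reference manifest of the 13 CHB-MIT cases targeted by this design ships
with the package. `summarize_manifest` reproduces its totals (77 seizures,
4,419 s, 599.5 h) and per-case mean ± SD rows; the seizure-length summary
is pooled over individual seizures (mean 4,419/77 = 57.4 s, SD
reconstructed from per-case means and SDs — 32.85 from the rounded inputs).

## Synthetic data

The generator emulates a CHB-MIT-style case so the entire pipeline is
testable with no download: several files at 256 Hz, a minority with
seizures, seizure lengths 30–90 s, ictal rhythm 3–7 Hz, at least one
seizure-free file.

Background is 1/f noise (exponent 1, RMS 20 µV) per referential electrode,
optionally with mains line noise. Each seizure is a Tukey-ramped sinusoid
with a slow linear frequency drift, amplitude `snr_ictal` × background RMS
(default 5). Spatial structure: the burst is injected on the dominant
derivation's electrode pair with compensation terms on first-ring
neighbouring electrodes, solved so that after montage derivation the
dominant channel carries the full amplitude and every other derivation
carries exactly `spatial_attenuation` (default 0.5) of it. The compensation
pattern is feasible for attenuation ≥ 1/3 (the bipolar montage is a
non-invertible linear map, so arbitrary spatial patterns cannot be hit);
the config enforces that bound. Seizure placement keeps ≥60 s spacing and
≥30 s from file edges so event matching is unambiguous.

What the generator does *not* model: artifacts (blinks, EMG, electrode
pops), non-stationary background, morphology evolution within a seizure,
or inter-patient variability. Passing tests therefore demonstrate that the
pipeline's machinery — labelling, training, smoothing, run-length logic,
fold hygiene, channel selection — behaves correctly on band-limited,
spatially localized events; they do not certify clinical performance on
real EEG, where published results at this design's full scale report
single-channel event sensitivity near 99% at ~0.2 false alarms/hour.

Default test scale is 0.25-h files (4 per case, 2 with seizures), chosen
as the smallest size at which every protocol element (k-fold, 7:2:1 split,
tuning, event scoring) is non-degenerate; full 1–4 h files are a config
change only. With this scale and a 5:1 ictal SNR, the end-to-end synthetic
recovery check requires event sensitivity ≥90% and FAR ≤1/h on the
ground-truth channel, and the ground-truth channel must beat a mismatched
one (which receives no ictal signal at all) in paired runs.

## Numerical details and edge cases

- EDF I/O: reading goes through MNE; writing is a minimal 16-bit EDF writer
  (1-s records, per-channel physical range ±⌈max|x|⌉), accurate to one
  quantization step. Duplicate CHB-MIT-style labels ("T8-P8-0/-1") resolve
  to the first occurrence; label matching is case-insensitive and
  whitespace-stripped.
- Filters: band edges validated against Nyquist; DC rejection >99% after
  transients; in-band re-filtering changes amplitude <1%.
- Empty annotation lists are valid (seizure-free files). Inverted or
  overlapping intervals are rejected at construction, so invalid
  annotations cannot propagate.
- Sensitivity with zero annotated seizures and zero misses is defined as
  100%; fold plans never hold out a seizure-free file, so this arises only
  for user-supplied data.
- All randomness (generator, batch stream, weight init, splits) flows from
  explicit integer seeds; identical seeds give identical results, bitwise
  for the generator.

## Limitations

Patient-specific only — no cross-patient generalization is attempted or
claimed. The NumPy network trains on one CPU at desk scale; it is the
specified architecture, not a performance-optimized trainer. The clinical
channel-designation step is represented by the generator's ground-truth
dominant channel, not by a model of clinician judgment. FAR denominators
use the single held-out file's duration; on 0.25-h synthetic files one
false alarm already means 4/h, so FAR comparisons at desk scale are
coarser than at clinical recording lengths.
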