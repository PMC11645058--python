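# Methods

## Problem and approach

Obstructive sleep apnea produces pauses in breathing of at least 10 s
that are audible — or rather, *inaudible* — in tracheal-microphone
recordings: normal breathing appears as periodic bursts of band-limited
acoustic energy, while an apnea episode suppresses them.  The package
classifies contiguous, non-overlapping 6-s windows of such recordings as
*apnea* or *non-apnea* in two stages:

1. **Metric learning.**  A convolutional-recurrent network maps a window's
   spectrogram to a 128-dimensional embedding.  It is trained in a Siamese
   configuration on window pairs with the contrastive loss

       L = (1/N) Σ_i (1 − y_i) · d_i² + y_i · max(0, m − d_i)²,

   where d_i is the Euclidean distance between the two embeddings of
   pair i, y_i = 0 for *similar* (apnea–apnea) pairs and y_i = 1 for
   *dissimilar* (apnea–non-apnea) pairs, and the margin is m = 2.
   Note the deliberate asymmetry: non-apnea–non-apnea pairs are never
   formed, so the loss shapes a compact apnea cluster and pushes
   everything else away from it.

2. **Centroid readout.**  k-means with k = 2 is fitted on the *training*
   embeddings only; each cluster takes the majority true label of its
   members, and a new window receives the class of the nearest centroid
   (Euclidean).  SVC and KNN readouts are available for comparison.

## Windowing and labels

Windows are 6 s, non-overlapping, aligned to multiples of 6 s; a trailing
remainder is discarded.  A window is labeled *apnea* only if a single
annotated event covers it entirely; partial coverage counts as
*non-apnea*.  This rule is intentionally strict: it keeps the positive
class pure at the cost of mildly polluting the negative class with
boundary windows, which is the main cause of residual false positives.
Annotations are onset/offset pairs in seconds on a 0.5-s grid; events
shorter than 10 s only raise a warning when loaded (real scorings contain
them), while the synthetic generator never produces them.

## Features

Both spectrogram variants use a 2048-sample analysis window, a 256-sample
hop, a periodic Hann window, and centred frames (reflect padding by half
a window), giving 1 + floor(n/hop) frames.

* **Mel variants.**  A 32-band Mel power spectrogram of the 16 kHz signal
  (Slaney-style triangular filters, 0–8000 Hz, area-normalised).  The
  reduced variants keep the lowest 8/12/18/25 bands of the *same* 32-band
  analysis — band truncation, not re-analysis — emulating signals
  band-limited to roughly 0.5/1/2/4 kHz.  One 6-s window yields
  1 + floor(96000/256) = 376 frames.  (Published descriptions of this
  analysis sometimes print 374 frames; no hop/window combination on
  exactly 96 000 samples produces that count — without centre padding the
  count is 368 — so the package implements the centred 376 and documents
  the discrepancy instead of guessing an unstated trimming.)
* **STFT variant.**  The signal is genuinely resampled to 1 kHz
  (anti-aliased polyphase), and the linear-frequency magnitude STFT of the
  6000-sample window is 1025 bins × 24 frames.

Spectrograms are log-scaled (10·log10 with floor 1e-10) and standardized
to zero mean/unit variance per window.  Whether the original analysis
applied any amplitude normalisation is unstated; standardization is the
common choice for spectrogram-fed networks and is exposed as a flag.
The truncation identity (k-band = first k rows of the 32-band analysis)
holds exactly *before* log/standardization and is enforced by tests.

## Architecture

`n_conv_blocks` blocks of [same-padding conv (unit stride) → batch norm →
ReLU → non-overlapping max pool], with per-block pool sizes
(2,2), (2,2), (4,2), (4,2) (frequency, time) — the pooling grows with
depth.  The frequency pool is clamped to the rows remaining, so narrow
inputs (8 Mel bands with 4 blocks) stay feasible; a time axis pooled to
zero is a configuration error.  Channel widths are constant
(`conv_channels`, default 64) across blocks.  After the last block the
channel and frequency axes are flattened into a per-frame vector
sequence, processed by `n_gru_layers` (default 2) bidirectional GRU
layers of `gru_hidden` units.  The sequence summary — concatenation of
the forward GRU's final state and the backward GRU's final state — is
mapped linearly to the 128-dimensional embedding.  Exact channel widths,
pool sizes and GRU depth of the reference design are not published;
these choices keep the parameter count in the 0.5–1 M range for the
default widths.

The search space for tuning is kernel ∈ {[5,5],[3,3],[5,1],[3,1]} ×
blocks ∈ {2,3,4} × GRU width ∈ {32,64,128}, crossed with the six input
variants (216 combinations); random search draws uniformly without
replacement.

All network code runs on a small reverse-mode automatic-differentiation
engine over numpy arrays (`apneasiam.nn`): a tape of array operations
with hand-derived adjoints for convolution (im2col), max-pooling, batch
normalisation, and the usual elementwise/matrix primitives.  Gradients
are verified against central finite differences in the test suite, and
the GRU input projections for all time steps are batched into a single
matrix product per layer for throughput.

## Training

Adam (lr 1e-3), batch size 128 pairs, margin 2.  Both pair members pass
through the same model instance, so branch weight sharing is structural.
Because the full pair set of a realistic cohort is combinatorially huge
(hundreds of millions of pairs), each epoch draws a fresh seeded,
exactly 50/50-balanced pair sample instead of materialising the
enumeration; `make_pairs` provides the exhaustive (optionally
oversampled) enumeration for small sets.  The returned checkpoint is the
epoch minimising the training loss, following the reference protocol;
validation-loss selection is available because training-loss selection
is unusual.  Distances are computed as sqrt(Σδ² + 1e-12); the epsilon
keeps the gradient finite for coincident embeddings.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline relies on,
not the acoustics of snoring:

* breathing: white noise band-passed to 100–800 Hz (4th-order
  Butterworth), gated by one 1.2-s Hann burst per 4-s breath period;
* apnea: events with durations uniform on 10–40 s (0.5-s grid,
  rejection-placed with at least one breath period between events),
  attenuating the breathing by 40 dB; total event time targets 30% of
  the recording (±5 percentage points), the class balance the pipeline
  assumes;
* ambient noise: broadband Gaussian at 15 dB SNR (breathing power over
  noise power) for clean patients.  *Corrupted* patients — emulating a
  malfunctioning device or an external noise source — use −25 dB.  The
  corrupted default is deliberately far below the nominal "≤ 0 dB"
  boundary: ambient noise is broadband while breathing occupies ≈ 700 Hz
  of the 8 kHz band, so a 0 dB broadband SNR still leaves ≈ +10 dB of
  in-band SNR and clearly visible breathing structure, and even −15 dB
  broadband leaves a learnable in-band residual; −25 dB puts the in-band
  SNR near −15 dB (bursts perturb the in-band level by under 3%) and
  genuinely drowns the structure.

Per-patient seeds are spawned from the base seed, so cohorts are
reproducible and one patient's audio is independent of another's
settings.  What the generator does *not* model: snoring and its spectral
richness, hypopnea vs. apnea subtypes, ambiguous events with residual
in-event energy, sensor artefacts, night-scale nonstationarity.  Passing
the synthetic end-to-end check therefore demonstrates that the pipeline
machinery (features → metric learning → readout) recovers a clean
apnea/breathing contrast; it does not certify clinical performance.

## Quality control

Corrupted recordings are screened by deliberately overfitting a fresh
Siamese model on one patient's windows and measuring the Euclidean
distance between the mean apnea and mean non-apnea embeddings (plus a
2-D PCA projection for visual inspection).  Clean patients separate
toward the margin (≈ 2); drowned recordings cannot be separated by
structure and stay low.  The default flag rule is an absolute threshold
of 1.5 — the reference analysis reports cohort means near 1.99 ± 0.11
with excluded patients near 0.88, and gives the outcome rather than the
rule — with a cohort-relative alternative (mean − 3·SD) provided.

Two desk-scale caveats found while sizing the QC procedure.  First, the
corruption level must truly erase the *in-band* structure: a dedicated
single-patient overfit is sensitive enough to separate classes from a
few-percent in-band residual, which is why the corrupted SNR default sits
at −25 dB rather than just below 0 (see above).  Second, with only tens
of windows per patient a network trained long enough starts separating
*any* patient by memorising per-window noise; with ≈ 150 windows per
patient and a short schedule (a small 16-channel/2-block/GRU-32 backbone,
7 epochs of 256 pairs) memorisation stays near the untrained floor while
clean patients converge toward the margin, reproducing the bimodal
clean ≈ 1.6–1.8 vs corrupted ≈ 0.2–0.4 separation the threshold 1.5 is
meant to split.

## Problem sizes and numerical choices

* End-to-end evaluation: 10 synthetic patients of 600 s (100 windows
  each), split 6/2/2 by patient; Mel-8 features; a small backbone
  (16 channels, 2 blocks, GRU 32, kernel [3,3]); 8 epochs of 512 pairs.
  Window F1 on the held-out patients is ≈ 0.91 across seeds, with
  recall 1.0 — residual errors are false positives on event-boundary
  windows, as expected from the strict labeling rule.
* k-means: 10 restarts, tolerance 1e-4, max 300 iterations (none of
  these are published; they are scikit-learn-style defaults).
  Prediction ties (exactly equidistant centroids) resolve to
  *non-apnea*, the conservative choice against false positives.
  If both clusters share a majority label, the cluster nearer the apnea
  points takes the apnea label and a warning is emitted.
* Degenerate metrics (0/0) return 0 with a warning.
* Weights are float32; gradient checks run in float64.
* Patient-level splits use largest-remainder rounding, which yields
  24/6/7 for 37 patients at (0.65, 0.15, 0.20); the published reference
  lists (23/6/8) are shipped verbatim in `tune.REFERENCE_SPLITS` for use
  with the real corpus.

## Known limitations

* The synthetic corpus is far easier than real tracheal audio; see above.
* No temporal smoothing or event-level merging of window predictions, and
  no apnea–hypopnea-index estimation: window-level classification only.
* The parameter counts of the reference architecture cannot be matched
  exactly because its channel widths, pool sizes and GRU depth are
  unpublished.
* Single-channel audio only; the annotation-file schema is this
  package's own (the reference corpus's metadata layout is not parsed).
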