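# Methods

## Problem and pipeline

`parkfuse` classifies Parkinson's disease (PD) versus healthy controls (HC)
from paired recordings of read speech and frontal video of the mouth. Two
motor signs motivate the two streams: hypokinetic dysarthria (reduced
loudness, monopitch, rough voice, imprecise articulation, frequent pauses)
in the audio, and hypomimia (reduced facial/mouth excursion) in the video.

The pipeline standardizes audio to 48 kHz (DC removal, peak normalization)
and video to 7 frames per second of 50×100 grayscale lip crops, then cuts
each recording into one-second bimodal segments: 48 000 audio samples
aligned with the 7 lip frames covering the same wall-clock second. Models
operate on segments; per-subject decisions take the mode over segment
decisions, with exact ties resolved toward PD by the mean PD posterior.

Two families of models are implemented:

* **Classical.** Hand-crafted descriptors — articulation (488 values:
  Bark-band energies, MFCCs and their first two derivative orders around
  voicing onsets/offsets, plus formant dynamics), phonation (28: F0
  differences, jitter, shimmer, perturbation quotients, log energy),
  prosody (103: F0/energy statistics, degree-5 polynomial contour
  coefficients per voiced segment, duration and rhythm measures) and a
  255-bin local-binary-pattern (LBP) lip-texture histogram — classified
  with an RBF support-vector machine whose C and γ are grid-searched on
  speaker-grouped training folds.
* **Deep.** A raw-waveform speech encoder (two strided 1-D convolutions
  with batch norm and non-overlapping max pooling, a two-layer
  bidirectional LSTM, a 9280→1024→256→2 fully connected head; stage
  lengths 3961→1980→291→145 for a one-second input, per-step embedding
  145×64) and a residual lip encoder (3×3 stem, three stages of two
  residual blocks at 16/32/64 maps with stride-2 entries and projection
  shortcuts, global average pooling to 64 values per frame, linear head).
  Fusion is single-head scaled dot-product attention
  softmax(QK^T/√d_k)V applied synchronously: in an "X-to-Y" projection,
  Q derives from the target stream Y and K, V from the source X, the
  output lives on Y's time axis and is averaged over time. The headline
  system concatenates both pooled projections (128 values) before a
  linear softmax head. Early, late (max/mean/product) and joint fusion
  baselines are included.

## Synthetic corpus

The clinical corpus this design targets is private, so the package ships a
generator that emulates the two phenomena with controllable class
structure. Per subject, four parameters are drawn: modulation depth
(fraction of full mouth excursion retained; HC mean 0.75, SD 0.05),
jitter level (fractional cycle-to-cycle period perturbation; HC 1%, SD
0.3%), pause rate (HC 0.3 events/s, SD 0.08) and habitual F0 (140 ± 25 Hz,
class-neutral). A single effect size δ scales the PD-direction shifts:
−0.10 modulation, +3 percentage points jitter, +0.35 pauses/s per unit δ.
At δ = 0 the class distributions coincide exactly.

Each utterance is driven by a latent aperture trajectory (three
random-phase sinusoids in 1–4 Hz, the syllabic range, rescaled to [0, 1]).
Audio is a glottal-like pulse train (raised-cosine pulses, 60% open
phase — strongly low-passed so the fundamental dominates) with
per-period jitter, filtered by a second-order resonance whose center
frequency tracks the aperture, amplitude-modulated by
1 − depth·(1 − aperture), gated by a pause mask (Poisson pauses of
0.25 ± 0.08 s plus a 70 ms silent lead-in/lead-out that guarantees one
voicing onset and offset per utterance), high-passed at 40 Hz, and mixed
with white noise at the configured SNR (30 dB default). Frames render a
textured lip ellipse whose dark opening height tracks the aperture, with
a fixed striped "teeth" band whose visible area grows with the opening,
spatially smoothed texture and sensor noise, and small per-frame
translation/rotation. Because the teeth band is spatially fixed, the
dark-opening pixel count is exactly monotone in the aperture.

`coupling_mode` routes the class information. In `shared` mode one
aperture drives both the lip opening and the audio envelope (and closes
during pauses), so the excursion cue is audible and visible. In
`complementary` mode the excursion cue is video-only (the audio envelope
uses a fixed class-neutral depth, and the video ignores pauses) while
jitter and pauses are audio-only — each stream alone then carries
strictly less information than both together, by construction.

What the generator does *not* model: real articulatory phonetics,
photorealistic faces, tremor or dyskinesia, medication state, recording
channel variability, or any correlation between disease severity and
age/sex. Passing tests therefore demonstrate that the pipeline recovers
planted class structure of the hypokinetic kind under controlled
conditions — not clinical performance.

## Training

Deep models train with Adam (L2 regularization 10⁻³ at desk scale),
batch normalization, dropout (0.2–0.3), gain/time-shift/resampling
augmentation for audio (all preserve jitter, pauses and envelope dynamics
while breaking speaker-identity shortcuts such as habitual pitch) and
photometric jitter plus horizontal flips for frames. Early stopping
monitors validation UAR: the starting point is scored too, strict
improvements reset the patience counter, ties refresh the stored weights
(so a flat validation curve returns trained weights), and the restored
checkpoint includes the batch-norm running statistics.

Fusion models are trained in three steps: (1) the two encoders are
warm-started from the trained unimodal models; (2) the attention
projections and classifier converge on cached encoder sequences (the
query/key maps start small and the value map at identity, so attention
begins as a temporal mean; the classifier starts at zero; per-sample
modality dropout keeps both halves of the fused vector independently
predictive); (3) a brief end-to-end fine-tune propagates the loss into
both encoders at 5% of the head learning rate.

## Evaluation

Five-fold speaker-independent stratified cross-validation: subjects are
shuffled within class and dealt round-robin, so per-fold class counts
deviate from proportionality by at most one; one training fold (rotating)
serves as the early-stopping/validation split. Metrics are reported in
percent as mean ± SD across folds: sensitivity (recall on PD, the
positive class), specificity (recall on HC), UAR = (sensitivity +
specificity)/2, and macro-averaged F1 (the macro flavor is a package
choice; binary-PD F1 would differ only under class imbalance). Multi-seed
studies that generate a fresh corpus per repetition use a single
speaker-disjoint train/validation/test split instead of full
cross-validation.

## Problem sizes and numerical choices

Experiments run at desk scale: reduced encoder widths (speech 4/8
channels, 8 LSTM units per direction; lip 4/8/16 maps with one block per
stage and frames block-averaged to 25×50), corpora of 10–16 subjects per
class with 2–6 one-second utterances each. The canonical Table-scale
geometry is always used for architecture checks and is fully functional
for inference. The multi-seed fusion study uses 10 seeds, complementary
coupling at δ = 1.5, 16 subjects per class (8 train / 2 validation / 6
test per class). The null-calibration check uses the full deep fusion
pipeline at δ = 0 with 20 subjects; the strong-effect check uses the
classical full-speech pipeline at δ = 2.

Other conventions: Fisher kurtosis with degenerate (zero-variance or
single-observation) skewness/kurtosis defined as 0; F0 by normalized
autocorrelation over 40 ms frames with 10 ms hop, voicing threshold 0.45
and a relative energy gate, parabolic lag interpolation, search range
50–500 Hz; voicing-transition windows of 40 ms on each side of the
border, truncated at signal edges; 22 Bark bands per transition (the
articulation total of 488 fixes 122 descriptors × 4 functionals);
formants from LPC (order 16 at 16 kHz) roots with bandwidth and range
gates; LBP codes sampled clockwise from the top neighbor with bilinear
interpolation off-grid, ties counted as ≥ with a relative epsilon
(interpolating an exactly constant patch can undershoot by a few ulps),
binned into 255 equal-width bins over [0, 256); a pause is an unvoiced
stretch of at least 100 ms; classical posteriors map the SVM margin
through a logistic link; exact decision ties resolve toward PD.

## Known limitations

The tiny speech encoder reads pause structure and coarse roughness but is
far from the linear-probe ceiling on jitter, so the audio stream at desk
scale is weaker relative to video than the corresponding full-scale
system would be. Attention weights are learned but not interpreted —
no claim is made that they localize disease-relevant intervals. The
prosody inventory documented here is normative for this package; other
toolboxes count a slightly different 103.
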