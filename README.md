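# parkfuse

Audiovisual detection of Parkinson's disease (PD) from read speech and lip
movement. The package implements a complete experimental framework around a
synchronous cross-modal fusion idea: encode one-second speech segments with
a raw-waveform 1D-CNN + bidirectional LSTM, encode the 7 time-aligned lip
frames with a small residual 2D-CNN, and fuse the two temporal streams with
scaled dot-product attention

    Attention(Q, K, V) = softmax(Q Kᵀ / √d_k) V

in both projection directions (speech-to-lip and lip-to-speech), pooling
each projected sequence over time and concatenating the two 64-value
summaries for classification. Classical baselines are included: articulation
(488), phonation (28) and prosody (103) speech descriptors, 255-bin local
binary pattern (LBP) lip-texture histograms, an RBF-SVM classifier, and
early/late/joint fusion. Everything is evaluated with 5-fold
speaker-independent stratified cross-validation; decisions are made per
subject by the mode over segment predictions, and metrics are UAR
(unweighted average recall), sensitivity, specificity and F1.

The clinical audience for such a system are speech-pathology and movement-
disorder researchers; since the paired clinical recordings such systems are
trained on are generally private, the package ships a synthetic-corpus
generator that plants hypokinetic class structure (reduced mouth excursion,
raised jitter, more pauses) with a controllable effect size, so every stage
is trainable and testable end to end.

## Worked example

```python
from parkfuse.synthetic import SynthConfig, generate_corpus
from parkfuse.experiments import ExperimentSpec, run_experiment

corpus = generate_corpus(SynthConfig(n_subjects_per_class=10,
                                     utterances_per_subject=3,
                                     effect_size=2.0,
                                     coupling_mode="shared",
                                     seed=42))
report, manifest = run_experiment(
    ExperimentSpec("classical", "speech", "full", seed=42), corpus)
print(report.summary())
```

prints

```
uar 95.0 ± 10.0 | sensitivity 100.0 ± 0.0 | specificity 90.0 ± 20.0 | f1 94.7 ± 10.7
```

i.e. at a strong planted effect (δ = 2) the 619-dimensional classical
speech representation recovers the cohorts almost perfectly across the five
speaker-disjoint folds (mean ± SD over folds, in percent). The same
`ExperimentSpec` grid covers every benchmark row, e.g.
`("deep", "both", "both_projections")` for the attention-fusion headline
system. The same experiments are available from the shell:

```bash
parkfuse generate --out corpus/ --subjects-per-class 10 --effect-size 2 --seed 42
parkfuse extract-features --corpus corpus/ --out features/
parkfuse run --corpus corpus/ --approach classical --streams speech --technique full --seed 42
parkfuse ordering-study --seeds 10
```

`ordering-study` runs the multi-seed complementary-mode comparison in which
each modality carries a disjoint cue; it reports mean subject-level UARs
for the unimodal speech encoder, the unimodal lip encoder, and the
concatenated-projection fusion, whose mean is expected to be at least that
of either unimodal stream.

## Layout

- `parkfuse.synthetic` — paired audio + lip-frame corpus generator
- `parkfuse.preprocessing` — 48 kHz / 7 FPS standardization, lip ROI, 1 s bimodal segments
- `parkfuse.features` — articulation / phonation / prosody / LBP extractors
- `parkfuse.nn` — autograd tensors, conv/LSTM/batch-norm layers, Adam, training loop
- `parkfuse.speech_encoder`, `parkfuse.lip_encoder` — the two deep encoders
- `parkfuse.fusion` — attention fusion and early/late/joint baselines
- `parkfuse.evaluation` — speaker folds, mode voting, metrics, cross-validation
- `parkfuse.experiments`, `parkfuse.cli` — the experiment grid and shell entry points

See `docs/methods.md` for the model details, generator assumptions and
numerical conventions.
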