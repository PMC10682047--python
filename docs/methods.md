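# Methods

`larynet` models the data stream of a skin-mounted laryngeal patch — a
triaxial accelerometer plus one surface-EMG (sEMG) channel sampled at 333 Hz —
and the analysis chain built on it: synthetic signal generation, vital-sign
decoupling, a convolutional sequence classifier with a dual
triplet/cross-entropy objective, subject adaptation, and an ordinal
rehabilitation score. This note records the model assumptions, the parameters
that matter, and the design choices made where the design was genuinely open.

## Signal model

All components mix additively per channel, with one seeded random generator
per recording so that equal inputs and seeds give bit-identical samples.

**Cardiac micro-vibrations (az).** Each beat is a sum of Gaussian lobes:
a sharp upward R lobe (width 18 ms), a sharp downward S lobe (45 ms later),
a small broad T lobe at 18 % of the cycle, and a broad diastolic trough
centred at 55 % of the cycle (width 0.2 cycles). The trough carries the slow
per-cycle net displacement, which anchors the dominant Welch-spectrum line at
the beat frequency rather than at a harmonic of the sharp lobes — without it,
a train of narrow biphasic pulses has an almost flat harmonic comb and its
PSD maximum lands on whichever harmonic the pulse shape favours.
Beat-to-beat intervals carry at most 2 % Gaussian jitter. Default amplitude
0.015 g (subjects drawn in 0.010–0.020 g).

**Respiration (ay).** Fundamental at the breath rate with two weak harmonics
(relative amplitudes 0.22 and 0.07), default amplitude 0.05 g. The harmonic
amplitudes are small enough that the waveform crosses its mean exactly once
per cycle, so a breath count equals the zero-up-crossing count.

**Acoustic classes.** Five "pinyin" and five "vowel" surrogate classes are
two-formant bursts on az: class *k* (k = 0..9) has formants at
(85 + 8k) ± 8 Hz with a class-specific syllabic AM rate (2 + 0.6k Hz) and a
plosive-like fast attack for pinyin versus a smooth attack for vowels. The
grid spans 80–165 Hz — the upper end is capped by the 166.5 Hz Nyquist limit
of 333 Hz sampling, so all "below 200 Hz" band constraints hold by
construction. Adjacent spectral centroids sit 8 Hz apart; classes two steps
apart differ by 16 Hz.

**Behaviors and artifacts.** Swallowing is two laryngeal-elevation bursts
(38 and 62 Hz carriers); drinking is three rhythmic ~28 Hz gulps; coughing is
one strong and one weaker broadband 90–150 Hz expulsion. All three
co-activate the sEMG envelope. Walking/jumping live on ay (step fundamental
~2 Hz, landing impulses up to ~1.4 g) and exceed every laryngeal event in
peak amplitude, while laryngeal events stay under 0.4 g at unit intensity.
Chewing, nodding and choking contaminate all axes at low frequency.

**Between-subject variation.** A `SubjectProfile` scales cardiac and
respiratory amplitude, sEMG gain and noise floor, and carries a
`spectral_jitter` fraction. The jitter *direction* per (subject, class) is a
fixed hash of the subject id, so a subject is internally consistent but
systematically shifted from the population templates — the property that
makes new-subject transfer degrade and adaptation worthwhile. Training
cohorts draw jitter uniformly in [0, 0.03]; the "perturbed new subject" used
in the adaptation studies carries jitter 0.10 (±10 % formant shift, i.e.
one to two class spacings at the top of the grid) with weaker sEMG gain and a
higher noise floor.

**sEMG channel.** Band-limited (20–150 Hz) Gaussian noise at unit RMS,
amplitude-modulated as `baseline + envelope × gain` with baseline RMS 0.05
a.u., so a silent larynx leaves pure baseline noise.

What the generator does **not** emulate: sensor nonidealities (quantisation,
clipping, drift), true phoneme acoustics, biomechanical coupling between
events, or pathological swallow morphology. Passing tests therefore
demonstrate that the *pipeline* recovers what the signal model encodes — not
that the classifier would reach the same accuracy on human recordings.

## Vital-sign estimation

HR comes from az, RR from ay, by zero-phase (forward–backward) Butterworth
filtering and refractory peak detection; rates are 60 over the trimmed mean
inter-peak interval (intervals outside 0.5–1.5× the median are discarded as
missed/double detections). The respiratory path detects peaks directly on
the 0.1–0.7 Hz band-passed ay with a 1.5 s refractory interval. The cardiac
path band-passes az at 5–25 Hz — the band of the sharp R/S transient — then
squares and smooths (80 ms moving average) into an energy envelope before
thresholding at mean + 0.5 sd with a 0.25 s refractory interval. Direct peak
picking on a wide (≈1–20 Hz) band was tried first and fails at realistic
noise floors (0.002–0.004 g white noise against 0.010–0.020 g R peaks): the
threshold admits enough noise maxima to bias the rate upward by tens of
beats per minute, while the energy envelope concentrates the R/S complex and
is robust across the tested HR range (45–150 bpm). Fewer than two detected
peaks yields an `undefined` flag rather than an exception.

## The 2D-SFE classifier

Windows of 4 channels × 1000 samples (the four channels z-scored per
recording, in fixed order ax, ay, az, semg) are treated like small images.
The extractor is 8 weight blocks; block *b* holds `r_b` (convolution →
activation) pairs and one width-2 max pool, with
`r = (1, 1, 1, 2, 3, 5, 6, 8)` so the census of processing layers —
convolution, pooling and activation counted individually — is exactly 62,
with convolution repeats concentrated where pooled maps are short. Channel
widths are (8, 8, 8, 12, 12, 16, 16, 16), kernels length 5 spanning all
input channels. Three implementation choices keep this depth trainable in a
plain-numpy engine:

* each convolution standardizes its output per channel over batch and time
  (batch normalisation folded into the layer, with running statistics for
  inference);
* channel-preserving (conv → activation) pairs carry an identity skip;
* the globally average-pooled feature vector is projected onto the unit
  sphere, which bounds triplet distances in [0, 2] and keeps logits
  scale-stable.

The head is exactly 2 fully connected layers (16 → 32 → classes) ending in a
softmax. Training minimises `λ·triplet + (1−λ)·cross-entropy` with λ = 0.5,
margin 1.0, batch 64, semi-hard within-batch triplet mining (hardest
positive; closest negative beyond it, falling back to the closest negative).
The best-evaluation-accuracy snapshot is returned.

**Learning-rate schedule.** Two modes are implemented. `as_printed`
evaluates the published recurrence literally,
`LR = (1 + 0.5·cos(x + π/epochs))·(1 − iLR)`, which oscillates near 1.5 and
is unusable as a learning rate; it exists as a fidelity mode and is what the
oracle tests check. `cosine_annealing` is the conventional reading,
`LR = iLR·0.5·(1 + cos(π·x/epochs))`, and is the training default. The
published initial rate is 1e-4; desk-scale configurations default to
iLR = 1e-2 because a reduced-epoch (≤ 30) run from scratch needs the larger
step to converge. `x` indexes epochs (the alternative, batch indexing, is
unstated in the source description; epoch indexing makes the schedule
independent of dataset size).

**Optimizer.** Adam moments `m_t = β₁m + (1−β₁)g`, `v_t = β₂v + (1−β₂)g²`
with β₁ = 0.9, β₂ = 0.999, ε = 1e-8; parameters move by
`−lr·m̂/(ε + √v̂)`. The scalar *attenuation rate* AR, initialised at 0.9, is
tracked alongside as a diagnostic by the same recurrence applied to the mean
update term; a zero gradient leaves both parameters and AR untouched.

**Adaptation.** For a new subject, the convolutional extractor is frozen
(embeddings computed once), and only the two classifying layers are refit by
cross-entropy on a small labeled set — half the new subject's windows,
stratified by class, with the other half held for evaluation. Zero
adaptation epochs return the model bit-identically.

## Evaluation protocols

`within_subject` scores held-back recordings of training subjects;
`new_subject_zero_shot` and `new_subject_adapted` score untouched subjects
before and after head adaptation; `artifact_noise` re-scores the held-back
windows after injecting chew/nod/choke acceleration deltas scaled to each
window's channel standard deviation (intensity 0 reproduces `within_subject`
exactly). t-SNE (scikit-learn, seeded, exact method below 600 points) gives
the 2-D feature view; the silhouette score is the scalar proxy for cluster
quality, since "clusters look tighter" is not testable.

## Rehabilitation scoring

Swallowing (S), drinking (D) and talking (T) are flagged abnormal when mean
classifier confidence falls below 0.5 (a configurable convention) or, for S
and D, when a timing rule fails. Timing comes from a 50 ms moving-RMS
envelope thresholded at median + 30 % of the dynamic range; bursts shorter
than 80 ms are ignored. Safety requires onset-to-first-burst-peak < 3 s
(the accelerometric proxy for the circumpharyngeal opening); effectiveness
requires onset-to-last-burst-offset < 15 s. Both are strict: exactly 15 s
fails. The three flags map bijectively to levels I–VIII, ordered by abnormal
count and, within a count, by S > D > T severity; the mid-level order is a
documented convention (the scale itself is a monitoring aid, not a validated
clinical instrument), and sessions missing a behavior are reported without a
level rather than scored.

## Problem sizes and numerics

Desk-scale runs use 18 subjects (16 train / 2 held out), 2 recordings per
class per subject of 4.5 s each, 4 windows per recording and ≤ 30 epochs;
at these sizes a full 13-class fit takes on the order of a minute on one
CPU core. The engine is float32 throughout, single-threaded-deterministic;
training, windowing and synthesis are reproducible bit-for-bit from the
seeds recorded in every artifact. Degenerate inputs follow one rule:
violated preconditions raise `ValueError` with the offending quantity named,
while legitimately uninformative data (flat channels, absent bursts,
incomplete sessions) yield flagged results (`undefined`, `not_assessable`,
a report without a level) instead of exceptions.

## Known limitations

* The synthetic classes are far more separable than human laryngeal
  recordings; accuracy figures on this generator are upper bounds by design.
* The 62-layer composition and channel widths are package choices; the
  original architecture's per-block hyperparameters are not public.
* The `as_printed` schedule is preserved for fidelity but never used to
  train.
* Batch statistics make training-time behaviour depend on batch composition;
  inference uses running statistics and is batch-independent.
* The swallow-timing proxy (first burst peak) approximates an event defined
  endoscopically in clinical practice; no claim of clinical validity is made.
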