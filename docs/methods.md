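# Methods

This note documents the models and procedures implemented in `eyewrite`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Problem and signal model

Eye-writing lets a user enter text by tracing character strokes with gaze.
Electrooculography (EOG) measures the corneoretinal potential through skin
electrodes: the two-channel signal (horizontal, vertical) tracks gaze
direction with amplitudes of roughly 250–1000 µV and spectral content
below ~30 Hz, contaminated by baseline drift, powerline interference,
sensor noise, and blink artifacts.  Continuous eye-writing — no pause
between characters — trades easy segmentation for speed, so recognition
is posed as continuous sequence decoding, exactly as in speech
recognition: characters are decomposed into strokes, strokes into basic
eye motions, and the motions are modeled by hidden Markov models whose
concatenation spells out whole sentences.

## Input protocol

Three levels, shipped as editable YAML data (`data/protocol_katakana.yaml`):

* **11 basic units** — eight directional gaze motions (cardinal +
  diagonal), a return-to-center motion, a blink, and `sil` (gaze resting
  at the neutral position).
* **12 strokes** — reusable glyph fragments, each a short motion sequence;
  stroke 11 is the closed box "left, up, right, down, left", stroke 12 is
  a single blink (dots and diacritic ticks).
* **70 characters** — 48 basic Katakana plus 22 derived (voiced) forms
  built as base strokes + mark strokes.

`sil` is inserted between strokes and between characters (and always
leads/trails a compiled string); consecutive `sil` collapse, making
compilation homomorphic over concatenation.  Several characters share an
identical motion expansion; these homographs are deliberate — the
character N-gram resolves them during decoding.  The exact glyph
decompositions are conventions, not claims: the table is data and can be
edited without touching code.

## Preprocessing and features

Continuous path: first-order DC blocker
`H(z) = (1 − z⁻¹)/(1 − R z⁻¹)` with `R = 0.999` (removes drift; zero gain
at DC), then a 201-tap Hamming windowed-sinc FIR low-pass at 20 Hz applied
at zero phase (group delay compensated with edge padding), then decimation
1 kHz → 50 Hz.  Isolated path: 9-sample median smoothing, decimation to
125 Hz.  The filtered 2-dim stream is the *baseform* feature.

*Expanded* features append regression deltas and delta-deltas (window 2,
edge replication) and join consecutive frame pairs: 2 → 6 → 12 dimensions
with rates 50 → 50 → 25 Hz (continuous) or 125 → 125 → 62.5 Hz (isolated).
The neural front-end splices ±5 frames (132 dims) and applies a PCA
transform fitted on training frames only.  The decorrelator default is a
pure rotation; the hybrid network enables per-component unit-variance
whitening (a config switch), because its SGD schedule (fixed initial
learning rate 0.05) assumes inputs of order one, whereas raw spliced EOG
components are in hundreds of µV.

## Acoustic models

Every unit is a 4-state left-to-right HMM with self-loops and single
forward arcs, so any compiled motion string is one linear state chain;
forward, backward and Viterbi are vectorized shift recursions.  State
outputs are diagonal-covariance GMMs stored in a flat emission table
indexed by the unit states — the indirection that makes state tying and
the hybrid network drop-in scorers.

Training is embedded Baum-Welch (sequence-level supervision, latent
alignment): flat start (all states share the global mean/variance,
transitions 0.5), EM, then iterated binary mixture splitting (means
perturbed ±0.2 σ, weights halved) with EM after each split until the
target component count, then a final EM stage.  Variances are floored at
10⁻⁴ of the global variance.  Zero-occupancy states keep their prior
parameters.  On Viterbi score ties the self-loop is preferred, for
determinism.

Context dependence: tri-motion models are cloned from their center unit
for every context window observed in training.  `sil` is context
independent and resets context (windows never cross it); because `sil` is
inserted between strokes and characters, contexts only span within a
stroke, which keeps the inventory small.  Decision-tree state clustering
then ties states per (center unit, state index) by greedily taking the
question — membership of the left/right context in singleton or
direction-family sets — with the largest single-Gaussian log-likelihood
gain, stopping at a gain threshold or a leaf cap.  Unseen test contexts
back off to their center unit.

## Hybrid network

A fully connected 132-200-100-K network (ReLU hidden layers, softmax
output; K = number of emission states) replaces the GMM scores with
scaled likelihoods `log p̃(x|s) = log P(s|x) − log P(s)`, the prior taken
from alignment counts (floored at 10⁻⁸).  Targets are hard Viterbi
emission-state labels from the final GMM system.  Training: Xavier
initialization, mini-batch SGD (batch 128) with momentum 0.9, initial
learning rate 0.05, 20 epochs, 1% of frames held out; the rate halves
after any epoch whose held-out frame accuracy drops (the halving keys on
accuracy, not loss — an open choice documented here).  Adaptation
re-trains all layers at rate 0.01 for 15 epochs.  The implementation is
plain-NumPy backpropagation; the network is small enough that this is the
natural engineering choice at these widths.

## Language model and decoder

The character N-gram (default order 5 over the 70-character vocabulary
plus sentence boundaries) uses interpolated Witten-Bell smoothing
expressed in backoff form, with ARPA read/write for interchange.
Witten-Bell was chosen for robustness on small corpora over a 70-symbol
alphabet; the discounting method is configurable in principle but only
Witten-Bell is implemented.

The decoder is a time-synchronous Viterbi beam search over the lexicon
network: one left-to-right sub-chain per character (expansion + trailing
sil) plus a leading sil chain.  Hypotheses recombine at (graph state,
truncated character history); each state carries its full emitted history
so recombination never loses the output.  Character exits pay
`lm_scale · log P(char | history) − insertion_penalty`; the winner
additionally pays the end-of-sentence event.  Defaults: `lm_scale = 1`,
`insertion_penalty = 0`, beam 120 (log margin), at most 32 live histories
— the history cap matters: 8 caused measurable search errors on
5-gram decoding of synthetic sentences, 32 removed them at ~1.5× cost.
Ties break toward earlier graph nodes.  The reported score decomposes
exactly into acoustic + scaled LM + penalty terms, verified by forced
alignment of the winning sequence.

Progressive output: after each frame, hypothesis posteriors (normalized
`exp(score)` over active states) below a threshold are pruned and every
character on which all survivors agree is committed with its frame time.
With threshold 0 the final output provably equals batch decoding.

## Isolated baseline

DTW with Euclidean local distances, the symmetric step set
{(i+1,j),(i,j+1),(i+1,j+1)}, anchored endpoints, no band (full search),
unit step weights, unnormalized cost (a length-normalization switch
exists).  Classification is nearest template over all stored templates;
ties go to the lower stroke id.  The 9-point gain calibration fits a
per-channel affine map (µV per unit gaze displacement) by least squares
from fixations at known targets; a rank-deficient target layout on either
axis is rejected.

## Adaptation

Only Gaussian means move.  MLLR estimates one global affine transform
`µ' = Aµ + b`; with diagonal covariances the rows of `[A b]` decouple into
d independent weighted least-squares solves, ridge-regularized if
singular, and the update refuses to run below d+1 frames of occupancy.
MAP interpolates per-Gaussian: `µ' = (τ µ₀ + Σγx)/(τ + Σγ)`, default
τ = 10; zero-occupancy Gaussians are untouched.  The two methods are
exposed independently (no cascade).  The network adapts by re-training
(above).

## Synthetic data generator

The simulator renders labelled 1 kHz two-channel EOG from text: the gaze
target integrates unit displacements (diagonals at ±45°) with smooth
sigmoid transitions (0.15 s) and jittered holds (0.35 ± 0.05 s); `sil`
returns the gaze to neutral and holds — the neutral-position semantics of
the unit, which also keeps deflections inside the physiological band
(amplitude 600 µV per step, soft-saturated at ±1000 µV).  Blinks add a
biphasic vertical bump (400 µV, 0.25 s).  Artifacts: random-walk drift
(20 µV/√s), 50 Hz powerline (5 µV; 60 Hz configurable), white noise
(8 µV).  User profiles scale per-channel amplitude, writing speed and
drift, and rotate the channel axes (electrode crosstalk).  All randomness
flows from an explicit corpus → user → item seed hierarchy; renders are
bit-reproducible.

Corpus shape mirrors the real study design: word lists of 1–3 characters
(mean ≈ 2.8, Zipf-like character frequencies), sentences of 5–20
characters concatenated from words, LM text sampled from the same word
distribution with test sentences excluded.

What the simulator does **not** emulate: per-writer glyph idiosyncrasy
(everyone traces the same canonical motion path), EMG/EEG contamination,
electrode drift within a session, saccade dynamics (transitions are
sigmoids, not ballistic profiles), or overlap/coarticulation between
motions beyond the low-pass smearing.  Consequently the synthetic
error rates are far below those on real recordings, and passing tests
demonstrate *correctness and qualitative behavior* of the pipeline — not
field performance.

## Desk-scale experiment sizes

Chosen once for single-CPU runtimes of minutes, documented here as the
package's study conditions: two synthetic users (one nominal, one with
1.25×/0.80× channel gains, 1.15× speed, 12° crosstalk, 1.3× drift); 100
training words × 3 repetitions per user; 10 test sentences of 5–12
characters; 4 Gaussian components per state with 4 EM iterations per
stage; mono-motion units in the canned continuous experiments (tri-motion
expansion and tying are exercised by their own tests); 5-gram LM from
4000 sampled sentences; isolated comparison over 12 strokes × 10
repetitions with 10-fold cross-validation.  The adaptation sweep adapts a
model trained on the nominal user with 5/20/100 words from the shifted
user (MAP, and MLLR at 100).

## Known limitations

* The protocol's stroke decompositions are plausible conventions; only
  the inventory sizes and the documented examples are normative.
* The decoder's history cap makes search inexact in principle; the
  default (32) showed no residual search errors on the synthetic suite.
* Witten-Bell is the only smoothing implemented.
* The hybrid scorer assumes frame-independent posteriors; no sequence
  discriminative training.
* MLLR uses a single regression class; no variance adaptation anywhere.
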