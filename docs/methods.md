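# Methods

`primflow` quantifies upper-extremity rehabilitation training by
decomposing wearable-sensor recordings into counted *functional
primitives*: reach, reposition and transport (motion primitives) and
stabilization and idle (minimal-motion primitives, distinguished by
grasp).  This note documents the models and procedures the package
implements, the assumptions behind them, and the choices made where the
design was genuinely open.

## Data model and preprocessing

A recording is a 77-channel series at 100 Hz: 27 linear accelerations
(9 sensors x 3 axes, g), 27 orientation components, 22 anatomical joint
angles (degrees) and a constant paretic-side flag.  Orientations are
stored as the 3-vector part of a unit quaternion per sensor with the
scalar part implied non-negative (`w = sqrt(1 - |v|^2)`), which is why
9 sensors occupy 27, not 36, columns.  Sample indices are 0-based with
half-open `[start, end)` intervals throughout.

Two preprocessing steps precede modeling:

* **Sensor-centric quaternion transform.**  Each sensor's orientation is
  re-expressed relative to a reference pose (`ref^-1 (x) q(t)`), so the
  channels describe rotation of the sensor about its own axes rather
  than absolute heading.  The reference defaults to the first sample of
  the recording and may be an explicit calibration record.  The double
  cover is fixed by keeping the scalar part non-negative.
* **Z-scoring.**  Per-channel mean/sd are estimated on training data
  only and applied everywhere; the flag channel passes through, and a
  floor of 1e-8 protects constant channels.

## Windowing

The sequence model reads 6-s windows and predicts the primitives of the
middle 4-s *core*; the 1-s flanks provide temporal context only.  At
training time windows slide by 0.5 s (data augmentation that also
exposes every core boundary placement); at test time the slide equals
the core so the cores partition the timeline exactly, with 1 s of zero
padding at the recording ends and a short trailing core when the
duration is not a multiple of 4 s.

A core's target sequence is the run-length collapse of its labels, with
one refinement: a primitive cut by an *internal* core boundary enters
the target only if at least 0.1 s of it falls inside the core.
Sub-perceptual edge fragments otherwise make targets noisy at every
boundary, and because 0.1 s is below half the shortest primitive
duration (0.3 s), every primitive still appears in at least one core —
so deduplicating counting remains exact (the invariant is tested).
Back-to-back same-class primitives merge under collapse; timing-free
sequences cannot distinguish them.  The synthetic grammar's zero
self-transition probability sidesteps this in generated data.

## The sequence model

The encoder is a three-layer bidirectional GRU of width H; the feature
vector is the concatenation of the final forward and backward top-layer
states (2H elements) and initializes a single-layer GRU decoder of width
2H.  The decoder starts from a start token and greedily emits primitive
tokens until an end token or 13 steps, with ties broken in the fixed
class order reach < reposition < transport < stabilization < idle.  The
published configuration uses H = 3072 and remains a config choice; the
desk default H = 64 trains on one CPU in minutes.  All recurrent
arithmetic is NumPy/numba with exact hand-derived backpropagation
(verified against finite differences); BLAS is pinned to one thread
because the recursion's many small matrix products are an order of
magnitude slower under a spinning multi-thread pool on single-core
machines.

Training minimizes teacher-forced token cross-entropy (padding masked,
end token appended) with Adam at learning rate 5e-4 by default.
Optional regularizers — decoupled weight decay, Gaussian input noise,
label smoothing, learning-rate decay on plateau — exist in the config
and default off.  Early stopping follows the overcounting-averse rule:
after each epoch, validation sensitivity/FDR/AER are computed; among
checkpoints whose FDR stays below 20%, the one with minimal AER (Action
Error Rate: edit distance normalized by ground-truth length) is kept,
falling back to plain minimum AER if none qualifies; training stops
after `patience` epochs without improvement.  AER charges insertions
and deletions symmetrically, so this choice keeps over- and
under-emission balanced — maximizing sensitivity under the FDR cap
instead was measured to select systematically over-emitting
checkpoints, the failure mode the FDR priority exists to avoid.
Validation metrics are computed at *trial* granularity — per-window
sequences are merged with the deduplication rule and aligned against
merged targets — matching how the pipeline is ultimately scored.
Training windows additionally include each recording's trailing
short-core window (the zero-filled edge geometry that otherwise appears
only at test time); leaving it out produced spurious emissions in
trailing windows.

The ensemble trains one model per subject-level cross-validation fold
(k = 4; roughly 75/25 subject splits under a seeded rotation).  At
prediction time the four per-step probability vectors are averaged, the
argmax token is emitted, and that token is fed back as the
previous-token input to all four decoders.  Each member stores its own
normalization statistics and applies them before encoding.

## Counting

Per-window sequences are concatenated in core order; whenever the last
element of one window equals the first element of the next, the pair is
merged into one counted instance (a primitive spanning three cores
merges pairwise and counts once).  Within-window repeats are never
merged.  Two genuinely distinct same-class primitives meeting exactly
at a core boundary are incorrectly merged — an inherent limitation of
timing-free sequences, accepted and documented.  Counting accuracy is
summarized as percent error `100*(predicted - true)/true` (negative =
undercount) and percent-of-true `100*predicted/true`; cells with zero
true count are flagged and excluded.  (The study this package follows
prints the opposite sign for counting error; the package uses
negative-means-undercount.)

## Evaluation

Predicted and true sequences are aligned per activity trial with a
unit-cost Levenshtein dynamic program.  Among equal-cost scripts the
operation list is made deterministic by walking forward from the
sequence starts over a suffix-distance table with tie preference
match > substitution > deletion > insertion.  Matches are true
positives; deletions and swap-outs (the ground-truth side of a
substitution) are the false-negative modes; insertions and swap-ins
(the predicted side) are the false-positive modes.  Summary metrics:
sensitivity TP/(TP+FN), FDR FP/(TP+FP), F1 = 2 s (1-f)/(s+(1-f)) =
2TP/(2TP+FN+FP), AER.  The confusion matrix normalizes by ground-truth
class counts; each row's diagonal, off-diagonals and deletion margin
sum to 1.

Model comparison bootstraps per-trial (TP, FN, FP) tallies: each of 250
replicates draws 81 trials with replacement (the same draw for every
model), aggregates, and computes the metrics; rivals are compared to
the reference with unpaired two-tailed t-tests (df = 2x250-2 = 498)
under Bonferroni correction over the number of rivals.

## Baselines

The pointwise benchmark is a random forest over per-channel statistics
(mean, max, min, sd, RMS; population convention, so RMS^2 = mean^2 +
sd^2) computed on 1-s sub-windows at 0.1-s stride and propagated to
every 10-ms step by nearest-center assignment (the sub-window geometry
is this package's choice; the study does not state one).  Probability
tracks are smoothed with a normalized Kaiser window (odd size; shape
parameter set by the relative sidelobe attenuation), reflection padding
at the edges, rows renormalized; window size and attenuation are chosen
by grid search maximizing sequence-level validation F1 (ties prefer the
smallest window).  Argmax plus run-length collapse over each core then
yields sequences that enter the same counting and evaluation machinery.

## Synthetic data

The generator emulates labeled sessions so the full pipeline trains and
evaluates without patient recordings.  A first-order Markov grammar per
synthetic activity (two defaults, "tabletop" and "shelf") strings
primitives together; durations are log-normal per class (medians 0.9-
1.8 s, truncated to [0.3, 5] s); the last segment truncates so segments
tile the trial exactly.  Motion primitives render minimum-jerk speed
bells, `v(tau) = 16 tau^2 (1-tau)^2`, on class-specific sensors of the
paretic side — reach is hand-dominant, reposition forearm-dominant,
transport whole-arm plus trunk, a deliberate stylization that keeps
class signatures well separated.  Orientation and angle channels carry
matching smooth excursions on top of constant per-trial calibration
baselines.  Quiescent classes render Gaussian sensor noise only;
stabilization additionally carries a grasp surrogate (constant 0.25
offset on a hand-orientation component plus a 10-degree wrist-flexion
posture), standing in for the finger data the sensor array lacks —
shrinking the offset toward zero reproduces the stabilization/idle
confusion seen with real recordings.  Defaults: acceleration noise
0.05 g, orientation noise 0.01, angle noise 0.5 degrees, no drift.

Default study conditions: 11 subjects (paretic side alternating), 7
trials each of 30 s — a realistic single-activity trial length — split
6/1/4 by subject, i.e. 42 training trials with roughly 1,000 labeled
primitives and a 28-trial held-out test set (~650 primitives, so
per-class counting error is measured on 80–170 counts per class rather
than being dominated by small-sample noise).  A single integer seed
reproduces the dataset bit for bit.

What the generator does **not** emulate: impairment-dependent kinematic
abnormality, object-specific motion, compensatory trunk strategies,
electromagnetic drift dynamics (only a linear optional drift), or
human labeling noise.  Passing tests on synthetic data therefore show
the pipeline's machinery is correct and trainable, not that the
desk-scale model would reach the published accuracy on patient data.

## Desk-scale protocol and problem sizes

The end-to-end experiment used by the test suite trains the 4-fold
ensemble at H = 64, batch 16, learning rate 3e-3 (up-scaled from the
published 5e-4: the desk model is ~50x narrower and the schedule — 4
epochs per fold — is short, so convergence has to happen in a few
hundred updates), on the default dataset above, and evaluates on the
four held-out test subjects (28 trials).  This trains in roughly a
quarter of an hour on one CPU.  The Levenshtein oracle suite samples
all sequence pairs up to length 4 exhaustively and 10,000 random longer
pairs; counting exactness uses 50 synthetic recordings; the bootstrap
machinery runs at its published size (250 replicates).

One benchmark observation deserves emphasis: on the synthetic data the
random-forest-plus-smoothing baseline *outperforms* the desk-scale
sequence model (sequence F1 near 0.99 versus ~0.90).  The synthetic
phenotypes are deliberately separable at every 10-ms step — the
generator's feasibility invariant guarantees it — so a pointwise
classifier with full temporal resolution is close to ceiling, while the
timing-free sequence decoder pays for its 128-element bottleneck.  The
published ordering (sequence model ahead of the random forest) belongs
to real recordings, where pointwise classification is genuinely hard;
reproducing that ordering is not a property of this synthetic task, and
the corresponding directional test is expected to fail honestly at desk
scale.

## Known limitations

* Timing-free sequences cannot separate back-to-back same-class
  primitives or attribute durations; duration and kinematic-quality
  estimation are out of scope.
* The deduplication rule can merge distinct same-class primitives that
  abut exactly at a core boundary.
* At H = 64 the 128-element feature vector is a tight bottleneck; very
  dense cores (more than ~6 primitives per 4 s) are decoded less
  reliably than the published full-width model would.
* The alignment's error taxonomy depends on the deterministic tie rule;
  equal-cost alignments with different tallies exist, so tallies are
  comparable only under this fixed rule.
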