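# primflow

Counting functional motion primitives in upper-extremity rehabilitation
from wearable-sensor recordings.

Stroke rehabilitation trains activities of daily living, but the dose
that matters — how many functional motions were actually practiced —
is rarely measured, because counting them by hand is prohibitively
slow.  `primflow` implements a pipeline that does it automatically from
a nine-sensor inertial measurement unit (IMU) array: a 77-channel,
100 Hz recording is cut into 6-s windows, a GRU encoder–decoder
(sequence-to-sequence) model predicts the sequence of *functional
primitives* performed in the middle 4 s of each window, and a counting
algorithm removes duplicate primitives at window boundaries and tallies
the rest.  The five primitive classes are **reach**, **reposition**,
**transport** (motion primitives) and **stabilization**, **idle**
(minimal-motion primitives, distinguished by grasp).

The package contains, as first-class tested components:

* `imu_data` — the 77-channel data model, delimited-text I/O,
  sensor-centric quaternion transformation, z-score normalization,
  segment/label handling and the window/core/flank scheme;
* `synthetic_motion` — a seeded generator of labeled synthetic sessions
  (Markov primitive grammar + minimum-jerk kinematic phenotypes) so the
  whole pipeline trains and evaluates without patient data;
* `seq2seq_model` — the 3-layer bidirectional GRU encoder (width H,
  feature vector 2H) and single-layer GRU decoder (width 2H), exact
  NumPy backpropagation, teacher-forced training with
  Action-Error-Rate-based early stopping under an FDR < 20% priority,
  and the 4-fold cross-validated ensemble with averaged probabilities
  and token feedback;
* `counting` — boundary-deduplicating tallies and counting-error
  summaries;
* `evaluation` — Levenshtein alignment with the
  deletion / swap-out / insertion / swap-in error taxonomy, sensitivity,
  FDR, F1, AER, confusion matrices, and bootstrap model comparison
  (unpaired t-tests, df = 2·replicates − 2, Bonferroni);
* `baselines` — a statistical-feature random forest emitting pointwise
  predictions, Kaiser-window smoothing, and pointwise-to-sequence
  conversion for benchmarking.

The key metrics, for predicted vs. ground-truth primitive sequences
aligned per activity trial:

    sensitivity = TP / (TP + FN)        FDR = FP / (TP + FP)
    F1  = 2·s·(1−f) / (s + (1−f))  =  2TP / (2TP + FN + FP)
    AER = edit_distance(pred, truth) / |truth|

where a false negative is a deletion or swap-out and a false positive
is an insertion or swap-in.

## Worked example

```python
import primflow as pf
from primflow import seq2seq_model as s2s

# a labeled synthetic study: 11 subjects x 7 trials x 30 s, split 6/1/4
dataset = pf.generate_dataset(pf.SyntheticConfig(seed=2024))

# train the 4-fold ensemble at desk scale (H=64)
config = s2s.ModelConfig(hidden=64, seed=13, learning_rate=3e-3,
                         batch_size=16, max_epochs=4, patience=4)
ensemble = s2s.cross_validated_train(dataset.subset("train"), config, k=4)

# predict, dedup-count and evaluate the held-out subjects
pairs, rows = [], []
for trial in dataset.subset("test"):
    window_seqs = s2s.predict_recording(ensemble, trial.recording)
    merged = tuple(pf.merge_window_sequences(window_seqs))
    pairs.append((pf.collapse_to_sequence(trial.labels), merged))
    true = {c: 0 for c in pf.CLASSES}
    for seg in trial.segments:
        true[seg.klass] += 1
    rows.append({"subject": trial.recording.subject_id,
                 "activity": trial.recording.activity_id,
                 "predicted": pf.dedup_and_count(window_seqs),
                 "true": true})
report = pf.evaluate_sequences(pairs)
print(f"sensitivity {report.sensitivity:.3f}  FDR {report.fdr:.3f} "
      f"F1 {report.f1:.3f}  AER {report.aer:.3f}")
print(pf.build_count_report(rows).per_class[["predicted", "true",
                                             "percent_error"]])
```

On the fixed seeds above this prints (elapsed ≈ 16 min on one CPU):

```
sensitivity 0.914  FDR 0.110  F1 0.902  AER 0.174
               predicted  true  percent_error
class
reach                178   168       5.952381
reposition           146   151      -3.311258
transport            127   123       3.252033
stabilization         84    78       7.692308
idle                 145   142       2.112676
```

Sensitivity is the fraction of truly performed primitives the ensemble
recovered; FDR the fraction of predicted primitives that were spurious
(overcounting); the per-class counting errors show the tallies a
therapist would read off are within a few percent of truth on held-out
subjects.  Shorter narrative examples live in `examples/`.

A command-line layer wraps the same pipeline
(`primflow simulate | train | count | evaluate | benchmark`); run
`primflow --help`.

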