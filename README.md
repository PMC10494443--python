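# somnoscore

Automatic sleep-stage scoring for single-channel EEG with a two-stage
CNN + bidirectional-LSTM model, partial sliding-window data
augmentation, outer-product residual fusion, and an adaptive
cross-entropy loss whose class weights track per-class training
F1-scores.  A seeded synthetic sleep-EEG generator lets the entire
pipeline run and be validated without clinical data.

## The problem

Clinical sleep studies are scored by hand: an expert reads the night
in 30-second epochs and labels each one Wake, N1, N2, N3 or REM.
Automating this from a *single* EEG channel is attractive wherever
full polysomnography is impractical, but it is hard for two
structural reasons:

* **Stage identity is contextual.**  N1 and REM show very similar
  mixed-frequency theta activity within a single epoch; human scorers
  separate them mostly from the surrounding epochs.  A purely
  per-epoch classifier hits a ceiling here.
* **Stages are heavily imbalanced.**  N1 is typically a few percent
  of the night, so a plain cross-entropy learner can score high
  accuracy while never predicting it at all.

`somnoscore` addresses the first with a two-stage model — a 1-D CNN
turns each epoch into a 256-d feature, then a 2-layer bidirectional
LSTM reads 30-epoch feature sequences and fuses its 512-d output with
the per-epoch feature via an outer-product residual — and the second
with a loss whose per-class weights grow as
`W = 1 − 3·log₁₀(F1)` whenever a class's training F1 drops, after a
warm-up third of training with uniform weights.  Stage-2 training
data is quadrupled by re-slicing each recording on grids shifted by
1, 2 and 3 seconds.  See [docs/methods.md](docs/methods.md) for the
full description.

Everything — models, gradients, Adam — runs on NumPy via a small
bundled reverse-mode autodiff core, so the only heavy dependencies
are the standard scientific Python stack and MNE for EDF I/O.

## Worked example (Python API)

Train on three synthetic subjects and score a held-out fourth.
Runs in a couple of minutes on one CPU core.

```python
from somnoscore import (
    SyntheticSpec, TrainConfig, generate_subjects, split_train_val,
    train_cnn, train_bilstm, cnn_from_checkpoint, bilstm_from_checkpoint,
    predict_two_stage, score,
)
from somnoscore.io import epoch_signal

spec = SyntheticSpec(n_epochs=200, seed=0)          # 200 x 30 s per subject
pairs = generate_subjects(spec, n_subjects=4)       # (Recording, Hypnogram) pairs
train_pool, test_pair = pairs[:3], pairs[3]

# short schedule + matching stage-2 learning rate for a small demo
cfg = TrainConfig(e_max=9, seq_len=10, lstm_lr=1e-3, val_fraction=0.34, seed=0)
tr, va = split_train_val(train_pool, cfg.val_fraction, seed=0)
cnn_ckpt, _ = train_cnn(tr, va, cfg)                # stage 1: per-epoch CNN
lstm_ckpt, _ = train_bilstm(tr, va, cnn_ckpt, cfg)  # stage 2: bi-LSTM + fusion

cnn = cnn_from_checkpoint(cnn_ckpt)
lstm = bilstm_from_checkpoint(lstm_ckpt)
test = epoch_signal(*test_pair)
pred = predict_two_stage(cnn, lstm, test, cfg.seq_len)
rep = score(test.label_indices, pred)
print(f"accuracy {rep.accuracy:.3f}  macro-F1 {rep.macro_f1:.3f}  kappa {rep.kappa:.3f}")
print("per-class F1:", {s: round(float(v), 3)
                        for s, v in zip(("Wake", "N1", "N2", "N3", "REM"), rep.per_class_f1)})
```

Output:

```
accuracy 0.900  macro-F1 0.827  kappa 0.862
per-class F1: {'Wake': 0.971, 'N1': 0.444, 'N2': 0.918, 'N3': 0.959, 'REM': 0.841}
```

N1 is the hardest class by design: the generator gives N1 and REM
nearly identical single-epoch spectra, so only the sequence stage can
tell them apart — the same bottleneck real scorers face.

## Command line

The same pipeline is available as a CLI (`somnoscore --help`).  A
full round trip on synthetic fixtures:

```bash
somnoscore simulate --out-dir data --n-subjects 4 --n-epochs 200 --seed 0
somnoscore train    --data-dir data --out-dir model --seq-len 10 --e-max 9 --seed 0
somnoscore predict  --edf data/S03.edf --model-dir model --out pred.csv
somnoscore evaluate --predictions pred.csv --reference data/S03_hypnogram.csv
somnoscore cv       --data-dir data --out-dir cv --mode loso --seq-len 10 --e-max 9
```

`simulate` writes EDF recordings with companion hypnogram CSVs;
`train` writes `cnn.npz` / `bilstm.npz` checkpoints plus per-epoch
training logs; every artifact-producing command writes a
`manifest.json` with the resolved configuration and seed so the run
can be reproduced exactly.  Real EDF recordings work the same way:
point `--data-dir` at EDF files with companion `*_hypnogram.csv`
label files (R&K labels are mapped to AASM automatically, and
movement/unknown epochs are excluded).

## Scope and limits

The synthetic generator is phenomenological (Markov hypnogram +
band-limited oscillations + noise); results on it validate the
implementation, not clinical performance.  No artifact handling,
no multi-channel fusion, and the bundled NumPy training loop is
CPU-bound — it is sized for method validation and small studies, not
for training on large overnight archives.
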