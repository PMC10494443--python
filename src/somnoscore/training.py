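"""Two-stage training: epoch CNN first, then the bi-LSTM on its features.

Stage 1 trains the CNN on single, unaugmented 30-s epochs (Adam,
lr 1e-3, batch 128, weight decay 1e-4).  Stage 2 freezes the CNN by
default, extracts evaluation-mode features from the 4-shift augmented
epoch series, and trains the recurrent model + fusion head on tiled
length-L feature sequences (Adam, lr 1e-4, batch 64, weight decay
1e-5).  Both stages run e_max epochs of the adaptive cross-entropy
schedule (warm-up for the first e_max/3 epochs, then F1-driven class
weights recomputed each epoch from predictions accumulated during the
epoch), validate every epoch on a held-out subject-level split, and
keep the parameters with the best validation macro-F1.

Evaluation and validation always consume unshifted (shift-0) data; the
augmented series feed training only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .augmentation import shift_series
from .bilstm import LSTMConfig, SequenceModel, build_bilstm
from .cnn import CNNConfig, EpochCNN, build_cnn, cnn_features, softmax
from .evaluation import ConfusionMatrix, confusion, metrics, per_class_f1
from .io import EpochedDataset, Hypnogram, Recording, STAGES, epoch_signal
from .loss import AdaptiveLossState, adaptive_ce_from_logits, onehot, update_state


class DivergenceError(RuntimeError):
    """Non-finite loss encountered during training."""


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Hyperparameters of the two-stage training run."""

    cnn_lr: float = 1e-3
    cnn_batch: int = 128
    cnn_weight_decay: float = 1e-4
    lstm_lr: float = 1e-4
    lstm_batch: int = 64
    lstm_weight_decay: float = 1e-5
    e_max: int = 30
    val_fraction: float = 0.10
    seed: int = 0
    repeats: int = 5
    seq_len: int = 30
    augment: bool = True
    fusion: bool = True
    finetune_cnn: bool = False
    alpha: float = 0.1
    K_base: float = 10.0
    gamma: float = 3.0
    floor: float = 1e-4

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")

    def loss_state(self) -> AdaptiveLossState:
        return AdaptiveLossState(
            e_max=self.e_max, alpha=self.alpha, K_base=self.K_base, gamma=self.gamma, floor=self.floor
        )


@dataclass
class FoldPlan:
    """Subject-level cross-validation layout."""

    mode: str  # "loso" | "kfold"
    folds: list  # list of lists of subject ids (each is one test fold)
    repeat_seeds: list

    def __post_init__(self):
        flat = [s for fold in self.folds for s in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("a subject appears in more than one test fold")
        if any(len(f) == 0 for f in self.folds):
            raise ValueError("empty test fold")

    @classmethod
    def loso(cls, subject_ids, repeats: int = 1, seed: int = 0) -> "FoldPlan":
        return cls(
            mode="loso",
            folds=[[s] for s in subject_ids],
            repeat_seeds=[_child_seed(seed, 7000 + r) for r in range(repeats)],
        )

    @classmethod
    def kfold(cls, subject_ids, k: int, repeats: int = 1, seed: int = 0) -> "FoldPlan":
        ids = list(subject_ids)
        rng = np.random.default_rng(_child_seed(seed, 7999))
        rng.shuffle(ids)
        folds = [list(f) for f in np.array_split(ids, k)]
        return cls(
            mode="kfold",
            folds=folds,
            repeat_seeds=[_child_seed(seed, 7000 + r) for r in range(repeats)],
        )


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with decoupled-from-schedule L2 weight decay added to gradients."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    kind: str  # "cnn" | "bilstm"
    state: dict
    config: dict
    best_epoch: int = 0
    val_macro_f1: float = 0.0


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    meta = json.dumps(
        {"kind": ckpt.kind, "config": ckpt.config, "best_epoch": ckpt.best_epoch,
         "val_macro_f1": ckpt.val_macro_f1}
    )
    np.savez(path, __meta=np.frombuffer(meta.encode(), dtype=np.uint8), **ckpt.state)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta"}
    return Checkpoint(kind=meta["kind"], state=state, config=meta["config"],
                      best_epoch=meta["best_epoch"], val_macro_f1=meta["val_macro_f1"])


def cnn_from_checkpoint(ckpt: Checkpoint, dtype=np.float32) -> EpochCNN:
    model = build_cnn(CNNConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in ckpt.config.items()}), dtype=dtype)
    model.load_state_dict(ckpt.state)
    return model


def bilstm_from_checkpoint(ckpt: Checkpoint, dtype=np.float32) -> SequenceModel:
    model = build_bilstm(LSTMConfig(**ckpt.config), dtype=dtype)
    model.load_state_dict(ckpt.state)
    return model


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _subject_of(item) -> str:
    if isinstance(item, tuple):
        return item[0].subject_id
    return item.subject_id


def _as_epoched(item) -> EpochedDataset:
    if isinstance(item, tuple):
        return epoch_signal(item[0], item[1])
    return item


def split_train_val(pool: list, fraction: float = 0.10, seed: int = 0):
    """Subject-level random split of a pool of recordings/datasets.

    Validation subjects are held out whole; with a single subject the
    split degrades to a contiguous sequence-level split with a warning.
    """
    if not pool:
        raise ValueError("empty pool")
    subjects = sorted({_subject_of(x) for x in pool})
    if len(subjects) == 1:
        warnings.warn("single-subject pool: falling back to sequence-level split", stacklevel=2)
        train, val = [], []
        for item in pool:
            ds = _as_epoched(item)
            cut = max(1, int(round(len(ds) * (1 - fraction))))
            cut = min(cut, len(ds) - 1)
            train.append(EpochedDataset(ds.epochs[:cut], ds.labels[:cut], ds.fs, ds.subject_id))
            val.append(EpochedDataset(ds.epochs[cut:], ds.labels[cut:], ds.fs, ds.subject_id))
        return train, val
    rng = np.random.default_rng(_child_seed(seed, 101))
    n_val = min(len(subjects) - 1, max(1, int(round(len(subjects) * fraction))))
    val_subjects = set(rng.choice(subjects, size=n_val, replace=False))
    train = [x for x in pool if _subject_of(x) not in val_subjects]
    val = [x for x in pool if _subject_of(x) in val_subjects]
    return train, val


def _stack_epochs(items: list) -> tuple[np.ndarray, np.ndarray, int]:
    dss = [_as_epoched(x) for x in items]
    fs = dss[0].fs
    X = np.concatenate([d.epochs for d in dss], axis=0)
    y = np.concatenate([d.label_indices for d in dss])
    return X, y, fs


# ---------------------------------------------------------------------------
# stage 1: CNN
# ---------------------------------------------------------------------------


def _log_record(e, losses, state, train_f1, val_f1):
    rec = {"epoch": e, "loss": float(np.mean(losses)), "val_macro_f1": val_f1}
    for i, s in enumerate(STAGES):
        rec[f"W_{s}"] = float(state.effective_weights[i])
        rec[f"f1_{s}"] = float(train_f1[i])
    return rec


def train_cnn(
    train: list,
    val: list,
    cfg: TrainConfig,
    cnn_cfg: CNNConfig | None = None,
    dtype=np.float32,
) -> tuple[Checkpoint, pd.DataFrame]:
    """Pre-train the epoch CNN on single epochs; checkpoint best val macro-F1."""
    Xtr, ytr, fs = _stack_epochs(train)
    Xva, yva, _ = _stack_epochs(val)
    cnn_cfg = cnn_cfg or CNNConfig(fs=fs)
    model = build_cnn(cnn_cfg, seed=_child_seed(cfg.seed, 201), dtype=dtype)
    opt = Adam(model.params, lr=cfg.cnn_lr, weight_decay=cfg.cnn_weight_decay)
    state = cfg.loss_state()
    shuffle_rng = np.random.default_rng(_child_seed(cfg.seed, 202))
    drop_rng = np.random.default_rng(_child_seed(cfg.seed, 203))

    best = (-np.inf, None, 0)
    records = []
    for e in range(1, cfg.e_max + 1):
        perm = shuffle_rng.permutation(len(Xtr))
        losses, preds = [], np.empty(len(Xtr), dtype=np.int64)
        for lo in range(0, len(Xtr), cfg.cnn_batch):
            idx = perm[lo : lo + cfg.cnn_batch]
            _, logits = model.forward(Xtr[idx], train=True, rng=drop_rng)
            lossT = adaptive_ce_from_logits(logits, onehot(ytr[idx]), state)
            if not np.isfinite(lossT.data):
                raise DivergenceError(f"non-finite loss at training epoch {e}")
            opt.zero_grad()
            lossT.backward()
            opt.step()
            losses.append(float(lossT.data))
            preds[idx] = logits.data.argmax(axis=1)
        train_f1 = per_class_f1(ytr, preds)
        val_f1 = metrics(confusion(yva, _predict_epochs_array(model, Xva))).macro_f1
        records.append(_log_record(e, losses, state, train_f1, val_f1))
        if val_f1 > best[0]:
            best = (val_f1, model.state_dict(), e)
        state = update_state(state, train_f1)
    model.load_state_dict(best[1])
    ckpt = Checkpoint("cnn", best[1], model.config_dict(), best[2], float(best[0]))
    return ckpt, pd.DataFrame(records)


def _predict_epochs_array(model: EpochCNN, X: np.ndarray, batch: int = 256) -> np.ndarray:
    out = [model.forward(X[i : i + batch])[1].data.argmax(axis=1) for i in range(0, len(X), batch)]
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def predict_cnn(model: EpochCNN, ds: EpochedDataset) -> np.ndarray:
    """Stage indices from the standalone CNN (evaluation mode)."""
    if ds.fs != model.cfg.fs:
        raise ValueError(f"sampling-rate mismatch: model fs={model.cfg.fs}, data fs={ds.fs}")
    return _predict_epochs_array(model, ds.epochs)


# ---------------------------------------------------------------------------
# stage 2: bi-LSTM
# ---------------------------------------------------------------------------


def _pair_series(item, augment: bool) -> list[EpochedDataset]:
    """Epoch series for one recording: 4 shifts if augmenting, else shift-0."""
    if isinstance(item, tuple):
        rec, hyp = item
        if augment and not np.any(hyp.exclude):
            return shift_series(rec, hyp)
        if augment:
            warnings.warn("recording has excluded epochs; augmentation skipped", stacklevel=2)
        return [epoch_signal(rec, hyp)]
    if augment:
        warnings.warn(
            "augmentation needs continuous recordings; got pre-epoched data, using shift-0 only",
            stacklevel=2,
        )
    return [item]


def _tile_sequences(arrs: list[np.ndarray], labels: list[np.ndarray], L: int):
    """Tile per-series feature/label arrays into (S, L, ...) blocks."""
    seqs, labs = [], []
    for a, y in zip(arrs, labels):
        for b in range(len(a) // L):
            seqs.append(a[b * L : (b + 1) * L])
            labs.append(y[b * L : (b + 1) * L])
    if not seqs:
        raise ValueError(f"no series long enough for sequences of L={L}")
    return np.stack(seqs), np.stack(labs)


def train_bilstm(
    train: list,
    val: list,
    cnn_ckpt: Checkpoint,
    cfg: TrainConfig,
    dtype=np.float32,
) -> tuple[Checkpoint, pd.DataFrame]:
    """Train the sequence model on (augmented) CNN feature sequences.

    The CNN runs in evaluation mode; its weights stay frozen unless
    ``cfg.finetune_cnn`` is set, in which case gradients flow through it
    and both models are updated (the returned checkpoint then embeds the
    updated CNN state under ``cnn.``-prefixed keys).
    """
    cnn = cnn_from_checkpoint(cnn_ckpt, dtype=dtype)
    L = cfg.seq_len
    lstm_cfg = LSTMConfig(seq_len=L, lr=cfg.lstm_lr, batch=cfg.lstm_batch,
                          weight_decay=cfg.lstm_weight_decay, fusion=cfg.fusion)
    model = build_bilstm(lstm_cfg, seed=_child_seed(cfg.seed, 301), dtype=dtype)

    train_series = [s for item in train for s in _pair_series(item, cfg.augment)]
    lab_list = [s.label_indices for s in train_series]
    feats_list = [cnn_features(cnn, s) for s in train_series]
    all_feats = np.concatenate(feats_list, axis=0)
    model.set_standardizer(all_feats.mean(axis=0), all_feats.std(axis=0))
    raw_seqs = feat_seqs = None
    if cfg.finetune_cnn:
        raw_seqs, lab_seqs = _tile_sequences([s.epochs for s in train_series], lab_list, L)
    else:
        feat_seqs, lab_seqs = _tile_sequences(feats_list, lab_list, L)
    val_series = [_as_epoched(item) for item in val]  # shift-0 only
    val_feat_list = [cnn_features(cnn, s) for s in val_series]
    val_labels = np.concatenate([s.label_indices for s in val_series])

    params = dict(model.params)
    if cfg.finetune_cnn:
        params.update({f"cnn.{k}": v for k, v in cnn.params.items()})
    opt = Adam(params, lr=cfg.lstm_lr, weight_decay=cfg.lstm_weight_decay)
    state = cfg.loss_state()
    shuffle_rng = np.random.default_rng(_child_seed(cfg.seed, 302))
    drop_rng = np.random.default_rng(_child_seed(cfg.seed, 303))

    n_seq = len(lab_seqs)
    best = (-np.inf, None, 0)
    records = []
    for e in range(1, cfg.e_max + 1):
        perm = shuffle_rng.permutation(n_seq)
        losses = []
        preds = np.empty(lab_seqs.shape, dtype=np.int64)
        for lo in range(0, n_seq, cfg.lstm_batch):
            idx = perm[lo : lo + cfg.lstm_batch]
            if cfg.finetune_cnn:
                B = len(idx)
                flat = raw_seqs[idx].reshape(B * L, -1)
                feat, _ = cnn.forward(flat, train=False)
                x_in = feat.reshape(B, L, -1)
            else:
                x_in = feat_seqs[idx]
            logits = model.forward(x_in, train=True, rng=drop_rng)
            lossT = adaptive_ce_from_logits(logits, _onehot_seq(lab_seqs[idx]), state)
            if not np.isfinite(lossT.data):
                raise DivergenceError(f"non-finite loss at training epoch {e}")
            opt.zero_grad()
            lossT.backward()
            opt.step()
            losses.append(float(lossT.data))
            preds[idx] = logits.data.argmax(axis=-1)
        train_f1 = per_class_f1(lab_seqs.ravel(), preds.ravel())
        val_pred = np.concatenate([_predict_feature_series(model, f, L) for f in val_feat_list])
        val_f1 = metrics(confusion(val_labels, val_pred)).macro_f1
        records.append(_log_record(e, losses, state, train_f1, val_f1))
        if val_f1 > best[0]:
            snap = model.state_dict()
            if cfg.finetune_cnn:
                snap.update({f"cnn.{k}": v for k, v in cnn.state_dict().items()})
            best = (val_f1, snap, e)
        state = update_state(state, train_f1)
    model.load_state_dict({k: v for k, v in best[1].items() if not k.startswith("cnn.")})
    ckpt = Checkpoint("bilstm", best[1], model.config_dict(), best[2], float(best[0]))
    return ckpt, pd.DataFrame(records)


def _onehot_seq(lab: np.ndarray, n_classes: int = 5) -> np.ndarray:
    out = np.zeros(lab.shape + (n_classes,))
    np.put_along_axis(out, lab[..., None], 1.0, axis=-1)
    return out


def _predict_feature_series(model: SequenceModel, feats: np.ndarray, L: int) -> np.ndarray:
    """Predict one stage index per epoch from a (E, 256) feature series.

    Consecutive blocks of L epochs; a trailing remainder is covered by one
    overlapping final window whose leading predictions are discarded.  A
    series shorter than L is scored as a single short window.
    """
    E = feats.shape[0]
    if E == 0:
        return np.empty(0, dtype=np.int64)
    if E < L:
        return _predict_sequences(model, feats[None])[0]
    n_full = E // L
    pred = _predict_sequences(model, feats[: n_full * L].reshape(n_full, L, -1)).reshape(-1)
    r = E - n_full * L
    if r:
        tail = _predict_sequences(model, feats[E - L :][None])[0]
        pred = np.concatenate([pred, tail[-r:]])
    return pred


def _predict_sequences(model: SequenceModel, feat_seqs: np.ndarray, batch: int = 128) -> np.ndarray:
    out = [
        model.forward(feat_seqs[i : i + batch]).data.argmax(axis=-1)
        for i in range(0, len(feat_seqs), batch)
    ]
    return np.concatenate(out, axis=0)


def predict_two_stage(cnn: EpochCNN, lstm: SequenceModel, ds: EpochedDataset, L: int) -> np.ndarray:
    """Per-epoch stage indices for one recording (shift-0 only).

    Epochs are scored in consecutive blocks of L; a trailing remainder
    is covered by one overlapping final window (its first predictions
    are discarded), so every epoch receives exactly one label.
    """
    return _predict_feature_series(lstm, cnn_features(cnn, ds), L)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def run_cv(
    pairs: list,
    plan: FoldPlan,
    cfg: TrainConfig,
    cnn_cfg: CNNConfig | None = None,
) -> dict:
    """Nested subject-level cross-validation of the full two-stage model.

    For each repeat and fold: inner 90:10 subject split, two-stage
    training, testing on the held-out subjects (shift-0 data only).
    Returns per-fold reports, the pooled confusion matrix, and the mean
    and standard deviation of the overall metrics across repeats.
    """
    by_subject = {}
    for item in pairs:
        by_subject.setdefault(_subject_of(item), []).append(item)
    missing = [s for fold in plan.folds for s in fold if s not in by_subject]
    if missing:
        raise ValueError(f"fold subjects not in data: {missing}")
    if len(by_subject) < 2:
        raise ValueError("cross-validation needs at least 2 subjects")

    repeat_summaries, fold_reports = [], []
    pooled = None
    for r, rseed in enumerate(plan.repeat_seeds):
        y_true_all, y_pred_all = [], []
        for f, test_subjects in enumerate(plan.folds):
            test_items = [x for s in test_subjects for x in by_subject[s]]
            train_pool = [x for s, items in by_subject.items() if s not in test_subjects for x in items]
            fold_cfg = TrainConfig(**{**asdict(cfg), "seed": _child_seed(cfg.seed, 5000 + 97 * r + f)})
            tr, va = split_train_val(train_pool, cfg.val_fraction, seed=fold_cfg.seed)
            cnn_ckpt, _ = train_cnn(tr, va, fold_cfg, cnn_cfg)
            lstm_ckpt, _ = train_bilstm(tr, va, cnn_ckpt, fold_cfg)
            cnn = cnn_from_checkpoint(cnn_ckpt)
            lstm = bilstm_from_checkpoint(lstm_ckpt)
            for item in test_items:
                ds = _as_epoched(item)
                pred = predict_two_stage(cnn, lstm, ds, cfg.seq_len)
                y_true_all.append(ds.label_indices)
                y_pred_all.append(pred)
                rep = metrics(confusion(ds.label_indices, pred))
                fold_reports.append(
                    {"repeat": r, "fold": f, "subject": ds.subject_id,
                     "macro_f1": rep.macro_f1, "accuracy": rep.accuracy, "kappa": rep.kappa}
                )
        cm = confusion(np.concatenate(y_true_all), np.concatenate(y_pred_all))
        pooled = cm if pooled is None else pooled + cm
        rep = metrics(cm)
        repeat_summaries.append(
            {"repeat": r, "macro_f1": rep.macro_f1, "accuracy": rep.accuracy, "kappa": rep.kappa}
        )
    df = pd.DataFrame(repeat_summaries)
    summary = {
        m: {"mean": float(df[m].mean()), "std": float(df[m].std(ddof=0))}
        for m in ("macro_f1", "accuracy", "kappa")
    }
    return {
        "summary": summary,
        "repeats": repeat_summaries,
        "per_subject": fold_reports,
        "pooled_confusion": pooled,
        "pooled_metrics": metrics(pooled),
    }
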