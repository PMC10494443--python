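"""Splits, checkpoints, the two training stages and cross-validation."""

import numpy as np
import pytest

from somnoscore import (
    CNNConfig,
    FoldPlan,
    SyntheticSpec,
    TrainConfig,
    bilstm_from_checkpoint,
    cnn_from_checkpoint,
    generate_subjects,
    load_checkpoint,
    predict_cnn,
    predict_two_stage,
    run_cv,
    save_checkpoint,
    split_train_val,
    train_bilstm,
    train_cnn,
)
from somnoscore.io import epoch_signal


@pytest.fixture(scope="module")
def tiny_pairs():
    """Three short synthetic subjects for fast training smoke tests."""
    return generate_subjects(SyntheticSpec(n_epochs=30, seed=77), 3)


@pytest.fixture(scope="module")
def tiny_cfg():
    return TrainConfig(e_max=3, seed=5, seq_len=5, val_fraction=0.34)


@pytest.fixture(scope="module")
def trained(tiny_pairs, tiny_cfg):
    tr, va = split_train_val(tiny_pairs, tiny_cfg.val_fraction, seed=5)
    cnn_ckpt, cnn_log = train_cnn(tr, va, tiny_cfg)
    lstm_ckpt, lstm_log = train_bilstm(tr, va, cnn_ckpt, tiny_cfg)
    return tr, va, cnn_ckpt, cnn_log, lstm_ckpt, lstm_log


class TestSplit:
    def test_subject_level_counts(self):
        pairs = generate_subjects(SyntheticSpec(n_epochs=2, seed=1), 20)
        tr, va = split_train_val(pairs, 0.10, seed=0)
        assert len(tr) == 18 and len(va) == 2

    def test_no_subject_leakage(self):
        pairs = generate_subjects(SyntheticSpec(n_epochs=2, seed=1), 10)
        tr, va = split_train_val(pairs, 0.2, seed=3)
        tr_ids = {r.subject_id for r, _ in tr}
        va_ids = {r.subject_id for r, _ in va}
        assert tr_ids.isdisjoint(va_ids)
        assert tr_ids | va_ids == {f"S{i:02d}" for i in range(10)}

    def test_deterministic(self):
        pairs = generate_subjects(SyntheticSpec(n_epochs=2, seed=1), 10)
        a = split_train_val(pairs, 0.2, seed=3)
        b = split_train_val(pairs, 0.2, seed=3)
        assert [r.subject_id for r, _ in a[1]] == [r.subject_id for r, _ in b[1]]

    def test_single_subject_fallback_warns(self):
        pairs = generate_subjects(SyntheticSpec(n_epochs=20, seed=1), 1)
        with pytest.warns(UserWarning):
            tr, va = split_train_val(pairs, 0.10, seed=0)
        assert len(tr[0]) == 18 and len(va[0]) == 2

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            split_train_val([], 0.1)


class TestFoldPlan:
    def test_loso_one_subject_per_fold(self):
        plan = FoldPlan.loso(["a", "b", "c"], repeats=2, seed=0)
        assert plan.folds == [["a"], ["b"], ["c"]]
        assert len(plan.repeat_seeds) == 2

    def test_kfold_partitions_subjects(self):
        ids = [f"s{i}" for i in range(7)]
        plan = FoldPlan.kfold(ids, k=3, seed=1)
        flat = sorted(s for f in plan.folds for s in f)
        assert flat == sorted(ids)
        assert len(plan.folds) == 3

    def test_duplicate_subject_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan(mode="loso", folds=[["a"], ["a"]], repeat_seeds=[1])

    def test_empty_fold_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan(mode="loso", folds=[["a"], []], repeat_seeds=[1])


class TestTrainCNN:
    def test_log_has_one_row_per_epoch(self, trained, tiny_cfg):
        _, _, ckpt, log, _, _ = trained
        assert len(log) == tiny_cfg.e_max
        assert 1 <= ckpt.best_epoch <= tiny_cfg.e_max

    def test_warmup_weights_logged_as_one(self, trained):
        # e_max=3 -> only epoch 1 is warm-up
        _, _, _, log, _, _ = trained
        row = log.iloc[0]
        assert all(row[f"W_{s}"] == 1.0 for s in ("Wake", "N1", "N2", "N3", "REM"))

    def test_checkpoint_reproduces_predictions(self, trained, tiny_pairs):
        _, _, ckpt, _, _, _ = trained
        ds = epoch_signal(*tiny_pairs[0])
        a = predict_cnn(cnn_from_checkpoint(ckpt), ds)
        b = predict_cnn(cnn_from_checkpoint(ckpt), ds)
        assert np.array_equal(a, b)

    def test_same_seed_same_checkpoint(self, tiny_pairs, tiny_cfg):
        tr, va = split_train_val(tiny_pairs, tiny_cfg.val_fraction, seed=5)
        a, _ = train_cnn(tr, va, tiny_cfg)
        b, _ = train_cnn(tr, va, tiny_cfg)
        assert all(np.array_equal(a.state[k], b.state[k]) for k in a.state)


class TestTrainBiLSTM:
    def test_checkpoint_and_log(self, trained, tiny_cfg):
        _, _, _, _, ckpt, log = trained
        assert ckpt.kind == "bilstm"
        assert len(log) == tiny_cfg.e_max
        assert ckpt.config["seq_len"] == tiny_cfg.seq_len

    def test_standardizer_was_fitted(self, trained):
        _, _, _, _, ckpt, _ = trained
        model = bilstm_from_checkpoint(ckpt)
        assert np.abs(model.feat_mean).max() > 0
        assert not np.allclose(model.feat_scale, 1.0)

    def test_save_load_round_trip(self, trained, tmp_path):
        _, _, _, _, ckpt, _ = trained
        save_checkpoint(ckpt, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz")
        assert back.kind == "bilstm"
        assert back.best_epoch == ckpt.best_epoch
        assert all(np.array_equal(back.state[k], ckpt.state[k]) for k in ckpt.state)


class TestPredictTwoStage:
    def test_every_epoch_scored_once(self, trained, tiny_pairs, tiny_cfg):
        _, _, cnn_ckpt, _, lstm_ckpt, _ = trained
        cnn = cnn_from_checkpoint(cnn_ckpt)
        lstm = bilstm_from_checkpoint(lstm_ckpt)
        ds = epoch_signal(*tiny_pairs[0])  # 30 epochs, L=5 divides evenly
        pred = predict_two_stage(cnn, lstm, ds, tiny_cfg.seq_len)
        assert pred.shape == (30,)
        # ragged tail: 28 epochs with L=5 -> 5 full blocks + 3-epoch overlap tail
        from somnoscore.io import EpochedDataset

        ragged = EpochedDataset(ds.epochs[:28], ds.labels[:28], ds.fs, ds.subject_id)
        assert predict_two_stage(cnn, lstm, ragged, 5).shape == (28,)
        # consistency: the first 25 predictions match the block decomposition
        assert np.array_equal(
            predict_two_stage(cnn, lstm, ragged, 5)[:25], pred[:25]
        )

    def test_short_recording_single_window(self, trained, tiny_pairs):
        _, _, cnn_ckpt, _, lstm_ckpt, _ = trained
        cnn = cnn_from_checkpoint(cnn_ckpt)
        lstm = bilstm_from_checkpoint(lstm_ckpt)
        ds = epoch_signal(*tiny_pairs[1])
        from somnoscore.io import EpochedDataset

        short = EpochedDataset(ds.epochs[:3], ds.labels[:3], ds.fs, ds.subject_id)
        assert predict_two_stage(cnn, lstm, short, 5).shape == (3,)


class TestRunCV:
    def test_loso_smoke(self, tiny_pairs):
        cfg = TrainConfig(e_max=2, seed=9, seq_len=5, val_fraction=0.5, repeats=1)
        plan = FoldPlan.loso([r.subject_id for r, _ in tiny_pairs[:2]], repeats=1, seed=9)
        result = run_cv(tiny_pairs[:2], plan, cfg)
        assert set(result["summary"]) == {"macro_f1", "accuracy", "kappa"}
        assert result["pooled_confusion"].total == 60  # 2 subjects x 30 epochs
        subjects = {r["subject"] for r in result["per_subject"]}
        assert subjects == {tiny_pairs[0][0].subject_id, tiny_pairs[1][0].subject_id}

    def test_unknown_fold_subject_rejected(self, tiny_pairs):
        cfg = TrainConfig(e_max=2, seed=9, seq_len=5)
        plan = FoldPlan.loso(["nope"], repeats=1, seed=0)
        with pytest.raises(ValueError):
            run_cv(tiny_pairs, plan, cfg)
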