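"""Partial data augmentation by shifted re-windowing of the continuous signal.

Sleep features (spindles, K-complexes, arousals) often straddle the
30-s scoring grid.  Re-cutting the continuous signal with the window
start shifted forward by 1, 2 and 3 s yields three extra epoch series
whose windows span two adjacent scored epochs; together with the
unshifted series this gives 4 views of each recording, used only when
training the sequence model.  A shifted window keeps the label of the
base epoch containing its start (at least 27 of its 30 s lie there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EPOCH_SEC, EpochedDataset, Hypnogram, Recording


class EmptySeriesError(ValueError):
    """Recording too short to produce any shifted window."""


class EmptyBatchError(ValueError):
    """No series is long enough for a single sequence of length L."""


@dataclass
class SequenceBatch:
    """Fixed-length epoch sequences for the recurrent stage.

    ``sequences`` is (S, L, 30*fs); ``shift_s`` records each sequence's
    window shift in seconds (0–3).
    """

    sequences: np.ndarray
    labels: np.ndarray  # (S, L) stage codes
    shift_s: np.ndarray  # (S,)
    L: int

    def __post_init__(self):
        if self.sequences.ndim != 3 or self.sequences.shape[1] != self.L:
            raise ValueError("sequences must be (S, L, 30*fs)")
        if self.labels.shape != self.sequences.shape[:2]:
            raise ValueError("labels must be (S, L)")
        if not np.all((self.shift_s >= 0) & (self.shift_s <= 3)):
            raise ValueError("shift_s must lie in {0, 1, 2, 3}")

    def __len__(self) -> int:
        return len(self.sequences)


def shift_series(
    rec: Recording, hyp: Hypnogram, window_s: int = 4, step_s: int = 1
) -> list[EpochedDataset]:
    """Extract the shifted epoch series from a continuous recording.

    Returns ``window_s / step_s`` series; series s holds 30-s windows
    starting at 30*t + s*step_s seconds.  The unshifted series has E
    epochs; shifted series have E-1 (the final shifted window would
    overrun the recording).
    """
    if window_s % step_s != 0:
        raise ValueError("window_s must be divisible by step_s")
    if np.any(hyp.exclude):
        raise ValueError("augmentation expects a clean hypnogram (no excluded epochs)")
    spe = rec.fs * EPOCH_SEC
    E = min(rec.n_epochs, len(hyp))
    if E < 2:
        raise EmptySeriesError("need at least 2 epochs to form shifted windows")
    labels = hyp.labels[:E]
    n_series = window_s // step_s
    out = []
    for k in range(n_series):
        off = k * step_s * rec.fs
        count = E if off == 0 else E - 1
        starts = np.arange(count) * spe + off
        rows = np.stack([rec.samples[s : s + spe] for s in starts])
        out.append(EpochedDataset(rows, labels[:count], fs=rec.fs, subject_id=rec.subject_id))
    return out


def build_sequences(series: list[EpochedDataset], L: int, step_s: int = 1) -> SequenceBatch:
    """Tile each series into non-overlapping length-L sequences.

    A series of length E contributes floor(E / L) sequences; the
    trailing remainder is dropped.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    seqs, labs, shifts = [], [], []
    for k, ds in enumerate(series):
        n_seq = len(ds) // L
        for b in range(n_seq):
            seqs.append(ds.epochs[b * L : (b + 1) * L])
            labs.append(ds.labels[b * L : (b + 1) * L])
            shifts.append(k * step_s)
    if not seqs:
        raise EmptyBatchError(f"no series of length >= L={L}")
    return SequenceBatch(
        sequences=np.stack(seqs),
        labels=np.stack(labs),
        shift_s=np.asarray(shifts, dtype=np.int64),
        L=L,
    )
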