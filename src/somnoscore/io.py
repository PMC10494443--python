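"""Signal and hypnogram I/O for 30-s-epoch sleep staging.

Recordings are single-channel EEG stored in EDF/EDF+; hypnograms are one
stage label per 30-s epoch, interchanged as a 2-column CSV
(``epoch,stage``).  Two label schemes are supported: the R&K alphabet
(W, 1, 2, 3, 4, R, plus movement ``M`` and unscored ``?``) and the AASM
5-stage alphabet (Wake, N1, N2, N3, REM).  R&K stages 3 and 4 merge into
N3; ``M``/``?`` epochs are excluded from training and evaluation.

Reading EDF goes through :mod:`mne`; writing uses a minimal EDF encoder
(16-bit, 1-s data records) implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

EPOCH_SEC = 30
STAGES = ("Wake", "N1", "N2", "N3", "REM")
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

RK_ALPHABET = ("W", "1", "2", "3", "4", "R", "M", "?")
RK_TO_AASM = {"W": "Wake", "1": "N1", "2": "N2", "3": "N3", "4": "N3", "R": "REM"}
RK_EXCLUDED = ("M", "?")


class ChannelNotFoundError(KeyError):
    """Requested channel is absent from the EDF file."""


class InvalidLabelError(ValueError):
    """A hypnogram label is outside its declared scheme's alphabet."""


class NoSleepPeriodError(ValueError):
    """Hypnogram contains no non-Wake epoch, so no in-bed period exists."""


class AlignmentError(ValueError):
    """Signal and hypnogram cannot be aligned on the 30-s epoch grid."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """A continuous single-channel signal with its sampling rate.

    Amplitudes are in microvolts.  The signal must cover at least one
    30-s epoch and contain no non-finite samples.
    """

    samples: np.ndarray
    fs: int
    channel: str = "EEG"
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0 or int(self.fs) != self.fs:
            raise ValueError(f"sampling rate must be a positive integer, got {self.fs}")
        self.fs = int(self.fs)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if len(self.samples) < self.fs * EPOCH_SEC:
            raise ValueError("recording shorter than one 30-s epoch")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_epochs(self) -> int:
        """Number of complete 30-s epochs covered by the signal."""
        return len(self.samples) // (self.fs * EPOCH_SEC)


@dataclass
class Hypnogram:
    """Per-30-s-epoch stage labels.

    ``exclude`` marks epochs (movement / unscored) that are dropped when
    the signal is epoched; excluded positions keep their original code so
    the epoch grid stays aligned with the signal until then.
    """

    labels: np.ndarray
    scheme: str = "AASM"
    epoch_sec: int = EPOCH_SEC
    exclude: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epoch_sec != EPOCH_SEC:
            raise ValueError(f"epoch duration is fixed at {EPOCH_SEC} s")
        if self.scheme not in ("RK", "AASM"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.exclude is None:
            self.exclude = np.zeros(len(self.labels), dtype=bool)
        else:
            self.exclude = np.asarray(self.exclude, dtype=bool)
            if len(self.exclude) != len(self.labels):
                raise ValueError("exclude mask length mismatch")
        alphabet = set(RK_ALPHABET) if self.scheme == "RK" else set(STAGES)
        for i, lab in enumerate(self.labels):
            if not self.exclude[i] and lab not in alphabet:
                raise InvalidLabelError(f"label {lab!r} at epoch {i} not in {self.scheme} alphabet")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def kept_labels(self) -> np.ndarray:
        """Labels of non-excluded epochs, in order."""
        return self.labels[~self.exclude]


@dataclass
class EpochedDataset:
    """Aligned epoch matrix and AASM labels for one recording."""

    epochs: np.ndarray  # (E, 30*fs)
    labels: np.ndarray  # (E,) AASM codes
    fs: int
    subject_id: str = ""

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epochs.ndim != 2 or self.epochs.shape[0] != len(self.labels):
            raise AlignmentError(
                f"epoch rows ({self.epochs.shape[0]}) != labels ({len(self.labels)})"
            )
        if self.epochs.shape[1] != EPOCH_SEC * self.fs:
            raise AlignmentError(
                f"epoch width {self.epochs.shape[1]} != 30*fs = {EPOCH_SEC * self.fs}"
            )
        bad = [lab for lab in self.labels if lab not in STAGE_INDEX]
        if bad:
            raise InvalidLabelError(f"non-AASM labels in epoched dataset: {sorted(set(map(str, bad)))}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def label_indices(self) -> np.ndarray:
        return np.array([STAGE_INDEX[lab] for lab in self.labels], dtype=np.int64)


# ---------------------------------------------------------------------------
# label mapping / trimming / epoching
# ---------------------------------------------------------------------------


def map_labels(hyp: Hypnogram) -> tuple[Hypnogram, np.ndarray]:
    """Map an R&K hypnogram to AASM, marking M/? epochs for exclusion.

    Stages 3 and 4 merge into N3.  Returns the mapped hypnogram (same
    epoch grid, with movement/unscored epochs flagged in ``exclude``) and
    the boolean exclusion mask over the original epoch indices.  AASM
    input is returned unchanged; the operation is idempotent.
    """
    if hyp.scheme == "AASM":
        return hyp, hyp.exclude.copy()
    mapped = np.empty(len(hyp), dtype=object)
    exclude = hyp.exclude.copy()
    for i, lab in enumerate(hyp.labels):
        if lab in RK_EXCLUDED:
            exclude[i] = True
            mapped[i] = lab
        elif lab in RK_TO_AASM:
            mapped[i] = RK_TO_AASM[lab]
        else:
            raise InvalidLabelError(f"unknown R&K code {lab!r} at epoch {i}")
    return Hypnogram(mapped, scheme="AASM", exclude=exclude), exclude


def trim_to_in_bed(
    rec: Recording, hyp: Hypnogram, margin_min: float = 30.0
) -> tuple[Recording, Hypnogram]:
    """Restrict recording and hypnogram to the in-bed period.

    Keeps epochs from (first non-Wake epoch - margin) through (last
    non-Wake epoch + margin), clipped to the recording bounds.  Excluded
    epochs do not count as sleep when locating the period.
    """
    if hyp.scheme != "AASM":
        raise ValueError("trim_to_in_bed expects an AASM-mapped hypnogram")
    n_sig = rec.n_epochs
    n = len(hyp)
    if n > n_sig:
        warnings.warn(
            f"hypnogram has {n} epochs but signal covers {n_sig}; dropping trailing labels",
            stacklevel=2,
        )
        hyp = Hypnogram(hyp.labels[:n_sig], scheme="AASM", exclude=hyp.exclude[:n_sig])
        n = n_sig
    sleep = np.array(
        [lab != "Wake" and not ex for lab, ex in zip(hyp.labels, hyp.exclude)], dtype=bool
    )
    if not sleep.any():
        raise NoSleepPeriodError("hypnogram contains no sleep epochs")
    first, last = int(np.argmax(sleep)), int(n - 1 - np.argmax(sleep[::-1]))
    margin_epochs = int(round(margin_min * 60 / EPOCH_SEC))
    lo = max(0, first - margin_epochs)
    hi = min(n, last + margin_epochs + 1)
    spe = rec.fs * EPOCH_SEC
    trimmed = replace(rec, samples=rec.samples[lo * spe : hi * spe])
    return trimmed, Hypnogram(hyp.labels[lo:hi], scheme="AASM", exclude=hyp.exclude[lo:hi])


def epoch_signal(rec: Recording, hyp: Hypnogram) -> EpochedDataset:
    """Cut the continuous signal into labelled 30-s epochs.

    Epoch t takes samples [30*fs*t, 30*fs*(t+1)); excluded epochs are
    dropped from both signal and labels; a trailing partial epoch is
    discarded.  A hypnogram longer than the signal loses its trailing
    labels with a warning.
    """
    if hyp.scheme != "AASM":
        raise ValueError("epoch_signal expects an AASM-mapped hypnogram")
    spe = rec.fs * EPOCH_SEC
    n_sig = rec.n_epochs
    n = len(hyp)
    if n > n_sig:
        warnings.warn(
            f"hypnogram has {n} epochs but signal covers {n_sig}; dropping trailing labels",
            stacklevel=2,
        )
        n = n_sig
    keep = [t for t in range(n) if not hyp.exclude[t]]
    rows = np.stack([rec.samples[t * spe : (t + 1) * spe] for t in keep]) if keep else np.empty((0, spe))
    return EpochedDataset(rows, hyp.labels[keep], fs=rec.fs, subject_id=rec.subject_id)


# ---------------------------------------------------------------------------
# hypnogram CSV
# ---------------------------------------------------------------------------


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    pd.DataFrame({"epoch": np.arange(len(hyp)), "stage": hyp.labels}).to_csv(path, index=False)


def read_hypnogram_csv(path, scheme: str | None = None) -> Hypnogram:
    df = pd.read_csv(path, dtype={"stage": str})
    if not {"epoch", "stage"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns epoch,stage")
    labels = df.sort_values("epoch")["stage"].to_numpy(dtype=object)
    if scheme is None:
        scheme = "AASM" if set(labels) <= set(STAGES) else "RK"
    return Hypnogram(labels, scheme=scheme)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def _edf_ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a single-channel EDF file (16-bit, 1-s data records, µV).

    The physical range is the symmetric integer envelope of the signal,
    so amplitudes survive a round trip to within one 16-bit quantum.  A
    trailing partial second is zero-padded to fill the last record.
    """
    fs = rec.fs
    x = rec.samples
    n_rec = int(np.ceil(len(x) / fs))
    pad = n_rec * fs - len(x)
    if pad:
        x = np.concatenate([x, np.zeros(pad)])
    phys_max = max(1, int(np.ceil(np.max(np.abs(x)) + 1e-12)))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.round((x + phys_max) * scale) + dig_min, dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _edf_ascii("0", 8),
            _edf_ascii(rec.subject_id or "X", 80),
            _edf_ascii("Startdate 01-JAN-2000", 80),
            _edf_ascii("01.01.00", 8),
            _edf_ascii("00.00.00", 8),
            _edf_ascii(256 * 2, 8),
            _edf_ascii("", 44),
            _edf_ascii(n_rec, 8),
            _edf_ascii(1, 8),
            _edf_ascii(1, 4),
        ]
    )
    sig_header = b"".join(
        [
            _edf_ascii(rec.channel, 16),
            _edf_ascii("", 80),
            _edf_ascii("uV", 8),
            _edf_ascii(-phys_max, 8),
            _edf_ascii(phys_max, 8),
            _edf_ascii(dig_min, 8),
            _edf_ascii(dig_max, 8),
            _edf_ascii("", 80),
            _edf_ascii(fs, 8),
            _edf_ascii("", 32),
        ]
    )
    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        f.write(digital.tobytes())


def read_edf(path, channel: str) -> Recording:
    """Read one channel from an EDF/EDF+ file, in microvolts."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path.name}; available: {raw.ch_names}"
        )
    raw = raw.pick([channel]).load_data(verbose="error")
    try:
        data = raw.get_data(units="uV")[0]
    except ValueError:  # channel without a convertible unit
        data = raw.get_data()[0]
    subject = (raw.info["subject_info"] or {}).get("his_id", "") if raw.info.get("subject_info") else ""
    return Recording(data, fs=int(round(raw.info["sfreq"])), channel=channel, subject_id=subject or path.stem)


def save_recording(rec: Recording, hyp: Hypnogram, edf_path) -> None:
    """Write an EDF plus its companion ``*_hypnogram.csv``."""
    edf_path = Path(edf_path)
    write_edf(rec, edf_path)
    write_hypnogram_csv(hyp, edf_path.with_name(edf_path.stem + "_hypnogram.csv"))


def load_recording(edf_path, channel: str = "EEG") -> tuple[Recording, Hypnogram]:
    """Read an EDF and its companion hypnogram CSV."""
    edf_path = Path(edf_path)
    rec = read_edf(edf_path, channel)
    hyp = read_hypnogram_csv(edf_path.with_name(edf_path.stem + "_hypnogram.csv"))
    return rec, hyp
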