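"""Intra-epoch feature extractor: a strided 1-D convolutional stack.

One 30-s raw EEG epoch (1 x 30*fs samples) is mapped to a 256-d feature
and, through a softmax head, to 5-class stage posteriors.  The first
convolution uses a kernel of fs*4 samples (reaching down to 0.5 Hz) with
stride fs/16; two further convolutions (kernel fs/12 and 3) mix
frequency and local temporal structure, a pointwise (1x1) convolution
compresses 64 feature maps to 16, and batch-norm + two fully connected
layers (1024, 256) produce the epoch feature.  All convolutions are
"valid" (no padding, no pooling); ReLU follows every conv/FC stage.

Default optimizer settings for this stage: Adam, lr 1e-3, batch 128,
weight decay 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, conv1d, dropout
from .io import EpochedDataset, EPOCH_SEC


class ConfigurationError(ValueError):
    """Architecture arithmetic impossible for the given sampling rate."""


def _round(x: float) -> int:
    """Round half to even (python built-in), as used for fs-derived sizes."""
    return int(round(x))


@dataclass
class CNNConfig:
    """Architecture hyperparameters; kernel/stride widths derive from fs."""

    fs: int = 100
    n_classes: int = 5
    filters: tuple = (16, 32, 64, 16)
    fc_sizes: tuple = (1024, 256)
    dropout: float = 0.5

    def __post_init__(self):
        if self.fc_sizes != (1024, 256):
            raise ConfigurationError("fully connected sizes are fixed at (1024, 256)")
        k, s = self.kernels, self.strides
        if any(v < 1 for v in k) or any(v < 1 for v in s):
            raise ConfigurationError(f"fs={self.fs} yields a kernel or stride < 1")
        if EPOCH_SEC * self.fs <= k[0]:
            raise ConfigurationError(f"30-s epoch ({EPOCH_SEC * self.fs}) not longer than conv1 kernel ({k[0]})")

    @property
    def kernels(self) -> tuple:
        return (self.fs * 4, _round(self.fs / 12), 3, 1)

    @property
    def strides(self) -> tuple:
        return (_round(self.fs / 16), 1, 1, 1)

    @property
    def conv_widths(self) -> tuple:
        """Valid-convolution output widths after each conv layer."""
        w = EPOCH_SEC * self.fs
        widths = []
        for k, s in zip(self.kernels, self.strides):
            w = (w - k) // s + 1
            widths.append(w)
        return tuple(widths)

    @property
    def flat_width(self) -> int:
        return self.filters[-1] * self.conv_widths[-1]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class EpochCNN:
    """The convolutional epoch model; parameters live in ``self.params``."""

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, cfg: CNNConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f1, f2, f3, f4 = cfg.filters
        k1, k2, k3, _ = cfg.kernels
        fc1, fc2 = cfg.fc_sizes

        def he(shape, fan_in):
            return Tensor(
                rng.normal(0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype), requires_grad=True
            )

        def zeros(shape):
            return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)

        self.params = {
            "conv1_w": he((f1, 1, k1), k1),
            "conv1_b": zeros(f1),
            "conv2_w": he((f2, f1, k2), f1 * k2),
            "conv2_b": zeros(f2),
            "conv3_w": he((f3, f2, k3), f2 * k3),
            "conv3_b": zeros(f3),
            "pw_w": he((f4, f3, 1), f3),
            "pw_b": zeros(f4),
            "bn_gamma": Tensor(np.ones(f4, dtype=dtype), requires_grad=True),
            "bn_beta": zeros(f4),
            "fc1_w": he((cfg.flat_width, fc1), cfg.flat_width),
            "fc1_b": zeros(fc1),
            "fc2_w": he((fc1, fc2), fc1),
            "fc2_b": zeros(fc2),
            "head_w": he((fc2, cfg.n_classes), fc2),
            "head_b": zeros(cfg.n_classes),
        }
        self.bn_mean = np.zeros(f4, dtype=dtype)
        self.bn_var = np.ones(f4, dtype=dtype)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Run a batch of epochs (B, 30*fs); returns (features, logits) Tensors.

        Features are the 256-d FC2 activations after ReLU, before the
        second dropout.  Evaluation mode (train=False) is deterministic.
        """
        if train and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        p = self.params
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 2 or x.shape[1] != EPOCH_SEC * self.cfg.fs:
            raise ValueError(
                f"input must be (B, {EPOCH_SEC * self.cfg.fs}) for fs={self.cfg.fs}, got {x.shape}"
            )
        h = Tensor(x[:, None, :])  # (B, 1, W)
        h = conv1d(h, p["conv1_w"], p["conv1_b"], stride=self.cfg.strides[0]).relu()
        h = conv1d(h, p["conv2_w"], p["conv2_b"]).relu()
        h = conv1d(h, p["conv3_w"], p["conv3_b"]).relu()
        h = conv1d(h, p["pw_w"], p["pw_b"])  # pointwise channel compression, no activation
        h = self._batch_norm(h, train).relu()
        h = dropout(h, self.cfg.dropout, rng, train)
        B = h.shape[0]
        h = h.reshape(B, self.cfg.flat_width)
        h = (h @ p["fc1_w"] + p["fc1_b"]).relu()
        feat = (h @ p["fc2_w"] + p["fc2_b"]).relu()
        h = dropout(feat, self.cfg.dropout, rng, train)
        logits = h @ p["head_w"] + p["head_b"]
        return feat, logits

    def _batch_norm(self, h: Tensor, train: bool) -> Tensor:
        g = self.params["bn_gamma"].reshape(1, -1, 1)
        b = self.params["bn_beta"].reshape(1, -1, 1)
        if train:
            mu = h.mean(axis=(0, 2), keepdims=True)
            var = ((h - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = self.BN_MOMENTUM
            self.bn_mean = (1 - m) * self.bn_mean + m * mu.data.ravel()
            self.bn_var = (1 - m) * self.bn_var + m * var.data.ravel()
            return (h - mu) * ((var + self.BN_EPS) ** -0.5) * g + b
        inv = 1.0 / np.sqrt(self.bn_var + self.BN_EPS)
        return (h - Tensor(self.bn_mean[None, :, None])) * Tensor(inv[None, :, None]) * g + b

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict:
        out = {k: v.data.copy() for k, v in self.params.items()}
        out["bn_mean"], out["bn_var"] = self.bn_mean.copy(), self.bn_var.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=self.dtype)
        self.bn_mean = np.asarray(state["bn_mean"], dtype=self.dtype)
        self.bn_var = np.asarray(state["bn_var"], dtype=self.dtype)

    def config_dict(self) -> dict:
        return asdict(self.cfg)


def build_cnn(cfg: CNNConfig, seed: int = 0, dtype=np.float32) -> EpochCNN:
    """Construct the epoch CNN with He-initialized weights."""
    return EpochCNN(cfg, seed=seed, dtype=dtype)


def _check_fs(model: EpochCNN, epochs: EpochedDataset) -> None:
    if epochs.fs != model.cfg.fs:
        raise ValueError(f"sampling-rate mismatch: model fs={model.cfg.fs}, data fs={epochs.fs}")


def cnn_features(model: EpochCNN, epochs: EpochedDataset, batch: int = 256) -> np.ndarray:
    """256-d evaluation-mode features, one row per epoch."""
    _check_fs(model, epochs)
    out = [model.forward(epochs.epochs[i : i + batch])[0].data for i in range(0, len(epochs), batch)]
    return np.concatenate(out, axis=0) if out else np.empty((0, model.cfg.fc_sizes[1]))


def cnn_posteriors(model: EpochCNN, epochs: EpochedDataset, batch: int = 256) -> np.ndarray:
    """Per-epoch 5-class posterior distributions (evaluation mode)."""
    _check_fs(model, epochs)
    out = [
        softmax(model.forward(epochs.epochs[i : i + batch])[1].data)
        for i in range(0, len(epochs), batch)
    ]
    return np.concatenate(out, axis=0) if out else np.empty((0, model.cfg.n_classes))
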