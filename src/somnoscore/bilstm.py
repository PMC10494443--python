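"""Inter-epoch sequence model: 2-layer bidirectional LSTM with residual fusion.

The recurrent stage consumes sequences of 256-d epoch features from the
pre-trained CNN and emits one 5-class posterior per epoch position
(many-to-many).  Its per-epoch output o (2 x 256 = 512) is fused with
the corresponding input feature x (256) by an outer product
(512 x 256), elementwise ReLU, and average pooling over the feature
axis, yielding a 512-vector that two fully connected layers
(512 -> 256 -> 5) map to stage logits.  The fusion lets every output
element be weighted by its agreement with the intra-epoch feature.

Because ReLU distributes over the product sign-wise, the pooled fusion
has the closed form

    fused_r = relu(o_r) * mean_c relu(x_c) + relu(-o_r) * mean_c relu(-x_c)

which the training path uses to avoid materializing the 512 x 256
matrix; :func:`fuse` computes the explicit outer product and is the
reference both for tests and for single-vector use.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._autodiff import Tensor, concat, dropout
from .cnn import softmax


@dataclass
class LSTMConfig:
    """Sequence-model hyperparameters (training defaults included)."""

    input_size: int = 256
    hidden_size: int = 256
    layers: int = 2
    bidirectional: bool = True
    dropout: float = 0.1
    seq_len: int = 30
    lr: float = 1e-4
    batch: int = 64
    weight_decay: float = 1e-5
    n_classes: int = 5
    fusion: bool = True
    head_hidden: int = 256

    def __post_init__(self):
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if not self.bidirectional or self.layers != 2:
            raise ValueError("architecture is fixed at 2 bidirectional layers")

    @property
    def out_size(self) -> int:
        return 2 * self.hidden_size


def fuse(cnn_feat: np.ndarray, lstm_out: np.ndarray, return_matrix: bool = False):
    """Residual fusion of one epoch's CNN feature (256) and LSTM output (512).

    Computes the outer product lstm_out (x) cnn_feat -> (512, 256),
    applies ReLU elementwise, then averages over the 256 feature axis.
    """
    cnn_feat = np.asarray(cnn_feat, dtype=float)
    lstm_out = np.asarray(lstm_out, dtype=float)
    if cnn_feat.ndim != 1 or lstm_out.ndim != 1:
        raise ValueError("fuse expects single vectors; see SequenceModel for batches")
    if cnn_feat.shape != (256,) or lstm_out.shape != (512,):
        raise ValueError(
            f"fuse expects a 256-d feature and a 512-d recurrent output, "
            f"got {cnn_feat.shape} and {lstm_out.shape}"
        )
    M = np.maximum(np.outer(lstm_out, cnn_feat), 0.0)
    fused = M.mean(axis=1)
    return (fused, M) if return_matrix else fused


class SequenceModel:
    """Bidirectional LSTM over epoch-feature sequences, with fusion head."""

    def __init__(self, cfg: LSTMConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        H = cfg.hidden_size

        def glorot(shape):
            fan = sum(shape)
            lim = np.sqrt(6.0 / fan)
            return Tensor(rng.uniform(-lim, lim, size=shape).astype(dtype), requires_grad=True)

        def zeros(n):
            return Tensor(np.zeros(n, dtype=dtype), requires_grad=True)

        self.params: dict[str, Tensor] = {}
        in_sizes = [cfg.input_size, 2 * H]
        for layer in range(cfg.layers):
            for d in ("f", "b"):
                pre = f"l{layer}{d}"
                self.params[f"{pre}_wx"] = glorot((in_sizes[layer], 4 * H))
                self.params[f"{pre}_wh"] = glorot((H, 4 * H))
                b = np.zeros(4 * H, dtype=dtype)
                b[H : 2 * H] = 1.0  # forget-gate bias
                self.params[f"{pre}_b"] = Tensor(b, requires_grad=True)
        head_in = cfg.out_size
        self.params["head1_w"] = glorot((head_in, cfg.head_hidden))
        self.params["head1_b"] = zeros(cfg.head_hidden)
        self.params["head2_w"] = glorot((cfg.head_hidden, cfg.n_classes))
        self.params["head2_b"] = zeros(cfg.n_classes)
        # per-dimension input standardizer (identity until fitted); the raw
        # CNN features are sparse with heavy-tailed magnitudes, which
        # saturates the gate nonlinearities, so training fits an affine
        # standardizer on the training features and stores it with the model
        self.feat_mean = np.zeros(cfg.input_size, dtype=dtype)
        self.feat_scale = np.ones(cfg.input_size, dtype=dtype)

    def set_standardizer(self, mean: np.ndarray, std: np.ndarray) -> None:
        """Fit the input standardizer: forward uses (x - mean) / std."""
        mean = np.asarray(mean, dtype=self.dtype).reshape(-1)
        std = np.asarray(std, dtype=self.dtype).reshape(-1)
        if mean.shape != (self.cfg.input_size,) or std.shape != (self.cfg.input_size,):
            raise ValueError("standardizer shape must match input_size")
        self.feat_mean = mean
        self.feat_scale = (1.0 / (std + 1e-6)).astype(self.dtype)

    # -- recurrence --------------------------------------------------------

    def _run_direction(self, xs: list[Tensor], prefix: str) -> list[Tensor]:
        """One LSTM direction over a list of (S, in) feature tensors."""
        H = self.cfg.hidden_size
        wx, wh, b = (self.params[f"{prefix}_{k}"] for k in ("wx", "wh", "b"))
        S = xs[0].shape[0]
        h = Tensor(np.zeros((S, H), dtype=self.dtype))
        c = Tensor(np.zeros((S, H), dtype=self.dtype))
        out = []
        for x_t in xs:
            gates = x_t @ wx + h @ wh + b
            i = gates[:, 0 * H : 1 * H].sigmoid()
            f = gates[:, 1 * H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out.append(h)
        return out

    def _forward(self, feature_seq, train, rng):
        if isinstance(feature_seq, Tensor):
            inp = feature_seq
        else:
            inp = Tensor(np.asarray(feature_seq, dtype=self.dtype))
        if inp.data.ndim != 3 or inp.data.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"feature sequences must be (S, L, {self.cfg.input_size}), got {inp.data.shape}"
            )
        S, L, _ = inp.data.shape
        inp = (inp + Tensor(-self.feat_mean)) * Tensor(self.feat_scale)
        xs = [inp[:, t, :] for t in range(L)]
        layer_in = xs
        for layer in range(self.cfg.layers):
            fwd = self._run_direction(layer_in, f"l{layer}f")
            bwd = self._run_direction(layer_in[::-1], f"l{layer}b")[::-1]
            layer_out = [concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
            if layer < self.cfg.layers - 1:
                layer_out = [dropout(h, self.cfg.dropout, rng, train) for h in layer_out]
            layer_in = layer_out
        logits, fused = [], []
        for t, o_t in enumerate(layer_in):
            z = self._fuse_batch(xs[t], o_t) if self.cfg.fusion else o_t
            fused.append(z)
            h = (z @ self.params["head1_w"] + self.params["head1_b"]).relu()
            logits.append(h @ self.params["head2_w"] + self.params["head2_b"])
        out = concat([l.reshape(S, 1, self.cfg.n_classes) for l in logits], axis=1)
        return out, layer_in, fused

    def forward(
        self,
        feature_seq: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Map (S, L, 256) feature sequences to (S, L, 5) logits."""
        if train and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        return self._forward(feature_seq, train, rng)[0]

    @staticmethod
    def _fuse_batch(x: Tensor, o: Tensor) -> Tensor:
        """Closed-form pooled residual fusion for a batch of epochs.

        Exact sign-split of mean_c relu(o_r * x_c); avoids the explicit
        (S, 512, 256) tensor.  Agrees with :func:`fuse` elementwise.
        """
        mean_pos = x.relu().mean(axis=1, keepdims=True)
        mean_neg = (-x).relu().mean(axis=1, keepdims=True)
        return o.relu() * mean_pos + (-o).relu() * mean_neg

    def posteriors(self, feature_seq: np.ndarray) -> np.ndarray:
        """(S, L, 5) evaluation-mode posterior distributions."""
        return softmax(self.forward(feature_seq).data)

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.params.items()}
        state["feat_mean"] = self.feat_mean.copy()
        state["feat_scale"] = self.feat_scale.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=self.dtype)
        if "feat_mean" in state:
            self.feat_mean = np.asarray(state["feat_mean"], dtype=self.dtype)
            self.feat_scale = np.asarray(state["feat_scale"], dtype=self.dtype)

    def config_dict(self) -> dict:
        return asdict(self.cfg)


def build_bilstm(cfg: LSTMConfig, seed: int = 0, dtype=np.float32) -> SequenceModel:
    return SequenceModel(cfg, seed=seed, dtype=dtype)


def forward_sequence(model: SequenceModel, feature_seq: np.ndarray) -> dict:
    """Evaluation-mode outputs for sequences of epoch features.

    Returns per-epoch recurrent outputs ``o`` (S, L, 512), fused vectors
    (S, L, 512), posteriors (S, L, 5) and predicted stage indices
    (S, L); posterior ties break toward the lower class index (numpy
    argmax convention).
    """
    logits, outs, fused = model._forward(feature_seq, train=False, rng=None)
    o = np.stack([t.data for t in outs], axis=1)
    z = np.stack([t.data for t in fused], axis=1)
    post = softmax(logits.data)
    return {"o": o, "fused": z, "posterior": post, "predicted": post.argmax(axis=-1)}
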