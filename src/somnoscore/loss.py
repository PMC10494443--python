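"""Adaptive F1-weighted cross-entropy with label smoothing.

The objective is plain smoothed cross-entropy during a warm-up phase
(the first e_max/3 training epochs) and, afterwards, a class-weighted
cross-entropy whose per-class weights are recomputed after every
training epoch from that epoch's per-class training F1-scores:

    W_i = 1 - gamma * log_K( max(CF_i, floor) )

with K = 10, gamma = 3 and floor = 1e-4 by default.  A perfectly learned
class (F1 = 1) keeps weight 1; typical F1-scores in [10^(-1/3), 1] give
weights in [1, 2]; a class with near-zero F1 is clamped at the floor,
where the weight reaches 13.  Weights multiply the smoothed target
distribution termwise, so smoothing and weighting compose exactly.

Label smoothing (alpha = 0.1 by default) maps a hard label to
y_k (1 - alpha) + alpha / K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Tensor

_LOG_FLOOR = 1e-12  # numerical floor for log(posterior)


def smooth_labels(onehot: np.ndarray, alpha: float = 0.1, K: int | None = None) -> np.ndarray:
    """Convert hard (or already soft) label distributions to smoothed ones."""
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    onehot = np.asarray(onehot, dtype=float)
    if K is None:
        K = onehot.shape[-1]
    return onehot * (1.0 - alpha) + alpha / K


def class_weights(
    CF: np.ndarray, K_base: float = 10.0, gamma: float = 3.0, floor: float = 1e-4
) -> np.ndarray:
    """Per-class loss weights from the previous epoch's per-class F1."""
    CF = np.asarray(CF, dtype=float)
    if np.any((CF < 0) | (CF > 1)):
        raise ValueError("class F1-scores must lie in [0, 1]")
    if floor <= 0:
        raise ValueError("floor must be positive")
    return 1.0 - gamma * np.log(np.maximum(CF, floor)) / np.log(K_base)


@dataclass
class AdaptiveLossState:
    """Phase and weight state of the adaptive objective.

    ``e`` is the 1-based index of the training epoch about to run (or
    running); the warm-up phase is e <= e_max / 3, during which all
    weights are 1.
    """

    n_classes: int = 5
    K_base: float = 10.0
    gamma: float = 3.0
    floor: float = 1e-4
    alpha: float = 0.1
    e: int = 1
    e_max: int = 30
    CF: np.ndarray = field(default=None)
    W: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.CF is None:
            self.CF = np.ones(self.n_classes)
        if self.W is None:
            self.W = np.ones(self.n_classes)
        self.CF = np.asarray(self.CF, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.warmup and not np.all(self.W == 1.0):
            raise ValueError("weights must all be 1 during warm-up")

    @property
    def warmup(self) -> bool:
        return self.e <= self.e_max / 3

    @property
    def effective_weights(self) -> np.ndarray:
        return np.ones(self.n_classes) if self.warmup else self.W


def update_state(state: AdaptiveLossState, train_F1: np.ndarray) -> AdaptiveLossState:
    """Advance to the next training epoch, recomputing weights from F1.

    The returned state has e incremented, CF set to ``train_F1``, and W
    recomputed via :func:`class_weights` — unless the next epoch is still
    in the warm-up phase, in which case all weights stay 1.
    """
    train_F1 = np.asarray(train_F1, dtype=float)
    if np.any((train_F1 < 0) | (train_F1 > 1)):
        raise ValueError("F1 entries must lie in [0, 1]")
    e_next = state.e + 1
    if e_next <= state.e_max / 3:
        W = np.ones(state.n_classes)
    else:
        W = class_weights(train_F1, state.K_base, state.gamma, state.floor)
    return replace(state, e=e_next, CF=train_F1, W=W)


def _coefficients(target: np.ndarray, state: AdaptiveLossState) -> np.ndarray:
    """Smoothed target times effective class weights (N, K)."""
    target = np.asarray(target, dtype=float)
    if target.shape[-1] != state.n_classes:
        raise ValueError(
            f"target has {target.shape[-1]} classes, state expects {state.n_classes}"
        )
    p = smooth_labels(target, state.alpha, state.n_classes)
    return p * state.effective_weights


def adaptive_ce(posterior: np.ndarray, target: np.ndarray, state: AdaptiveLossState) -> float:
    """Mean adaptive cross-entropy over samples (numpy, for evaluation).

    ``posterior`` rows are predicted class distributions; ``target`` rows
    are hard one-hot (or soft) true distributions, smoothed internally
    with ``state.alpha``.
    """
    posterior = np.asarray(posterior, dtype=float)
    if posterior.shape[-1] != state.n_classes:
        raise ValueError(
            f"posterior has {posterior.shape[-1]} classes, state expects {state.n_classes}"
        )
    coeff = _coefficients(target, state)
    logp = np.log(np.maximum(posterior, _LOG_FLOOR))
    return float(np.mean(-(coeff * logp).sum(axis=-1)))


def adaptive_ce_from_logits(logits: Tensor, target: np.ndarray, state: AdaptiveLossState) -> Tensor:
    """Differentiable adaptive cross-entropy on raw logits (training path).

    Uses a numerically stable log-softmax; gradients are exact analytic
    expressions through the autodiff graph.
    """
    coeff = _coefficients(target, state).astype(logits.data.dtype)
    n = int(np.prod(logits.data.shape[:-1]))
    return (Tensor(coeff) * logits.log_softmax(axis=-1)).sum() * (-1.0 / n)


def onehot(label_indices: np.ndarray, n_classes: int = 5) -> np.ndarray:
    out = np.zeros((len(label_indices), n_classes))
    out[np.arange(len(label_indices)), label_indices] = 1.0
    return out
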