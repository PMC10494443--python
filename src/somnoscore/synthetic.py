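"""Synthetic sleep-EEG generator: Markov hypnograms + stage-conditioned signal.

The generator emulates the canonical spectral signatures of the AASM
stages on a single EEG channel: prominent alpha (8–13 Hz) in Wake,
low-amplitude theta (4–8 Hz) in N1 and REM (deliberately near-identical
so their separation requires inter-epoch context, as on real EEG),
spindle bursts (11–16 Hz) over a mixed background in N2, and dominant
high-amplitude delta (0.5–4 Hz) in N3.  Stage sequences follow a
first-order Markov chain built by a Metropolis construction so that its
stationary distribution equals a target stage-proportion vector; the
default targets the class proportions typical of healthy overnight
polysomnography (Wake 19.6%, N1 6.6%, N2 42.1%, N3 13.5%, REM 18.2%),
making N1 the rare, hard class.

Everything is deterministic under the spec seed: per-epoch random
streams are derived from ``(seed, epoch_index)`` via
``numpy.random.SeedSequence`` spawn keys, independent of generation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EPOCH_SEC, Recording, Hypnogram, STAGES, STAGE_INDEX

#: Default stationary stage proportions (Wake, N1, N2, N3, REM).
DEFAULT_PROPORTIONS = np.array([0.196, 0.066, 0.421, 0.135, 0.182])
DEFAULT_PROPORTIONS = DEFAULT_PROPORTIONS / DEFAULT_PROPORTIONS.sum()

#: Symmetric stage-affinity matrix: which transitions are physiologically
#: plausible (Wake<->N1 and N1<->N2 common; Wake<->N3, N1<->N3 rare).
_AFFINITY = np.array(
    [
        # Wake  N1    N2    N3    REM
        [0.00, 1.00, 0.15, 0.02, 0.12],  # Wake
        [1.00, 0.00, 1.00, 0.02, 0.50],  # N1
        [0.15, 1.00, 0.00, 0.60, 0.50],  # N2
        [0.02, 0.02, 0.60, 0.00, 0.05],  # N3
        [0.12, 0.50, 0.50, 0.05, 0.00],  # REM
    ]
)

#: Default per-stage band powers: stage -> [(low Hz, high Hz, relative power)].
#: N1 and REM share the same dominant theta component on purpose: on a
#: single EEG channel their theta activity is famously near-identical, so
#: distinguishing them must rely mostly on inter-epoch context (stage
#: sequence structure), with only a weak secondary-band cue intra-epoch.
DEFAULT_BAND_POWER = {
    "Wake": [(8.0, 13.0, 1.0), (15.0, 30.0, 0.3)],
    "N1": [(4.0, 8.0, 0.7), (8.0, 13.0, 0.15)],
    "N2": [(4.0, 8.0, 0.5), (0.5, 4.0, 0.3)],
    "N3": [(0.5, 4.0, 1.5), (4.0, 8.0, 0.3)],
    "REM": [(4.0, 8.0, 0.7), (15.0, 30.0, 0.15)],
}


def transition_from_stationary(
    pi: np.ndarray, affinity: np.ndarray | None = None, mobility: float = 0.12
) -> np.ndarray:
    """Build a row-stochastic matrix with stationary distribution ``pi``.

    Metropolis construction over a symmetric affinity proposal: for i != j,
    P[i, j] = mobility * A[i, j] * min(1, pi[j] / pi[i]); the remaining
    mass stays on the diagonal, giving realistic stage persistence
    (mean dwell of several epochs).  Detailed balance guarantees the
    stationary distribution is exactly ``pi``.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-9:
        raise ValueError("pi must be a strictly positive probability vector")
    A = _AFFINITY if affinity is None else np.asarray(affinity, dtype=float)
    if A.shape != (len(pi), len(pi)) or not np.allclose(A, A.T):
        raise ValueError("affinity must be a symmetric matrix matching pi")
    P = mobility * A * np.minimum(1.0, pi[None, :] / pi[:, None])
    np.fill_diagonal(P, 0.0)
    off = P.sum(axis=1)
    if np.any(off >= 1.0):
        raise ValueError("mobility too large: off-diagonal mass exceeds 1")
    np.fill_diagonal(P, 1.0 - off)
    return P


DEFAULT_TRANSITION = transition_from_stationary(DEFAULT_PROPORTIONS)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic recording generator.

    ``amplitude`` sets the RMS (µV) corresponding to relative band power
    1.0; ``noise_sd`` is the broadband Gaussian noise scale in µV;
    ``spindle_rate`` is the expected number of 11–16 Hz bursts per N2
    epoch.
    """

    fs: int = 100
    n_epochs: int = 960
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    initial: np.ndarray = field(default_factory=lambda: DEFAULT_PROPORTIONS.copy())
    band_power: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BAND_POWER.items()})
    noise_sd: float = 6.0
    spindle_rate: float = 2.0
    amplitude: float = 20.0
    seed: int = 0

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (5, 5):
            raise ValueError("transition must be 5x5")
        if np.any(self.transition < 0) or np.any(np.abs(self.transition.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition rows must be non-negative and sum to 1")
        if abs(self.initial.sum() - 1) > 1e-9 or np.any(self.initial < 0):
            raise ValueError("initial probabilities must sum to 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        nyq = self.fs / 2
        for stage, bands in self.band_power.items():
            if stage not in STAGE_INDEX:
                raise ValueError(f"unknown stage {stage!r} in band_power")
            for lo, hi, _pw in bands:
                if not (0 < lo < hi < nyq):
                    raise ValueError(f"band ({lo}, {hi}) invalid for fs={self.fs}")


def _epoch_rng(spec: SyntheticSpec, epoch_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(epoch_seed,)))


def sample_hypnogram(spec: SyntheticSpec) -> Hypnogram:
    """Draw an AASM hypnogram of ``n_epochs`` from the Markov chain."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2**32,)))
    states = np.empty(spec.n_epochs, dtype=np.int64)
    states[0] = rng.choice(5, p=spec.initial)
    for t in range(1, spec.n_epochs):
        states[t] = rng.choice(5, p=spec.transition[states[t - 1]])
    return Hypnogram(np.array([STAGES[s] for s in states], dtype=object), scheme="AASM")


def _synthesize(stage: str, spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Stage-conditioned signal of ``n`` samples (de-meaned)."""
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    for lo, hi, power in spec.band_power.get(stage, []):
        comp = np.zeros(n)
        for _ in range(6):  # a few random tones per band approximate band-limited noise
            f = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            comp += np.sin(2 * np.pi * f * t + phase)
        sd = comp.std()
        if sd > 0:
            x += comp * (power * spec.amplitude / sd)
    if stage == "N2" and spec.spindle_rate > 0:
        for _ in range(rng.poisson(spec.spindle_rate * n / (EPOCH_SEC * spec.fs))):
            dur = rng.uniform(0.6, 1.2)
            m = max(int(dur * spec.fs), 2)
            start = rng.integers(0, max(n - m, 1))
            f = rng.uniform(11.0, 16.0)
            env = np.hanning(m)
            burst = env * np.sin(2 * np.pi * f * np.arange(m) / spec.fs + rng.uniform(0, 2 * np.pi))
            x[start : start + m] += spec.amplitude * 1.4 * burst
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, n)
    if np.any(x):
        x -= x.mean()
    return x


def synthesize_epoch(stage: str, spec: SyntheticSpec, epoch_seed: int) -> np.ndarray:
    """One 30-s epoch of stage-conditioned signal, deterministic in
    ``(spec.seed, epoch_seed)``."""
    if stage not in STAGE_INDEX:
        raise ValueError(f"unknown stage {stage!r}")
    return _synthesize(stage, spec, _epoch_rng(spec, epoch_seed), EPOCH_SEC * spec.fs)


def generate_dataset(spec: SyntheticSpec, subject_id: str = "synthetic") -> tuple[Recording, Hypnogram]:
    """Continuous recording + hypnogram with 1-s cross-fades at boundaries.

    Epoch t of the output is synthesized from hypnogram stage t; each
    epoch extends 1 s into the next and the overlap is blended with
    complementary linear ramps, so windows re-cut across boundaries (as
    the sliding-window augmentation does) see smooth transitions.
    """
    hyp = sample_hypnogram(spec)
    spe = EPOCH_SEC * spec.fs
    fade = spec.fs  # 1-s cross-fade
    total = spec.n_epochs * spe
    out = np.zeros(total)
    ramp_up = np.linspace(0.0, 1.0, fade, endpoint=False)
    for ep in range(spec.n_epochs):
        last = ep == spec.n_epochs - 1
        n = spe if last else spe + fade
        x = _synthesize(hyp.labels[ep], spec, _epoch_rng(spec, ep), n)
        w = np.ones(n)
        if ep > 0:
            w[:fade] = ramp_up
        if not last:
            w[-fade:] = 1.0 - ramp_up
        start = ep * spe
        out[start : start + n] += x * w
    return Recording(out, fs=spec.fs, channel="EEG", subject_id=subject_id), hyp


def generate_subjects(
    spec: SyntheticSpec, n_subjects: int
) -> list[tuple[Recording, Hypnogram]]:
    """Independent recordings for several subjects (seeds offset per subject)."""
    from dataclasses import replace

    out = []
    for s in range(n_subjects):
        sub_spec = replace(spec, seed=int(np.random.SeedSequence(entropy=spec.seed, spawn_key=(10_000 + s,)).generate_state(1)[0] % (2**31)))
        out.append(generate_dataset(sub_spec, subject_id=f"S{s:02d}"))
    return out
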