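"""Synthetic multichannel EEG with state-dependent directed coupling.

The generator emulates what the pipeline's discriminative statistic —
directed transfer entropy between channels — actually measures: each
recording is a stable VAR(2) process whose diagonal is a per-channel
resonant AR(2) background (1/f-ish, band-limited rhythms between roughly
6 and 20 Hz) and whose off-diagonal lag-1 terms encode a sparse, directed,
state-specific coupling topology.  Mental-state classes therefore differ in
*which channels drive which*, mirroring how stress alters causal
interaction strength between brain regions, while the marginal spectra stay
comparable.

On top of the VAR background the generator adds the nuisance structure the
preprocessing stages exist to remove: a 50 Hz line-interference sinusoid,
Poisson-timed ocular-type transients (low-frequency raised-cosine bumps,
5–10× the background SD, confined to the designated "frontal" channels),
and white sensor noise.  One global seed drives all randomness; per-state
substreams are derived deterministically from the state's position in the
state list, so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Recording, get_logger
from .preprocess import EpochSet, epoch, preprocess_recording

__all__ = ["SimSpec", "simulate_recording", "simulate_dataset", "two_state_spec", "three_state_spec"]

_log = get_logger("simulate")

Edge = tuple[int, int, float]  # (source channel, destination channel, gain)


@dataclass
class SimSpec:
    """Everything needed to generate one labeled multi-state dataset."""

    n_channels: int = 32
    fs: float = 512.0
    duration_seconds: float = 300.0            # per state: one 5 min block
    states: list[str] = field(default_factory=lambda: ["baseline", "stress"])
    coupling: dict[str, list[Edge]] = field(default_factory=dict)
    ar_coeffs: np.ndarray | None = None        # (n_channels, 2); None → defaults
    line_amp: float = 5.0                      # 50 Hz amplitude, µV
    line_freq: float = 50.0
    artifact_rate: float = 6.0                 # ocular transients per minute
    artifact_channels: int = 4                 # leading "frontal" channels
    noise_sd: float = 0.5                      # white sensor noise, µV
    innovation_sd: float = 1.0                 # VAR driving noise, µV
    seed: int = 0
    burn_in: int = 2048

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need ≥ 2 channels")
        if self.fs <= 0 or self.duration_seconds <= 0:
            raise ValueError("fs and duration_seconds must be positive")
        if len(set(self.states)) != len(self.states):
            raise ValueError("state names must be unique")
        if self.ar_coeffs is None:
            self.ar_coeffs = _default_ar_coeffs(self.n_channels, self.fs)
        self.ar_coeffs = np.asarray(self.ar_coeffs, dtype=float)
        if self.ar_coeffs.shape != (self.n_channels, 2):
            raise ValueError(f"ar_coeffs must be ({self.n_channels}, 2)")
        for ch, (a1, a2) in enumerate(self.ar_coeffs):
            roots = np.roots([1.0, -a1, -a2])
            if np.abs(roots).max() >= 1.0:
                raise ValueError(f"channel {ch}: AR(2) roots not inside the unit circle")
        for state, edges in self.coupling.items():
            if state not in self.states:
                raise ValueError(f"coupling given for unknown state {state!r}")
            for s, d, g in edges:
                if not (0 <= s < self.n_channels and 0 <= d < self.n_channels) or s == d:
                    raise ValueError(f"invalid edge {s}→{d}")
                if not (0 <= g < 1):
                    raise ValueError(f"edge gain must be in [0, 1), got {g}")

    def var_matrices(self, state: str) -> tuple[np.ndarray, np.ndarray]:
        """Lag-1 and lag-2 coefficient matrices for one state."""
        n = self.n_channels
        A1 = np.diag(self.ar_coeffs[:, 0]).astype(float)
        A2 = np.diag(self.ar_coeffs[:, 1]).astype(float)
        for s, d, g in self.coupling.get(state, []):
            A1[d, s] += g
        return A1, A2

    def validate_stability(self, state: str) -> float:
        """Spectral radius of the VAR(2) companion matrix; raises if ≥ 1."""
        A1, A2 = self.var_matrices(state)
        n = self.n_channels
        comp = np.zeros((2 * n, 2 * n))
        comp[:n, :n] = A1
        comp[:n, n:] = A2
        comp[n:, :n] = np.eye(n)
        radius = float(np.abs(np.linalg.eigvals(comp)).max())
        if radius >= 1.0:
            raise ValueError(
                f"state {state!r}: VAR companion spectral radius {radius:.4f} ≥ 1 (non-stationary)"
            )
        return radius


def _default_ar_coeffs(n_channels: int, fs: float) -> np.ndarray:
    """Resonant AR(2) backgrounds with peak frequencies spread over 6–20 Hz."""
    freqs = np.linspace(6.0, 20.0, n_channels)
    r = 0.95
    theta = 2.0 * np.pi * freqs / fs
    a1 = 2.0 * r * np.cos(theta)
    a2 = -np.full(n_channels, r * r)
    return np.column_stack([a1, a2])


def _state_rng(spec: SimSpec, state: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, spec.states.index(state)])


def _ocular_bumps(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float,
    rate_per_min: float, target_channels: int, background_sd: float,
) -> np.ndarray:
    """Poisson-timed raised-cosine transients on the leading channels.

    Bump durations of 0.33–2 s put their energy in the 0.5–3 Hz band;
    amplitudes are 5–10× the background SD, as blink deflections dwarf
    ongoing EEG.
    """
    out = np.zeros((n_channels, n_samples))
    n_events = rng.poisson(rate_per_min * n_samples / fs / 60.0)
    for _ in range(n_events):
        half_period = rng.uniform(1.0 / 6.0, 1.0)  # seconds; 0.5–3 Hz content
        width = int(2 * half_period * fs)
        start = rng.integers(0, max(1, n_samples - width))
        amp = rng.uniform(5.0, 10.0) * background_sd
        t = np.arange(width) / width
        bump = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
        for ch in range(min(target_channels, n_channels)):
            out[ch, start:start + width] += bump * rng.uniform(0.6, 1.0)
    return out


def simulate_recording(spec: SimSpec, state: str) -> Recording:
    """One continuous recording for one state (validates stationarity first)."""
    if state not in spec.states:
        raise ValueError(f"unknown state {state!r}; spec defines {spec.states}")
    spec.validate_stability(state)
    rng = _state_rng(spec, state)
    n = spec.n_channels
    total = int(spec.fs * spec.duration_seconds) + spec.burn_in
    A1, A2 = spec.var_matrices(state)
    innov = rng.standard_normal((n, total)) * spec.innovation_sd
    x = np.zeros((n, total))
    for t in range(2, total):
        x[:, t] = A1 @ x[:, t - 1] + A2 @ x[:, t - 2] + innov[:, t]
    x = x[:, spec.burn_in:]
    n_samples = x.shape[1]
    tt = np.arange(n_samples) / spec.fs
    if spec.line_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, n)
        x = x + spec.line_amp * np.sin(2 * np.pi * spec.line_freq * tt + phases[:, None])
    if spec.artifact_rate > 0:
        background_sd = float(np.median(x.std(axis=1)))
        x = x + _ocular_bumps(
            rng, n, n_samples, spec.fs, spec.artifact_rate,
            spec.artifact_channels, background_sd,
        )
    if spec.noise_sd > 0:
        x = x + rng.standard_normal((n, n_samples)) * spec.noise_sd
    return Recording(
        data=x, fs=spec.fs,
        meta={"state": state, "seed": spec.seed, "simulated": True},
    )


def simulate_dataset(
    spec: SimSpec,
    window_seconds: float = 2.0,
    band_low: float = 0.5,
    band_high: float = 60.0,
    notch: float = 50.0,
    preprocess: bool = True,
) -> EpochSet:
    """Simulate every state, preprocess, epoch, and shuffle.

    Returns one pooled :class:`EpochSet` with labels equal to state names,
    shuffled deterministically with the spec seed.  ICA denoising is not
    applied here; the end-to-end pipeline inserts it before epoching.
    """
    if len(spec.states) < 2:
        raise ValueError("need ≥ 2 states to build a labeled dataset")
    sets = []
    for state in spec.states:
        rec = simulate_recording(spec, state)
        if preprocess:
            rec = preprocess_recording(rec, band_low, band_high, notch)
        sets.append(epoch(rec, window_seconds, label=state))
        _log.info("state %s: %d epochs", state, len(sets[-1]))
    pooled = EpochSet.concatenate(sets)
    return pooled.shuffled(np.random.default_rng([spec.seed, len(spec.states), 7]))


def _disjoint_pairings(n_channels: int, n_edges: int, offset: int, gain: float) -> list[Edge]:
    """Directed edges over disjoint channel pairs (a DAG, hence always stable)."""
    edges = []
    for i in range(n_edges):
        s = (2 * i + offset) % n_channels
        d = (2 * i + 1 + offset) % n_channels
        edges.append((s, d, gain))
    return edges


def two_state_spec(seed: int = 0, duration_seconds: float = 300.0, gain: float = 0.8) -> SimSpec:
    """Benchmark spec: two states with distinct sparse coupling topologies.

    Each state couples 12 disjoint channel pairs; the pair sets (and hence
    the directed TE fingerprints) differ between states.  Because each
    state's graph is a union of single edges with no feedback, stationarity
    holds for any gain < 1.
    """
    return SimSpec(
        seed=seed,
        duration_seconds=duration_seconds,
        states=["baseline", "stress"],
        coupling={
            "baseline": _disjoint_pairings(32, 12, 0, gain),
            "stress": _disjoint_pairings(32, 12, 7, gain),
        },
    )


def three_state_spec(seed: int = 0, duration_seconds: float = 300.0, gain: float = 0.8) -> SimSpec:
    """Ternary benchmark: baseline / working-memory / risk-task style states."""
    return SimSpec(
        seed=seed,
        duration_seconds=duration_seconds,
        states=["baseline", "2-back", "BART"],
        coupling={
            "baseline": _disjoint_pairings(32, 12, 0, gain),
            "2-back": _disjoint_pairings(32, 12, 7, gain),
            "BART": _disjoint_pairings(32, 12, 15, gain),
        },
    )
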