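"""Standardization chain for raw EEG: baseline correction, common average
reference, zero-phase band-pass + notch filtering, and non-overlapping
epoching.

The chain order is fixed — baseline → CAR → filters → (ICA) → epoching —
and all operations except epoching preserve shape and sampling rate.
Filters are a 4th-order Butterworth band-pass plus a second-order IIR notch
(Q = 30), both applied forward–backward (``filtfilt``) so epoch timing is
not skewed by filter group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io_formats import Recording

__all__ = [
    "EpochSet",
    "baseline_correct",
    "common_average_reference",
    "bandpass_notch",
    "epoch",
    "preprocess_recording",
]


@dataclass
class EpochSet:
    """Fixed-length labeled windows cut from one or more recordings.

    ``epochs`` has shape (n_epochs, channels, window_samples); ``labels``
    holds one state name per epoch.
    """

    epochs: np.ndarray
    labels: list[str]
    fs: float
    window_samples: int

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D: (n_epochs, channels, window_samples)")
        if self.epochs.shape[2] != self.window_samples:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != window_samples {self.window_samples}"
            )
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError(
                f"labels length {len(self.labels)} != epoch count {self.epochs.shape[0]}"
            )

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    @staticmethod
    def concatenate(sets: Sequence["EpochSet"]) -> "EpochSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        fs = sets[0].fs
        ws = sets[0].window_samples
        for s in sets[1:]:
            if s.fs != fs or s.window_samples != ws:
                raise ValueError("EpochSets differ in fs or window length")
        return EpochSet(
            epochs=np.concatenate([s.epochs for s in sets], axis=0),
            labels=[lab for s in sets for lab in s.labels],
            fs=fs,
            window_samples=ws,
        )

    def shuffled(self, rng: np.random.Generator) -> "EpochSet":
        order = rng.permutation(len(self))
        return EpochSet(
            epochs=self.epochs[order],
            labels=[self.labels[i] for i in order],
            fs=self.fs,
            window_samples=self.window_samples,
        )


def baseline_correct(rec: Recording) -> Recording:
    """Subtract each channel's mean so every channel is zero-mean."""
    return rec.copy_with(rec.data - rec.data.mean(axis=1, keepdims=True))


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference each channel against the instantaneous mean of all channels.

    At every sample, the cross-channel mean of the output is zero.  Undefined
    (and rejected) for single-channel recordings.
    """
    if rec.n_channels < 2:
        raise ValueError("common average reference requires ≥ 2 channels")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def design_bandpass(low: float, high: float, fs: float, order: int = 4):
    """Butterworth band-pass coefficients (b, a)."""
    return sps.butter(order, [low, high], btype="bandpass", fs=fs)


def design_notch(freq: float, fs: float, q: float = 30.0):
    """Second-order IIR notch coefficients (b, a)."""
    return sps.iirnotch(freq, q, fs=fs)


def bandpass_notch(
    rec: Recording,
    low: float = 0.5,
    high: float = 60.0,
    notch: float = 50.0,
) -> Recording:
    """Zero-phase band-pass (Butterworth, order 4) plus 50 Hz-style notch.

    Passband gain is ≈ 1 (squared magnitude of the design, since the filter
    runs forward–backward); out-of-band components and the notch frequency
    are strongly attenuated.
    """
    fs = rec.fs
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band edges must satisfy 0 < low < high < fs/2, got ({low}, {high}) at fs={fs}")
    if not (low < notch < high):
        raise ValueError(f"notch frequency {notch} must lie inside the ({low}, {high}) pass band")
    b_bp, a_bp = design_bandpass(low, high, fs)
    b_n, a_n = design_notch(notch, fs)
    out = sps.filtfilt(b_bp, a_bp, rec.data, axis=1)
    out = sps.filtfilt(b_n, a_n, out, axis=1)
    return rec.copy_with(out)


def epoch(rec: Recording, window_seconds: float, label: str | None = None) -> EpochSet:
    """Cut a recording into contiguous non-overlapping windows.

    The trailing remainder shorter than one window is discarded.  Every
    epoch inherits the recording-level state label (``label`` argument, or
    ``rec.meta['state']``).
    """
    window_samples = int(round(rec.fs * window_seconds))
    if rec.n_samples < window_samples:
        raise ValueError(
            f"recording has {rec.n_samples} samples, shorter than one "
            f"{window_samples}-sample window"
        )
    n_epochs = rec.n_samples // window_samples
    trimmed = rec.data[:, : n_epochs * window_samples]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, window_samples).transpose(1, 0, 2)
    state = label if label is not None else str(rec.meta.get("state", "unlabeled"))
    return EpochSet(
        epochs=epochs.copy(),
        labels=[state] * n_epochs,
        fs=rec.fs,
        window_samples=window_samples,
    )


def preprocess_recording(
    rec: Recording,
    low: float = 0.5,
    high: float = 60.0,
    notch: float = 50.0,
) -> Recording:
    """Apply the continuous-signal part of the chain: baseline → CAR → filters."""
    return bandpass_notch(common_average_reference(baseline_correct(rec)), low, high, notch)
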