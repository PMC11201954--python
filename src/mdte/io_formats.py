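"""Recordings, pipeline configuration, and file I/O.

The pipeline's raw unit is a :class:`Recording` — a channels × samples
matrix in microvolts with a sampling rate and channel labels.  Recordings
can be read from EDF (European Data Format) via MNE or from plain delimited
text matrices (one row per channel); a minimal EDF+ writer is provided so
simulated data can round-trip through the same interchange format real
amplifier exports use.

Configuration is a single flat :class:`PipelineConfig` loaded from JSON;
unspecified keys fall back to the pipeline defaults (512 Hz sampling,
2 s windows, 0.5–60 Hz band, 50 Hz notch, FrFT orders {0, 0.5, 1},
3×3 PCANet patches with 9 filters per stage, 32×32 blocks at 0.5 overlap,
linear SVM with C = 2, 10-fold CV).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import struct
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

__all__ = [
    "Recording",
    "PipelineConfig",
    "FormatError",
    "read_edf",
    "write_edf",
    "read_matrix",
    "write_matrix",
    "load_config",
    "dump_config",
    "get_logger",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


_LOG_FORMAT = "%(asctime)s [%(name)s] %(levelname)s: %(message)s"


def get_logger(stage: str) -> logging.Logger:
    """Return a stage-tagged logger emitting to stderr."""
    logger = logging.getLogger(f"mdte.{stage}")
    if not logger.handlers and not logging.getLogger("mdte").handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        root = logging.getLogger("mdte")
        root.addHandler(handler)
        if root.level == logging.NOTSET:
            root.setLevel(logging.INFO)
    return logger


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data
        Real matrix of shape (channels, samples), in microvolts.
    fs
        Sampling rate in Hz; must be positive.
    channel_names
        One label per channel, ordered as stored.  Channel order is
        authoritative; no montage-based reordering is ever applied.
    meta
        Free-form provenance map (e.g. state label, simulation seed).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels × samples), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError(f"data must have ≥1 channel and ≥1 sample, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"channel_names length {len(self.channel_names)} != channel count {self.data.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, **meta_updates: Any) -> "Recording":
        """New Recording sharing fs/names, with replaced data and updated meta."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Recording(data=data, fs=self.fs, channel_names=list(self.channel_names), meta=meta)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with field-level validation."""

    fs: float = 512.0
    window_seconds: float = 2.0
    band_low: float = 0.5
    band_high: float = 60.0
    notch: float = 50.0
    frft_orders: tuple[float, ...] = (0.0, 0.5, 1.0)
    tren_k: int = 1
    tren_lag: int = 1
    tren_bins: int = 8
    pcanet_k1: int = 3
    pcanet_k2: int = 3
    pcanet_l1: int = 9
    pcanet_l2: int = 9
    block_h: int = 32
    block_w: int = 32
    overlap_ratio: float = 0.5
    svm_c: float = 2.0
    cv_folds: int = 10
    ica_kurtosis_threshold: float = 5.0
    ica_reject: list[int] | None = None  # manual override; None = automatic
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_seconds > 0:
            raise ValueError(f"window_seconds must be positive, got {self.window_seconds}")
        if not (0 < self.band_low < self.band_high < self.fs / 2):
            raise ValueError(
                f"band edges must satisfy 0 < low < high < fs/2, "
                f"got low={self.band_low}, high={self.band_high}, fs={self.fs}"
            )
        if not (self.band_low < self.notch < self.band_high):
            raise ValueError(f"notch {self.notch} must lie inside the pass band")
        for key in ("tren_k", "tren_lag"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be ≥ 1")
        if self.tren_bins < 2:
            raise ValueError("tren_bins must be ≥ 2")
        for key in ("pcanet_k1", "pcanet_k2", "pcanet_l1", "pcanet_l2", "block_h", "block_w"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be ≥ 1")
        if not (0 <= self.overlap_ratio < 1):
            raise ValueError(f"overlap_ratio must be in [0, 1), got {self.overlap_ratio}")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be ≥ 2")
        self.frft_orders = tuple(float(p) for p in self.frft_orders)

    @property
    def window_samples(self) -> int:
        return int(round(self.fs * self.window_seconds))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["frft_orders"] = list(self.frft_orders)
        return d


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a JSON document.

    Unspecified keys take the pipeline defaults; an empty document yields the
    full default configuration.  Unknown keys raise, so typos do not silently
    fall back to defaults.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        if text.strip():
            try:
                raw = json.loads(text)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: not valid JSON: {exc}") from exc
            if not isinstance(raw, dict):
                raise FormatError(f"{path}: config document must be a JSON object")
    if overrides:
        raw.update(overrides)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config validation failed: {exc}") from exc


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Delimited text matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, fs: float, delimiter: str | None = None) -> Recording:
    """Read a delimited numeric matrix (one row per channel) as a Recording.

    ``delimiter=None`` auto-detects comma vs tab from the first line.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file — cannot build a Recording")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    rows: list[list[float]] = []
    width: int | None = None
    for r, line in enumerate(lines):
        cells = line.split(delimiter)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise FormatError(f"{path}: ragged rows — row {r} has {len(cells)} cells, expected {width}")
        row: list[float] = []
        for c, cell in enumerate(cells):
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}") from exc
        rows.append(row)
    return Recording(data=np.array(rows, dtype=float), fs=fs, meta={"source": str(path)})


def write_matrix(rec_or_array: Recording | np.ndarray, path: str | Path, delimiter: str = ",") -> None:
    data = rec_or_array.data if isinstance(rec_or_array, Recording) else np.asarray(rec_or_array)
    np.savetxt(path, data, delimiter=delimiter, fmt="%.10g")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: Any, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # numeric fields: shorten via repr precision rather than truncate digits
        if isinstance(value, float):
            s = f"{value:.{max(width - 8, 1)}g}"
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt8(value: float) -> str:
    """Most precise representation of a float that fits an 8-char EDF field."""
    for prec in range(10, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{value:.0e}"[:8]


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as EDF+ with 16-bit samples.

    Signals are stored in microvolts with per-channel physical scaling, so
    the quantization step is (max − min)/(2¹⁶ − 1) per channel.  Uses 1 s
    data records when the sample count divides evenly by ``fs``, otherwise a
    single record spanning the whole signal.
    """
    path = Path(path)
    data = rec.data
    n_ch, n_samp = data.shape
    fs = rec.fs
    if float(fs).is_integer() and n_samp % int(fs) == 0:
        spr = int(fs)  # samples per record
        record_dur = 1.0
    else:
        spr = n_samp
        record_dur = n_samp / fs
    n_records = n_samp // spr

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid a zero physical span for constant channels
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + dig_min).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(header_bytes, 8),
        _edf_field("EDF+C", 44),
        _edf_field(n_records, 8),
        _edf_field(f"{record_dur:g}", 8),
        _edf_field(n_ch, 4),
    ])
    per_signal: list[bytes] = []
    for width, values in [
        (16, rec.channel_names),
        (80, [""] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [_fmt8(v) for v in phys_min]),
        (8, [_fmt8(v) for v in phys_max]),
        (8, [dig_min] * n_ch),
        (8, [dig_max] * n_ch),
        (80, [""] * n_ch),
        (8, [spr] * n_ch),
        (32, [""] * n_ch),
    ]:
        per_signal.extend(_edf_field(v, width) for v in values)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(per_signal))
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (microvolts), via MNE.

    The sampling rate and channel labels come from the EDF header; MNE
    returns data in volts, which is rescaled to µV here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # reject non-EDF input up front with a format error naming the file
    with open(path, "rb") as fh:
        head = fh.read(8)
    if not head.startswith(b"0"):
        raise FormatError(f"{path}: not an EDF file (bad version field in header)")
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6
    return Recording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=[str(name) for name in raw.ch_names],
        meta={"source": str(path)},
    )
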