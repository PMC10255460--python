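"""Reading and writing EEG and gaze recordings.

Two on-disk dialects are supported for EEG: a long-form CSV (one column per
channel, ``time_s`` first) and standard EDF with one signal per channel in
microvolts.  Gaze streams use a GazePoint-style CSV export with pupil
diameters in millimetres and per-eye validity flags.

CSV round-trips are lossless (floats are written with shortest-repr
precision); EDF round-trips are exact up to its 16-bit quantization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS

logger = logging.getLogger(__name__)

GAZE_CSV_COLUMNS = (
    "time_s", "gaze_x", "gaze_y",
    "pupil_left_mm", "pupil_right_mm", "valid_left", "valid_right",
)


class SchemaError(ValueError):
    """A file did not match the expected column schema or timing contract."""


@dataclass
class EEGRecording:
    """Multichannel uniformly sampled EEG signal in microvolts.

    ``data`` is a ``(n_channels, n_samples)`` array; ``channels`` gives the
    row order.  Samples are assumed uniform at ``rate`` starting at
    ``start_time`` seconds.
    """

    rate: float
    channels: list[str]
    data: np.ndarray
    start_time: float = 0.0
    unknown_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass
class GazeRecording:
    """60 Hz gaze/pupil stream with per-eye validity flags.

    Gaze coordinates are screen degrees (or normalized units, declared by
    the producer); pupil diameters are millimetres.  ``time`` is
    authoritative and must be strictly increasing.
    """

    rate: float
    time: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        arrays = [self.time, self.gaze_x, self.gaze_y, self.pupil_left,
                  self.pupil_right]
        self.time, self.gaze_x, self.gaze_y, self.pupil_left, self.pupil_right = (
            np.asarray(a, dtype=float) for a in arrays)
        self.valid_left = np.asarray(self.valid_left, dtype=bool)
        self.valid_right = np.asarray(self.valid_right, dtype=bool)
        n = len(self.time)
        for a in (self.gaze_x, self.gaze_y, self.pupil_left, self.pupil_right,
                  self.valid_left, self.valid_right):
            if len(a) != n:
                raise ValueError("all gaze arrays must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise SchemaError("non-monotonic time")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            rate=self.rate,
            time=self.time.copy(),
            gaze_x=self.gaze_x.copy(),
            gaze_y=self.gaze_y.copy(),
            pupil_left=self.pupil_left.copy(),
            pupil_right=self.pupil_right.copy(),
            valid_left=self.valid_left.copy(),
            valid_right=self.valid_right.copy(),
            n_rejected_rows=self.n_rejected_rows,
        )


_QUADRANTS = (
    "pleasant-aroused", "pleasant-relaxed",
    "unpleasant-relaxed", "unpleasant-aroused",
)


@dataclass(frozen=True)
class SessionLabel:
    """Condition label of one viewing: empathy flag plus emotion quadrant."""

    empathic: bool
    valence: str  # pleasant | unpleasant
    arousal: str  # aroused | relaxed
    subject_id: int = 0
    video_id: int = 0

    def __post_init__(self) -> None:
        if self.valence not in ("pleasant", "unpleasant"):
            raise ValueError(f"invalid valence {self.valence!r}")
        if self.arousal not in ("aroused", "relaxed"):
            raise ValueError(f"invalid arousal {self.arousal!r}")

    @property
    def quadrant(self) -> str:
        return f"{self.valence}-{self.arousal}"

    @property
    def condition(self) -> str:
        return "empathic" if self.empathic else "non_empathic"


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "edf" if str(path).lower().endswith(".edf") else "csv"


def read_eeg(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording from CSV or EDF.

    CSV must carry a ``time_s`` column and one column per expected 10-20
    channel; extra columns are preserved as channels but flagged in
    ``unknown_channels``.  Timestamps must be uniform within one sample.
    """
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise SchemaError("missing required column 'time_s'")
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing channel column(s): {', '.join(missing)}")
    extras = [c for c in df.columns if c not in CHANNELS and c != "time_s"]
    if extras:
        logger.warning("unknown channel columns preserved: %s", extras)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError("EEG CSV must contain at least two samples")
    dt = np.diff(t)
    rate = 1.0 / np.median(dt)
    if np.any(np.abs(dt - np.median(dt)) > 1.0 / rate):
        raise SchemaError("non-uniform timestamps beyond one-sample tolerance")
    channels = list(CHANNELS) + extras
    data = df[channels].to_numpy(dtype=float).T
    return EEGRecording(rate=float(np.round(rate, 6)), channels=channels,
                        data=data, start_time=float(t[0]),
                        unknown_channels=extras)


def write_eeg(recording: EEGRecording, path: str | Path,
              format: str | None = None) -> None:
    """Write an EEG recording to CSV or EDF."""
    if recording.n_samples == 0 or not recording.channels:
        raise ValueError("refusing to write an empty recording")
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(recording, path)
        return
    df = pd.DataFrame({"time_s": recording.times})
    for name, row in zip(recording.channels, recording.data):
        df[name] = row
    df.to_csv(path, index=False)


def read_gaze(path: str | Path,
              column_map: dict[str, str] | None = None) -> GazeRecording:
    """Read a gaze CSV (GazePoint-style dialect, see ``GAZE_CSV_COLUMNS``).

    Vendor exports with different headers are supported through
    ``column_map``, a ``{file_column: schema_column}`` rename applied
    before validation.  Rows with unparseable numeric fields are dropped
    and counted in ``n_rejected_rows``.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in GAZE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    numeric = ["time_s", "gaze_x", "gaze_y", "pupil_left_mm", "pupil_right_mm"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[numeric].isna().any(axis=1)
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning("rejected %d unparseable gaze rows", n_rejected)
        df = df[~bad]
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError("gaze CSV must contain at least two samples")
    rate = 1.0 / np.median(np.diff(t))
    return GazeRecording(
        rate=float(np.round(rate, 6)),
        time=t,
        gaze_x=df["gaze_x"].to_numpy(dtype=float),
        gaze_y=df["gaze_y"].to_numpy(dtype=float),
        pupil_left=df["pupil_left_mm"].to_numpy(dtype=float),
        pupil_right=df["pupil_right_mm"].to_numpy(dtype=float),
        valid_left=df["valid_left"].to_numpy().astype(bool),
        valid_right=df["valid_right"].to_numpy().astype(bool),
        n_rejected_rows=n_rejected,
    )


def write_gaze(recording: GazeRecording, path: str | Path) -> None:
    if recording.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    df = pd.DataFrame({
        "time_s": recording.time,
        "gaze_x": recording.gaze_x,
        "gaze_y": recording.gaze_y,
        "pupil_left_mm": recording.pupil_left,
        "pupil_right_mm": recording.pupil_right,
        "valid_left": recording.valid_left.astype(int),
        "valid_right": recording.valid_right.astype(int),
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------
# Minimal EDF writer: one signal per channel, physical dimension uV, 16-bit
# samples, 1 s data records.  No installed library writes EDF, so the format
# is emitted directly; reading goes through mne, which doubles as an
# independent check that the files are standard.

def _write_edf(recording: EEGRecording, path: str | Path) -> None:
    rate = recording.rate
    spr = int(round(rate))  # samples per 1 s record
    if abs(spr - rate) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    data = recording.data
    n_samples = data.shape[1]
    n_records = int(np.ceil(n_samples / spr))
    pad = n_records * spr - n_samples
    if pad:
        data = np.pad(data, ((0, 0), (0, pad)), mode="edge")
    nch = len(recording.channels)

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid degenerate scaling for flat channels
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def pad_field(value: str, width: int) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad_field("0", 8),                       # version
        pad_field("X X X X", 80),                # patient id
        pad_field("Startdate X X X X", 80),      # recording id
        pad_field("01.01.00", 8),                # start date
        pad_field("00.00.00", 8),                # start time
        pad_field(str(256 * (nch + 1)), 8),      # header bytes
        pad_field("", 44),                       # reserved
        pad_field(str(n_records), 8),
        pad_field("1", 8),                       # record duration (s)
        pad_field(str(nch), 4),
    ])
    per_signal = b"".join([
        b"".join(pad_field(c, 16) for c in recording.channels),   # label
        b"".join(pad_field("", 80) for _ in range(nch)),          # transducer
        b"".join(pad_field("uV", 8) for _ in range(nch)),         # dimension
        b"".join(pad_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(nch)),
        b"".join(pad_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(nch)),
        b"".join(pad_field(str(dig_min), 8) for _ in range(nch)),
        b"".join(pad_field(str(dig_max), 8) for _ in range(nch)),
        b"".join(pad_field("", 80) for _ in range(nch)),          # prefilter
        b"".join(pad_field(str(spr), 8) for _ in range(nch)),
        b"".join(pad_field("", 32) for _ in range(nch)),          # reserved
    ])
    # physical min/max written with limited precision: quantize with the
    # values as printed so readers reconstruct exactly what we encoded
    pmin = np.array([float(f"{phys_min[i]:.6g}"[:8]) for i in range(nch)])
    pmax = np.array([float(f"{phys_max[i]:.6g}"[:8]) for i in range(nch)])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.rint((data - pmin[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def _read_edf(path: str | Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volts -> uV
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    extras = [n for n in names if n not in CHANNELS]
    return EEGRecording(rate=float(raw.info["sfreq"]), channels=names,
                        data=data, start_time=0.0, unknown_channels=extras)
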