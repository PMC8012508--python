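"""Reading, writing, validation and windowing of EPG voltage recordings.

An electrophytography (EPG) recording is a single channel of extracellular
micro-voltage differences (µV) sampled at a fixed rate, together with the
identity of the plant it came from and the experimental condition
(treatment and before/after phase).  Data files are plain delimited text
(CSV or TSV), one row per sample, with an optional leading time column;
metadata travels in a YAML sidecar next to the data file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

TREATMENTS = ("bean", "wheat", "control", "synthetic")
PHASES = ("before", "after", "none")

__all__ = [
    "Recording",
    "WindowSet",
    "read_recording",
    "write_recording",
    "expected_length",
    "segment",
    "sidecar_path",
]


@dataclass
class Recording:
    """One channel of micro-voltage variation ΔV with its condition labels.

    Parameters
    ----------
    samples : array-like of float
        Voltage values in µV.  Must be finite and at least two samples long.
    fs : float
        Sampling rate in Hz (62.5 Hz for the acquisition protocol this
        package targets; a 2 h segment then holds 450,000 samples).
    plant_id : str
        Identifier of the source plant / twig.
    treatment : str
        One of ``bean``, ``wheat``, ``control``, ``synthetic``.
    phase : str
        One of ``before``, ``after``, ``none`` (relative to the stimulus).
    channel : int
        Acquisition channel number.
    """

    samples: np.ndarray
    fs: float = 62.5
    plant_id: str = "unknown"
    treatment: str = "synthetic"
    phase: str = "none"
    channel: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a Recording needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with new sample values, same labels."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))

    @property
    def label(self) -> str:
        """Condition label, e.g. ``bean-after``."""
        return f"{self.treatment}-{self.phase}"


@dataclass
class WindowSet:
    """Overlapping analysis windows over a parent recording.

    ``windows`` is a list of half-open ``(start, length)`` index pairs,
    sorted by start; consecutive windows share
    ``round(overlap_fraction * length)`` samples.
    """

    parent: Recording
    windows: list[tuple[int, int]] = field(default_factory=list)
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        n = self.parent.n
        prev_start = -1
        for start, length in self.windows:
            if start <= prev_start:
                raise ValueError("windows must be sorted by start")
            if start < 0 or start + length > n:
                raise ValueError("window outside the recording")
            prev_start = start

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.arrays())

    def arrays(self) -> list[np.ndarray]:
        """Sample arrays, one per window (views into the parent)."""
        x = self.parent.samples
        return [x[s : s + w] for s, w in self.windows]


def expected_length(duration_s: float, fs: float) -> int:
    """Number of samples a recording of ``duration_s`` seconds at ``fs`` Hz holds.

    ``expected_length(7200, 62.5) == 450_000`` — the standard 2 h segment.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    return int(round(duration_s * fs))


def segment(
    rec: Recording, n_windows: int = 10, overlap_fraction: float = 0.3
) -> WindowSet:
    """Split a recording into ``n_windows`` windows overlapping by a fraction.

    The window length is the largest ``w`` such that ``n_windows`` windows
    with step ``w - round(overlap_fraction * w)`` fit into the series:
    ``w = floor(n / (n_windows - (n_windows - 1) * overlap_fraction))``.
    Remainder samples at the end of the series are dropped.  The default
    (10 windows, 30 % overlap) mirrors the windowing used for feature
    extraction in the classification stage.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    denom = n_windows - (n_windows - 1) * overlap_fraction
    w = math.floor(rec.n / denom + 1e-9)  # epsilon guards 7300/7.3 = 999.99…9
    # rounding in the step can push the last window past the end; shrink w
    # (never by more than a couple of samples) until the layout fits
    while w >= 2:
        step = w - int(round(overlap_fraction * w))
        if step >= 1 and (n_windows - 1) * step + w <= rec.n:
            break
        w -= 1
    else:
        raise ValueError(
            f"recording too short: n={rec.n} cannot hold {n_windows} windows "
            f"with overlap {overlap_fraction}"
        )
    starts = [i * step for i in range(n_windows)]
    return WindowSet(
        parent=rec,
        windows=[(s, w) for s in starts],
        overlap_fraction=overlap_fraction,
    )


def sidecar_path(path: Path | str) -> Path:
    """Metadata sidecar path for a data file: ``rec.csv`` -> ``rec.meta.yaml``."""
    p = Path(path)
    return p.with_suffix(".meta.yaml")


def _parse_table(path: Path) -> np.ndarray:
    """Parse a comma- or tab-delimited numeric table, erroring on bad rows."""
    rows: list[list[float]] = []
    ncols = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"non-numeric value in row {lineno} of {path}") from exc
            if any(not math.isfinite(v) for v in values):
                raise ValueError(f"non-finite sample in row {lineno} of {path}")
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ValueError(f"inconsistent column count in row {lineno} of {path}")
            rows.append(values)
    if not rows:
        raise ValueError(f"no data rows in {path}")
    return np.asarray(rows, dtype=np.float64)


def _looks_like_time(col: np.ndarray, fs: float) -> bool:
    if col.size < 3:
        return False
    d = np.diff(col)
    if np.any(d <= 0):
        return False
    # arithmetic progression with step close to the sampling interval
    return bool(np.allclose(d, 1.0 / fs, rtol=0.05, atol=1e-6))


def read_recording(
    path: Path | str,
    meta: Path | str | dict | None = None,
) -> list[Recording]:
    """Read a delimited-text recording file into one Recording per channel.

    ``meta`` is either a mapping of metadata fields, a path to a YAML/JSON
    sidecar, or None (the default sidecar next to ``path`` is used).  The
    metadata must contain ``fs``; ``plant_id``, ``treatment``, ``phase``
    and ``time_column`` (``auto``/True/False) are optional.  A leading
    time column is detected automatically under ``time_column: auto``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if meta is None:
        meta = sidecar_path(path)
    if isinstance(meta, (str, Path)):
        with open(meta, "r", encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "fs" not in meta:
        raise ValueError("metadata must provide the sampling rate 'fs'")
    fs = float(meta["fs"])

    data = _parse_table(path)
    time_column = meta.get("time_column", "auto")
    if time_column == "auto":
        time_column = data.shape[1] >= 2 and _looks_like_time(data[:, 0], fs)
    if time_column:
        data = data[:, 1:]
    if data.shape[1] == 0:
        raise ValueError("no voltage columns after removing the time column")

    common = dict(
        fs=fs,
        plant_id=str(meta.get("plant_id", "unknown")),
        treatment=str(meta.get("treatment", "synthetic")),
        phase=str(meta.get("phase", "none")),
    )
    first_channel = int(meta.get("channel", 1))
    return [
        Recording(samples=data[:, j], channel=first_channel + j, **common)
        for j in range(data.shape[1])
    ]


def write_recording(rec: Recording, path: Path | str) -> None:
    """Write a Recording as delimited text plus a YAML metadata sidecar.

    Values are printed with 17 significant digits so that a read/write
    round trip reproduces the samples bit-exactly.
    """
    path = Path(path)
    if rec.n < 2:
        raise ValueError("refusing to write an empty recording")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.samples, fmt="%.17g", delimiter=",")
    meta = {
        "fs": float(rec.fs),
        "plant_id": rec.plant_id,
        "treatment": rec.treatment,
        "phase": rec.phase,
        "channel": int(rec.channel),
        "time_column": False,
        "n": rec.n,
        "units": "uV",
    }
    with open(sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
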