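"""Reading, writing, resampling, scaling and windowing of motion time series.

All downstream stages assume the conventions fixed here: recordings are
column-per-axis CSV/TSV tables, resampling is anti-aliased and zero-phase,
amplitude normalisation is an invertible per-recording min-max affine map,
and fixed-length analysis windows tile a series from its start.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sps

__all__ = [
    "Task",
    "Pathology",
    "Recording",
    "AffineTransform",
    "read_recording",
    "write_recording",
    "downsample",
    "scale_affine",
    "segment_series",
]


class Task(str, enum.Enum):
    """Scripted assessment tasks; the first six capture static tremor."""

    REST_1 = "Rest-1"
    REST_2 = "Rest-2"
    POSTURE_1 = "Posture-1"
    POSTURE_2 = "Posture-2"
    LOAD_1 = "Load-1"
    LOAD_2 = "Load-2"
    ACTION = "Action"
    UNLABELED = "Unlabeled"


class Pathology(str, enum.Enum):
    PD = "PD"
    ET = "ET"
    HEALTHY = "Healthy"
    SYNTHETIC = "Synthetic"


@dataclass
class Recording:
    """A sampled multi-axis motion time series.

    ``samples`` has shape ``(n_samples, n_axes)``; axis k is labelled
    ``axes[k]``.  Units are arbitrary (accelerometer counts, g, or the
    unit-free pipeline scale after normalisation).
    """

    samples: np.ndarray
    rate_hz: float
    axes: tuple[str, ...] = ("x",)
    subject_id: str = ""
    task: Task = Task.UNLABELED
    pathology: Pathology = Pathology.SYNTHETIC

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be 1-D or (n_samples, n_axes)")
        if self.samples.shape[1] != len(self.axes):
            raise ValueError(
                f"{self.samples.shape[1]} sample columns but {len(self.axes)} axis labels"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("a Recording needs at least one sample")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        self.task = Task(self.task)
        self.pathology = Pathology(self.pathology)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    def axis(self, label: str) -> np.ndarray:
        """Return one axis as a 1-D array."""
        return self.samples[:, self.axes.index(label)]


@dataclass(frozen=True)
class AffineTransform:
    """An invertible map ``y = scale * x + offset``."""

    scale: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.scale == 0:
            raise ValueError("scale must be nonzero so the transform is invertible")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(x, dtype=float) + self.offset

    def invert(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.offset) / self.scale


def read_recording(
    path,
    *,
    axis_columns: list[str] | None = None,
    time_column: str = "time",
    rate_hz: float | None = None,
    sep: str = ",",
    **recording_kwargs,
) -> Recording:
    """Read a Recording from a one-header-row CSV/TSV file.

    Every numeric column except ``time_column`` is taken as an axis unless
    ``axis_columns`` names an explicit ordered subset.  ``rate_hz`` may be
    given directly; otherwise it is inferred from the time column (median
    sample interval).

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` with
    row/column context for non-numeric cells or ragged rows.
    """
    try:
        table = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    if axis_columns is None:
        axis_columns = [c for c in table.columns if c != time_column]
    missing = [c for c in axis_columns if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    data = np.empty((len(table), len(axis_columns)), dtype=float)
    for j, col in enumerate(axis_columns):
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy() & ~table[col].isna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric value {table[col].iloc[bad[0]]!r} "
                f"in column {col!r}, row {bad[0] + 1}"
            )
        if converted.isna().any():
            row = int(np.nonzero(converted.isna().to_numpy())[0][0])
            raise ValueError(f"{path}: missing value in column {col!r}, row {row + 1}")
        data[:, j] = converted.to_numpy(dtype=float)
    if rate_hz is None:
        if time_column in table.columns:
            t = pd.to_numeric(table[time_column], errors="coerce").to_numpy(dtype=float)
            dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
            rate_hz = 1.0 / dt if dt > 0 else 1.0
        else:
            rate_hz = 1.0
    return Recording(
        samples=data, rate_hz=float(rate_hz), axes=tuple(axis_columns), **recording_kwargs
    )


def write_recording(path, rec: Recording, *, sep: str = ",", time_column: str = "time") -> None:
    """Write a Recording as CSV/TSV with a time column; round-trips with
    :func:`read_recording` to printed precision."""
    t = np.arange(len(rec)) / rec.rate_hz
    table = pd.DataFrame({time_column: t})
    for j, label in enumerate(rec.axes):
        table[label] = rec.samples[:, j]
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")


def _resample_axis(x: np.ndarray, rate_hz: float, target_hz: float, n_out: int) -> np.ndarray:
    """Zero-phase anti-alias low-pass at 0.45*target_hz, then resample."""
    nyq = rate_hz / 2.0
    cutoff = 0.45 * target_hz
    if cutoff < nyq:
        sos = _sps.butter(8, cutoff / nyq, btype="low", output="sos")
        x = _sps.sosfiltfilt(sos, x)
    ratio = rate_hz / target_hz
    idx = np.arange(n_out) * ratio
    if float(ratio).is_integer():
        return x[idx.astype(int)]
    return np.interp(idx, np.arange(len(x)), x)


def downsample(rec: Recording, target_hz: float) -> Recording:
    """Reduce the sampling rate with anti-alias filtering before decimation.

    The spectral band of interest for hand tremor lies below ~15 Hz, so a
    zero-phase low-pass at 0.45*target_hz precedes decimation (no passband
    phase distortion; content below target_hz/2 preserved).  Output length
    is ``floor(len(rec) * target_hz / rate_hz)``; output sample k sits at
    input position ``k * rate_hz / target_hz`` (linear interpolation for
    non-integer decimation ratios).
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if target_hz >= rec.rate_hz:
        raise ValueError(
            f"target_hz ({target_hz}) must be below the recording rate ({rec.rate_hz})"
        )
    n_out = int(np.floor(len(rec) * target_hz / rec.rate_hz))
    out = np.column_stack(
        [
            _resample_axis(rec.samples[:, j], rec.rate_hz, target_hz, n_out)
            for j in range(rec.samples.shape[1])
        ]
    )
    return Recording(
        samples=out,
        rate_hz=float(target_hz),
        axes=rec.axes,
        subject_id=rec.subject_id,
        task=rec.task,
        pathology=rec.pathology,
    )


def scale_affine(
    series: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, AffineTransform]:
    """Min-max scale a series into ``[lo, hi]`` and return the transform used.

    The returned :class:`AffineTransform` maps original values to scaled
    ones; ``transform.invert`` recovers the input exactly.  A constant
    series has no min-max scaling and raises ``ValueError`` (callers that
    want a midpoint-fill policy must opt in explicitly).
    """
    if not hi > lo:
        raise ValueError("hi must exceed lo")
    x = np.asarray(series, dtype=float)
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if xmax == xmin:
        raise ValueError("constant series: min-max scaling undefined")
    scale = (hi - lo) / (xmax - xmin)
    transform = AffineTransform(scale=scale, offset=lo - scale * xmin)
    return transform.apply(x), transform


def segment_series(series: np.ndarray, window: int, stride: int) -> list[np.ndarray]:
    """Cut fixed-length windows starting at 0, stride, 2*stride, ...

    A trailing partial window is discarded; a series shorter than one
    window yields an empty list.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    x = np.asarray(series)
    return [x[s : s + window] for s in range(0, len(x) - window + 1, stride)]
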