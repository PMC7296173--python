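"""Reading, writing and basic manipulation of uniformly sampled signals.

The universal in-memory container is :class:`Signal`: a 1-D array of real
samples together with its sampling rate.  Plain-text CSV (one column of
values, or two columns of ``time,value``) and mono WAV files are supported,
which covers the common export paths of laboratory amplifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "Signal",
    "read_signal",
    "write_signal",
    "split_signed",
    "detrend",
]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : ndarray
        Signal values (arbitrary units, e.g. volts).  Must be 1-D, of
        length >= 1, and finite everywhere.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a 1-D array of length >= 1")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be a positive finite number, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "t0", float(self.t0))

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs


def _parse_text_rows(path: Path) -> list[tuple[int, list[float]]]:
    """Parse a permissive CSV: comma or whitespace delimited, '#' comments.

    Returns (1-based line number, row values) pairs; raises on non-numeric
    rows naming the offending line.
    """
    rows: list[tuple[int, list[float]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            try:
                rows.append((lineno, [float(p) for p in parts]))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value on line {lineno}: {text!r}"
                ) from None
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    return rows


def read_signal(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
) -> Signal:
    """Read a signal from a CSV or WAV file.

    Parameters
    ----------
    path : path-like
        File to read.
    format : {'csv_one_col', 'csv_two_col', 'wav'}, optional
        Input layout.  If omitted it is inferred: ``.wav`` extension means
        WAV, otherwise the column count of the first data row decides
        between the two CSV layouts.
    fs : float, optional
        Sampling rate in Hz.  Required for ``csv_one_col``; ignored (and
        checked against nothing) for the other formats, whose rate comes
        from the timestamps or the WAV header.

    Notes
    -----
    Two-column files must have uniformly spaced timestamps (relative
    tolerance 1e-6); the first column is time in seconds, the second the
    value.  Multi-channel WAV files are reduced to channel 0 with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if format is None:
        if path.suffix.lower() == ".wav":
            format = "wav"
        else:
            rows = _parse_text_rows(path)
            format = "csv_two_col" if len(rows[0][1]) >= 2 else "csv_one_col"
    else:
        rows = None

    if format == "wav":
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim == 2:
            warnings.warn(
                f"{path}: {data.shape[1]} channels found; using channel 0",
                stacklevel=2,
            )
            data = data[:, 0]
        return Signal(samples=data.astype(float), fs=float(rate))

    if format not in ("csv_one_col", "csv_two_col"):
        raise ValueError(f"unknown format {format!r}")

    if rows is None:
        rows = _parse_text_rows(path)

    if format == "csv_one_col":
        if fs is None:
            raise ValueError("fs must be provided for one-column CSV input")
        for lineno, row in rows:
            if len(row) != 1:
                raise ValueError(
                    f"{path}: expected 1 column on line {lineno}, got {len(row)}"
                )
        return Signal(samples=np.array([row[0] for _, row in rows]), fs=fs)

    # csv_two_col
    for lineno, row in rows:
        if len(row) != 2:
            raise ValueError(
                f"{path}: expected 2 columns on line {lineno}, got {len(row)}"
            )
    t = np.array([row[0] for _, row in rows])
    x = np.array([row[1] for _, row in rows])
    if t.size < 2:
        raise ValueError(f"{path}: need >= 2 rows to infer sampling rate")
    dt = np.diff(t)
    dt_mean = dt.mean()
    if dt_mean <= 0:
        raise ValueError(f"{path}: timestamps must be increasing")
    dev = np.abs(dt - dt_mean).max()
    if dev > 1e-6 * dt_mean:
        raise ValueError(
            f"{path}: non-uniform timestamps, max deviation {dev:.3g} s "
            f"from mean step {dt_mean:.3g} s"
        )
    return Signal(samples=x, fs=1.0 / dt_mean, t0=float(t[0]))


def write_signal(path: str | Path, signal: Signal, format: str | None = None) -> None:
    """Write a signal to CSV (one or two columns) or WAV (float32 mono)."""
    path = Path(path)
    if format is None:
        format = "wav" if path.suffix.lower() == ".wav" else "csv_two_col"
    if format == "wav":
        wavfile.write(path, int(round(signal.fs)), signal.samples.astype(np.float32))
    elif format == "csv_one_col":
        np.savetxt(path, signal.samples, fmt="%.17g")
    elif format == "csv_two_col":
        np.savetxt(
            path,
            np.column_stack([signal.times, signal.samples]),
            fmt="%.17g",
            delimiter=",",
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def split_signed(signal: Signal) -> tuple[Signal, Signal]:
    """Split a signal into its positive part and negated negative part.

    Returns ``(pos, neg)`` with ``pos = max(x, 0)`` and ``neg = max(-x, 0)``
    elementwise, so that ``pos - neg`` reconstructs the input exactly.  Both
    outputs share the input's sampling rate and start time.  Biphasic spike
    signals are analysed by transforming the two parts separately and
    summing the resulting powers.
    """
    x = signal.samples
    pos = np.maximum(x, 0.0)
    neg = np.maximum(-x, 0.0)
    return (
        Signal(samples=pos, fs=signal.fs, t0=signal.t0),
        Signal(samples=neg, fs=signal.fs, t0=signal.t0),
    )


def detrend(signal: Signal, method: str = "none", fc: float | None = None) -> Signal:
    """Optionally remove slow baseline components.

    method 'none' returns the input unchanged, 'subtract_mean' removes the
    mean, and 'highpass' applies a zero-phase 4th-order Butterworth
    high-pass with cutoff ``fc`` Hz (must be below Nyquist).  The default is
    'none': no particular drift-removal procedure is assumed, this is
    offered only as a convenience for signals with obvious baseline wander.
    """
    if method == "none":
        return signal
    if method == "subtract_mean":
        return Signal(
            samples=signal.samples - signal.samples.mean(),
            fs=signal.fs,
            t0=signal.t0,
        )
    if method == "highpass":
        if fc is None:
            raise ValueError("fc is required for method='highpass'")
        if not 0 < fc < signal.fs / 2:
            raise ValueError(
                f"highpass cutoff {fc} Hz must lie in (0, Nyquist={signal.fs / 2} Hz)"
            )
        sos = butter(4, fc, btype="highpass", fs=signal.fs, output="sos")
        return Signal(
            samples=sosfiltfilt(sos, signal.samples), fs=signal.fs, t0=signal.t0
        )
    raise ValueError(f"unknown detrend method {method!r}")
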