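"""Threshold-crossing spike detection: the conventional comparison method.

A threshold is placed a chosen proportion of the way from the signal mean to
the signal maximum; each contiguous run of supra-threshold samples counts as
one spike, timed at the run's maximum.  The distribution of inverse
inter-spike intervals then estimates the firing-frequency distribution.
Simple and precise when spikes are clean, but sensitive to the threshold
choice: spikes with noisy heights randomly fall below it, doubling apparent
intervals and producing subharmonic artifacts.
"""

from __future__ import annotations

import numpy as np

from .signal_io import Signal
from .simulate import SpikeTrain

__all__ = ["detect_peaks", "isi_histogram"]


def detect_peaks(signal: Signal, threshold_prop: float) -> SpikeTrain:
    """Detect spikes as contiguous runs of samples above a threshold.

    The threshold is ``mean + threshold_prop * (max - mean)``:
    ``threshold_prop`` runs from 0 (the signal mean) to 1 (the signal
    maximum).  Each supra-threshold run yields one spike at the time of its
    maximum sample (first sample on ties).  A constant signal yields no
    spikes, since nothing exceeds the threshold.
    """
    if not 0 <= threshold_prop <= 1:
        raise ValueError("threshold_prop must lie in [0, 1]")
    x = signal.samples
    threshold = x.mean() + threshold_prop * (x.max() - x.mean())
    above = x > threshold
    if not above.any():
        return SpikeTrain(times=np.array([]), duration=signal.duration)
    edges = np.diff(above.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [x.size]])
    spike_idx = np.array([a + np.argmax(x[a:b]) for a, b in zip(starts, ends)])
    return SpikeTrain(times=spike_idx / signal.fs, duration=signal.duration)


def isi_histogram(train: SpikeTrain, freq_grid: np.ndarray) -> np.ndarray:
    """Histogram of inverse inter-spike intervals on a log-frequency grid.

    Bin edges sit at the geometric midpoints between adjacent grid
    frequencies (the outer bins extend symmetrically, in log, beyond the
    ends).  Counts are normalized to sum to 1; rates falling outside the
    grid are dropped; fewer than two spikes give an all-zero histogram.
    """
    freq_grid = np.asarray(freq_grid, dtype=float)
    if freq_grid.ndim != 1 or np.any(np.diff(freq_grid) <= 0):
        raise ValueError("freq_grid must be 1-D and strictly increasing")
    out = np.zeros(freq_grid.size)
    if train.times.size < 2:
        return out
    rates = train.inverse_isis
    if freq_grid.size == 1:
        out[0] = 1.0
        return out
    inner = np.sqrt(freq_grid[:-1] * freq_grid[1:])
    ratio = np.sqrt(freq_grid[1] / freq_grid[0])
    ratio_hi = np.sqrt(freq_grid[-1] / freq_grid[-2])
    edges = np.concatenate([[freq_grid[0] / ratio], inner, [freq_grid[-1] * ratio_hi]])
    counts, _ = np.histogram(rates, bins=edges)
    total = counts.sum()
    if total == 0:
        return out
    return counts / total
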