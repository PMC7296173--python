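"""Synchrosqueezing: reassigning wavelet power from scales to frequencies.

A scale's coefficient track oscillates at the signal's local frequency, not
necessarily at the scale's nominal frequency.  Synchrosqueezing moves each
squared amplitude to the frequency bin containing the track's instantaneous
frequency (the time-derivative of phase), sharpening the representation.
Applied here as a post-process: amplitudes are reassigned after clipping,
using the clamped monotone phase, which is the only phase the clipped
representation retains.
"""

from __future__ import annotations

import numpy as np

from .morse import AmplitudePhaseTrack, ScaleGrid

__all__ = ["instantaneous_frequency", "synchrosqueeze", "default_bins"]


def instantaneous_frequency(track: AmplitudePhaseTrack, fs: float) -> np.ndarray:
    """Instantaneous frequency in Hz by forward differences of the phase.

    The last element repeats the penultimate value so the output matches the
    track length.  Nonnegative by the track's monotone-phase invariant.
    """
    dphi = np.diff(track.phi)
    f = dphi * fs / (2.0 * np.pi)
    if f.size == 0:
        return np.zeros(1)
    return np.concatenate([f, f[-1:]])


def default_bins(grid: ScaleGrid) -> np.ndarray:
    """Output bin edges covering the analysis grid, half a voice beyond it.

    Edges sit at the geometric midpoints between adjacent grid frequencies,
    extended by half a voice on each side, so each analysis frequency owns
    exactly one bin and squeezed results plot on the same axis.
    """
    f = np.sort(grid.frequencies)
    step = 2.0 ** (0.5 / grid.voices_per_octave)
    inner = np.sqrt(f[:-1] * f[1:])
    return np.concatenate([[f[0] / step], inner, [f[-1] * step]])


def synchrosqueeze(
    amplitudes: np.ndarray, inst_freq: np.ndarray, out_bins: np.ndarray
) -> np.ndarray:
    """Accumulate squared amplitudes into frequency bins, per time column.

    Parameters
    ----------
    amplitudes, inst_freq : ndarray, shape (n_scales, n_times)
        Amplitudes (clipped or not) and their instantaneous frequencies in
        Hz, matching elementwise.
    out_bins : ndarray
        Strictly increasing bin edges in Hz; ``len(out_bins) - 1`` bins.

    Returns
    -------
    ndarray, shape (n_bins, n_times)
        Squared amplitude reassigned by instantaneous frequency.  Power
        whose frequency falls outside the bin range is dropped; everything
        inside is conserved exactly.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    inst_freq = np.asarray(inst_freq, dtype=float)
    out_bins = np.asarray(out_bins, dtype=float)
    if amplitudes.shape != inst_freq.shape:
        raise ValueError("amplitudes and inst_freq must have identical shapes")
    if out_bins.ndim != 1 or out_bins.size < 2 or np.any(np.diff(out_bins) <= 0):
        raise ValueError("out_bins must be strictly increasing with >= 2 edges")
    n_bins = out_bins.size - 1
    n_times = amplitudes.shape[1]
    idx = np.searchsorted(out_bins, inst_freq, side="right") - 1
    inside = (idx >= 0) & (idx < n_bins) & (inst_freq < out_bins[-1])
    # right edge is inclusive, matching a closed frequency range
    inside |= inst_freq == out_bins[-1]
    idx = np.where(inst_freq == out_bins[-1], n_bins - 1, idx)
    out = np.zeros((n_bins, n_times))
    power = amplitudes**2
    cols = np.broadcast_to(np.arange(n_times), amplitudes.shape)
    np.add.at(out, (idx[inside], cols[inside]), power[inside])
    return out
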