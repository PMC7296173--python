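"""Synthetic spike-train signals with controlled regularity and noise.

The generator emulates extracellular recordings of rhythmically firing
cells: instantaneous firing rates (inverse inter-spike intervals) are
log-normal around a median of 8 Hz, each spike rides on a smooth membrane
"bump", spike heights vary randomly, and pink (1/f) background noise is
added at a controlled power ratio.  Regularity is set by ``sigma_log2``
(spread of log2 firing rate: 1 is highly irregular, 1/16 near-metronomic)
and noise by ``snr`` (spike-component power over noise power; 0 means pure
noise).  Also provides three deterministic demonstration signals with known
frequency content (a morphing 1 Hz oscillation, a bursting spike train, and
a thresholded chirp).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import chirp

from .signal_io import Signal

__all__ = [
    "SpikeTrainConfig",
    "SpikeTrain",
    "sample_spike_train",
    "rasterize",
    "synthesize_signal",
    "pink_noise",
    "demo_signal",
    "DEMO_SIGNALS",
]


@dataclass(frozen=True)
class SpikeTrainConfig:
    """Parameters of the spike-train signal generator.

    mu_log2 : mean of log2 instantaneous rate (default log2(8), i.e. a
        median firing rate of 8 Hz).
    sigma_log2 : std of log2 instantaneous rate; the study grid is
        {1, 1/2, 1/4, 1/8, 1/16}.
    snr : power of the noise-free spike component divided by pink-noise
        power; the study grid is {0, 0.1, 0.29, 1, 2.9}; 0 means the spike
        component is replaced by zeros (pure-noise baseline).
    fs, duration : sampling rate (Hz) and record length (s).  Defaults
        100 Hz / 20 s resolve 8 Hz spiking with 12.5 samples per cycle while
        keeping a single record cheap to transform.
    bump_sigma : width (s) of the Gaussian membrane bump under each spike.
    """

    mu_log2: float = 3.0  # log2(8)
    sigma_log2: float = 0.25
    snr: float = 1.0
    fs: float = 100.0
    duration: float = 20.0
    bump_sigma: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.sigma_log2 <= 0:
            raise ValueError("sigma_log2 must be positive")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (s) within [0, duration)."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.size and (
            np.any(np.diff(times) <= 0)
            or times[0] < 0
            or times[-1] >= self.duration
        ):
            raise ValueError("times must be strictly increasing in [0, duration)")
        object.__setattr__(self, "times", times)

    @property
    def inverse_isis(self) -> np.ndarray:
        """Instantaneous firing rates 1/ISI in Hz (empty for < 2 spikes)."""
        return 1.0 / np.diff(self.times)


def _rng_of(config: SpikeTrainConfig, rng: np.random.Generator | None):
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def sample_spike_train(
    config: SpikeTrainConfig, rng: np.random.Generator | None = None
) -> SpikeTrain:
    """Draw a spike train whose inverse ISIs are log2-normal.

    Each inter-spike interval is ``1/v`` with ``log2(v) ~
    Normal(mu_log2, sigma_log2^2)``; spikes accumulate from time 0 until the
    duration is exceeded, the final partial interval being discarded.
    """
    rng = _rng_of(config, rng)
    times = [0.0]
    t = 0.0
    while True:
        v = 2.0 ** rng.normal(config.mu_log2, config.sigma_log2)
        t += 1.0 / v
        if t >= config.duration:
            break
        times.append(t)
    return SpikeTrain(times=np.array(times), duration=config.duration)


def rasterize(train: SpikeTrain, fs: float, duration: float) -> np.ndarray:
    """0/1 raster of length round(fs * duration); colliding spikes stay 1."""
    n = int(round(fs * duration))
    raster = np.zeros(n)
    if train.times.size:
        idx = np.clip(np.round(train.times * fs).astype(int), 0, n - 1)
        raster[idx] = 1.0
    return raster


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance zero-mean noise with power spectral density ~ 1/f.

    Generated by shaping a white Gaussian spectrum with 1/sqrt(f) amplitude
    (DC bin zeroed), which hits the 1/f power target exactly in expectation.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros(freqs.size)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = shape * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    x = np.fft.irfft(spectrum, n)
    x -= x.mean()
    return x / x.std()


def synthesize_signal(
    train: SpikeTrain,
    config: SpikeTrainConfig,
    rng: np.random.Generator | None = None,
    return_parts: bool = False,
):
    """Render a spike train as a noisy membrane-potential-like signal.

    The raster is Gaussian-smoothed (std ``bump_sigma`` seconds) to emulate
    membrane bumps, a single-sample impulse of random height
    ``1/(1 + e^x), x ~ N(0, 1)`` is added at each spike, and pink noise is
    mixed in so the spike-component power divided by noise power equals
    ``snr``.  For ``snr = 0`` the spike component is dropped and unit-power
    pink noise returned (the chance-level baseline).

    With ``return_parts=True`` returns ``(signal, spike_component,
    noise_component)`` so the power ratio of the summed parts can be
    inspected directly.
    """
    rng = _rng_of(config, rng)
    n = int(round(config.fs * config.duration))
    raster = rasterize(train, config.fs, config.duration)
    clean = gaussian_filter1d(raster, sigma=config.bump_sigma * config.fs)
    if train.times.size:
        idx = np.clip(np.round(train.times * config.fs).astype(int), 0, n - 1)
        heights = 1.0 / (1.0 + np.exp(rng.standard_normal(idx.size)))
        np.add.at(clean, idx, heights)
    noise = pink_noise(n, rng)
    if config.snr == 0:
        clean = np.zeros(n)
        scaled = noise
    else:
        scaled = np.sqrt(np.mean(clean**2) / config.snr) * noise
    signal = Signal(samples=clean + scaled, fs=config.fs)
    if return_parts:
        return signal, clean, scaled
    return signal


def _morph_1hz(t: np.ndarray) -> np.ndarray:
    # per-cycle waveform exp(c (cos(2 pi t) - 1)) rescaled to [-1, 1];
    # c ~ 0 is a cosine, large c a narrow periodic pulse
    c = np.geomspace(0.05, 100.0, t.size)
    y = np.exp(c * (np.cos(2.0 * np.pi * t) - 1.0))
    lo = np.exp(-2.0 * c)  # per-sample waveform minimum (at cos = -1)
    return 2.0 * (y - lo) / (1.0 - lo) - 1.0


def _bursting(t: np.ndarray, burst_rate=0.25, spike_rate=8.0, duty=0.4) -> np.ndarray:
    in_burst = (t * burst_rate) % 1.0 < duty
    pulses = np.exp(12.0 * (np.cos(2.0 * np.pi * spike_rate * t) - 1.0))
    return pulses * in_burst


def _chirp_1_10(t: np.ndarray, threshold=0.9) -> np.ndarray:
    T = t[-1] if t.size else 1.0
    x = chirp(t, f0=1.0, f1=10.0, t1=T, method="linear")
    return np.maximum(x - threshold, 0.0)


DEMO_SIGNALS = ("morph_1hz", "bursting", "chirp_1_10")


def demo_signal(name: str, fs: float = 100.0, duration: float = 30.0):
    """Deterministic demonstration signals with known frequency content.

    Returns ``(Signal, metadata)`` where metadata holds the true frequency
    properties.  'morph_1hz': a 1 Hz oscillation whose waveform interpolates
    from a cosine to a narrow periodic pulse over the record. 'bursting':
    0.25 Hz bursts of 8 Hz pulses. 'chirp_1_10': a linear 1->10 Hz chirp
    thresholded so only narrow supra-threshold lobes remain.
    """
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    if name == "morph_1hz":
        x = _morph_1hz(t)
        meta = {"frequency_hz": 1.0}
    elif name == "bursting":
        burst_rate, spike_rate = 0.25, 8.0
        x = _bursting(t, burst_rate, spike_rate)
        meta = {"burst_rate_hz": burst_rate, "spike_rate_hz": spike_rate}
    elif name == "chirp_1_10":
        x = _chirp_1_10(t)
        meta = {
            "f0_hz": 1.0,
            "f1_hz": 10.0,
            "instantaneous_frequency_hz": 1.0 + 9.0 * t / t[-1],
        }
    else:
        raise ValueError(f"unknown demo signal {name!r}; choose from {DEMO_SIGNALS}")
    return Signal(samples=x, fs=fs), meta
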