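# mesaclip

Time-frequency analysis of spiky electrophysiological signals without
harmonic artifacts.

## The problem

Many electrophysiological signals (smooth-muscle EMG, extracellular spike
trains) are not smooth oscillations but sequences of brief spikes separated
by quiescent periods.  A continuous wavelet transform (CWT) of such a signal
does capture the rate at which spikes recur, but it also responds strongly
to the *shape* of each spike, filling the spectrogram with energy at integer
multiples of the spike rate (harmonic artifacts).  The conventional remedy —
detect spikes by threshold crossing and histogram the inverse inter-spike
intervals (ISIs) — depends entirely on an arbitrary threshold: spikes whose
heights randomly dip below it double the apparent intervals and create
*sub*harmonic artifacts instead.

## The method

Write one scale's wavelet coefficients in polar form `w(t) = r(t) e^{iφ(t)}`
with unwrapped, non-decreasing phase φ.  A peak of the amplitude `r` that
spans less than `k` full cycles of φ cannot be evidence of `k` repeated
events — it is a single-event (spike-shape) response.  Mesa clipping removes
exactly those peaks: with `κ = 2πk`,

    r′(i) = max { min r[a..b]  :  a ≤ i ≤ b,  φ[b] − φ[a] ≥ κ },

i.e. the greyscale morphological opening of the amplitude track by a flat
structuring element of width κ in the phase domain.  Narrow peaks are
clipped down to flat-topped "mesas" spanning at least `k` cycles; genuine
oscillations are untouched.  `k = 2` is an excellent default, and the
algorithm runs in O(n) per scale.  Applied over all scales of a CWT, the
spike-shape harmonics disappear while the spike-train frequencies remain.

The wavelet matters: the package uses generalized Morse wavelets
`Ψ_{β,γ}(ω) = 2 (eγ/β)^{β/γ} ω^β e^{−ω^γ}` with γ = 3, and a calibrated
β\* = 1.58174 chosen so that the wavelet's response to a Dirac comb is
practically zero halfway between impulses — the locus of the first harmonic
(`mesaclip.calibrate_beta_star` recomputes this constant).  Synchrosqueezing
(reassignment of power to instantaneous-frequency bins) is available as a
post-process, and a simulation benchmark compares the approach against
threshold-crossing peak detection.

## Worked example

Simulate 20 s of a noisy spike train whose instantaneous rate is log-normal
around 8 Hz (regularity σ = 1/4 in log2 Hz, pink noise at equal power to the
spike component), then estimate its frequency distribution three ways:

```python
import numpy as np
import mesaclip as m

config = m.SpikeTrainConfig(sigma_log2=0.25, snr=1.0, fs=100.0, duration=20.0)
rng = np.random.default_rng(0)
train = m.sample_spike_train(config, rng)
signal = m.synthesize_signal(train, config, rng)
print(f"simulated {train.times.size} spikes, median rate "
      f"{np.median(train.inverse_isis):.2f} Hz")

params = m.MorseParams(beta=m.BETA_STAR, gamma=3.0)
grid = m.build_scale_grid(params, fmin=0.5, fmax=32.0, voices_per_octave=16, fs=100.0)
res = m.mesaclip_transform(signal, params, grid, m.ClipParams(k=2.0))
spectrum = m.global_spectrum(res.amplitudes, grid.frequencies)
s = spectrum.summaries
print(f"clipped-spectrum ArgMax {s['argmax']:.2f} Hz, median {s['median']:.2f} Hz, "
      f"mean {s['mean']:.2f} Hz")

raw = m.cwt(signal, params, grid)
unclipped = m.global_spectrum(np.abs(raw.coefficients), grid.frequencies)
print(f"unclipped ArgMax {unclipped.summaries['argmax']:.2f} Hz")

peaks = m.detect_peaks(signal, 0.7)
hist = m.isi_histogram(peaks, grid.frequencies)
ps = m.spectrum_summaries(hist, grid.frequencies)
print(f"peak method (threshold 0.7) ArgMax {ps['argmax']:.2f} Hz")
```

prints

```
simulated 159 spikes, median rate 8.12 Hz
clipped-spectrum ArgMax 7.66 Hz, median 7.66 Hz, mean 6.55 Hz
unclipped ArgMax 19.03 Hz
peak method (threshold 0.7) ArgMax 0.50 Hz
```

The unclipped wavelet spectrum peaks at 19 Hz — spike-shape harmonics, not a
firing rate.  The high-threshold peak method misses dim spikes, doubling
intervals until its histogram peaks at the 0.5 Hz floor — a subharmonic
artifact.  The clipped spectrum's ArgMax, 7.66 Hz, is within a tenth of an
octave of the true 8 Hz median rate, with no tuning beyond the default
`k = 2`.

## Command line

```sh
mesaclip calibrate-beta --gamma 3            # prints 1.581743
mesaclip simulate --sigma 0.25 --snr 1 --seed 0 --out sim      # CSV + JSON truth
mesaclip transform sim.csv --out sim_tf      # spectrogram + spectrum CSVs
mesaclip benchmark --reps 50 --seed 0 --out bench.csv
```

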