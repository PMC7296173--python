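# Methods

## Model and procedure

### Continuous wavelet transform

Signals are 1-D uniformly sampled real series (`Signal`: samples + sampling
rate).  The CWT is computed in the frequency domain: the signal is
zero-padded to the next power of two at least twice its length (so wavelet
tails do not wrap circularly), FFT'd once, multiplied per scale by the
frequency-domain Morse wavelet `Ψ_{β,γ}(sω)`, and inverse-FFT'd.  The Morse
family

    Ψ_{β,γ}(ω) = 2 (eγ/β)^{β/γ} ω^β e^{−ω^γ},  ω ≥ 0

is exactly analytic (no negative-frequency response), so coefficients are
complex with well-defined amplitude and phase.  γ = 3 throughout: it gives
frequency-symmetric wavelets with near-minimal Heisenberg area.  Scales map
to frequencies by the reciprocal law `f = ω_{β,γ} · fs / (2πs)` with
`ω_{β,γ} = (β/γ)^{1/γ}` the peak radian frequency.

**Scale normalization.**  Coefficients use the amplitude (L1) convention
`W_s = IFFT(X(ω) Ψ(sω))` rather than the unit-energy (L2) convention
`√s Ψ(sω)`.  Two reasons, both load-bearing for the rest of the pipeline:
a unit-amplitude sinusoid yields unit coefficient amplitude at its own scale
regardless of frequency, so spectra at different scales are directly
comparable; and pink (1/f) background noise — the realistic noise floor for
electrophysiology — contributes a *flat* global wavelet spectrum.  Under the
L2 convention pink noise's global spectrum grows as 1/f and a noise floor at
comparable power to the signal drags every spectral summary toward the
lowest analysed frequency; with the L1 convention the benchmark's frequency
estimates stay anchored at the firing rate down to SNR well below 1, which
is the regime the method is for.

**Scale grid.**  Log2-spaced frequencies, default 16 voices per octave,
default range from four cycles per record (`4·fs/n`) up to `fs/4`, endpoints
included.  The grid is a display/estimation resolution choice; results are
insensitive to it beyond quantization.

**Padding and edges.**  A cone-of-influence helper
(`cone_of_influence`) reports, per scale, the e-folding duration of the
wavelet envelope — the extent of edge contamination — but no mask is applied
automatically.

### The calibrated wavelet β\*

A Dirac comb's transform shows responses at the comb rate *and* its
harmonics.  The first-harmonic response, midway between two impulses, can be
nulled by choice of β: since the Fourier transform of a single impulse is 1,
the between-impulse response is the inverse FFT of the scaled wavelet
itself.  `calibrate_beta_star` scales the wavelet to a peak frequency of
2 Hz on N frequency samples `ω = 2π·(0…N−1)` (N = 2¹⁴ by default; the
optimum is insensitive to N, which a test verifies by doubling it), takes
the absolute inverse-FFT value at the midpoint sample N/2, and minimizes it
over β with a coarse log-spaced scan followed by bounded 1-D refinement.
For γ = 3 the minimizer is β\* = 1.58174 and the objective there is many
orders of magnitude below its value at a conventional β = 12.  A minimizer
landing on the search boundary is an error (minimum not bracketed), not a
result.

### Amplitude/phase tracks and monotone phase

Per scale, `amplitude_phase` takes `r = |w|` and the unwrapped phase of `w`.
Analytic-signal phase can momentarily run backwards where amplitude is
small; negative forward differences of phase are clamped to zero and the
phase rebuilt by cumulative summation, guaranteeing a non-decreasing φ.
Samples with exactly zero amplitude have no defined phase; they carry the
previous phase forward (zero instantaneous frequency), which keeps φ
monotone and finite.

### Mesa clipping

With `κ = 2πk`, the clipped amplitude is defined as

    r′[i] = max { min(r[a..b]) : a ≤ i ≤ b, φ[b] − φ[a] ≥ κ },

the discrete greyscale opening of `r` by a flat structuring element of
phase-width κ.  If the whole track spans less than κ, no admissible interval
exists and the entire track is set to its global minimum (the limiting case
of draining ever-wider candidate ranges).  `k` is the method's only
parameter: a peak must span at least `k` cycles to survive.  `k = 2` is the
default — one event cannot span two cycles.

`mesaclip` computes this exactly in O(n).  For each left anchor `a` the
minimal admissible range `(a, b(a))` is found with two pointers (`b(a)`
non-decreasing because φ is), and its amplitude floor maintained on a
monotonic min-stack; a second sweep assigns each sample the highest floor
among the ranges covering it (again a monotonic stack, since coverage is an
index window).  A mirrored right-anchored pass is taken elementwise-max with
the first; index reversal negates φ so the span arithmetic
`φ[b] − φ[a] ≥ κ` stays bit-identical between passes.  Every floor is a
selected element of `r` (no arithmetic), so results are exact and
positive-scaling equivariance holds exactly, not just to rounding.

`mesaclip_bruteforce` evaluates the defining max-min over all O(n²)
intervals and is the verification oracle: the production path is tested for
exact equality against it on thousands of randomized tracks, including
repeated phase values, tied amplitudes and degenerate spans.  Guaranteed
properties (all property-tested): output ≤ input; κ = 0 is the identity;
idempotence; monotone in κ; positive-scaling equivariance; every interior
strict-local-maximum plateau spans at least κ of phase.

A design note on control flow: the clipping semantics are often described
operationally as iterating over amplitude peaks, expanding an index range
per peak, and keeping not-yet-wide-enough ranges on a stack for later
merging and final draining.  This package's kernel keeps the
range-and-stack machinery but anchors ranges at samples rather than peaks:
peak-anchored expansion with range clipping to `min(r[a], r[b])` is exact
only while expansion stays downhill, and we found adversarial tracks
(interior troughs below both range ends after a merge; stuck edge-adjacent
ranges whose correct level is not a function of their own endpoints) where
no local per-peak rule reproduces the interval definition.  The
sample-anchored form is provably identical to the definition and is what
the oracle-equivalence tests pin down.

The full-signal pipelines: `mesaclip_transform` runs the CWT and clips every
scale independently, retaining the (monotone) phases alongside the clipped
amplitudes so downstream phase analysis remains possible;
`mesaclip_transform_signed` transforms the positive and negated negative
parts of a biphasic signal separately and sums their squared amplitudes
(power, consistent with the squared-amplitude spectra used throughout; the
alternative of summing amplitudes was rejected as it has no power
interpretation).

### Synchrosqueezing

Instantaneous frequency is the forward difference of the clamped monotone
phase times `fs/2π` (last value repeated), hence nonnegative.  Squared
amplitudes are reassigned, per time column, to the frequency bin containing
their instantaneous frequency; default bins extend the analysis grid by half
a voice on each side.  Power inside the bin range is conserved exactly;
power outside is dropped.  The squeezed quantity is power (squared
amplitude), matching the global spectra.  Squeezing uses the clamped phase
because that is the only phase the clipped representation retains; no
second-order or iterative variants are provided.

## Synthetic data

`spike_sim` emulates rhythmic extracellular firing:

- **Rates.**  Inverse ISIs are log2-normal: `log2(1/ISI) ~ N(μ, σ²)` with
  μ = log2(8) (median 8 Hz).  σ ∈ {1, 1/2, 1/4, 1/8, 1/16} spans irregular
  to near-metronomic firing.  Spikes accumulate from t = 0; the final
  partial interval is discarded.
- **Waveform.**  The 0/1 raster is Gaussian-smoothed (σ = 0.01 s) to mimic
  membrane-potential bumps, and each spike adds a single-sample impulse of
  height `1/(1+eˣ)`, x ~ N(0,1) — heights in (0, 1), median 0.5 — giving the
  height variability that defeats threshold detectors.
- **Noise.**  Pink noise, generated by spectrally shaping white Gaussian
  noise with 1/√f amplitude (DC zeroed), normalized to unit variance.  SNR
  is the power (variance) ratio of spike component to noise component;
  SNR = 0 replaces the spike component with zeros, giving the pure-noise
  chance-level baseline against which relative errors are defined.
- **Record.**  fs = 100 Hz, 20 s by default: 12.5 samples per cycle at 8 Hz
  and ~160 spikes per record, enough for stable spectra while keeping a
  1250-replicate benchmark under two minutes.

What the generator does *not* emulate: biophysical spike shapes (bumps and
heights are phenomenological), refractoriness or rate serial correlation,
nonstationary rates, electrode drift, or multi-unit superposition.  Passing
benchmarks therefore demonstrate robustness to rate dispersion, height
variability and 1/f noise — not to every artifact of real recordings.

Three deterministic demonstration signals with known frequency content are
included (`demo_signal`): a 1 Hz oscillation morphing from cosine to narrow
pulse (waveform `exp(c(cos 2πt − 1))` rescaled to [−1, 1], c log-spaced from
0.05 to 100), 0.25 Hz bursts of 8 Hz pulses, and a 1→10 Hz linear chirp
thresholded at 0.9 so only narrow lobes remain.

## The comparison method and the benchmark

`detect_peaks` places a threshold at `mean + p·(max − mean)`, p ∈ [0, 1];
each contiguous supra-threshold run is one spike at the run's maximum (first
sample on ties; boundary-touching runs count; a constant signal yields no
spikes).  Inverse ISIs are histogrammed on the shared log-frequency grid
(edges at geometric midpoints) and normalized to sum 1; fewer than two
spikes give an all-zero histogram.

`run_benchmark` crosses σ ∈ {1, 1/2, 1/4, 1/8, 1/16} with
SNR ∈ {0, 0.1, 0.29, 1, 2.9}.  Per replicate it simulates a train and
signal, computes one CWT (shared across k ∈ {2, 4, 8}), the clipped global
spectra, and the peak histograms at p ∈ {0.3, 0.5, 0.7}; ground truth is the
replicate's own empirical inverse-ISI histogram on the same grid.  Summary
errors are `log2(estimate) − log2(truth)` (octaves) for ArgMax/Median/Mean
and plain differences for Variance (already octaves²); frequencies enter all
summaries on the log2 axis because the grid, the smoothing and the rate
distribution are all logarithmic, and octave errors are comparable across
frequencies.  Per cell: RMS over replicates (replicates with undefined
estimates — e.g. a zero histogram — are dropped from that cell's RMS), a
percentile bootstrap CI (1000 resamples of the squared errors), and the RMS
relative to the same estimator/summary at SNR = 0, which is 1 at SNR = 0 by
construction.  Default 50 replicates per cell (a documented scale-down;
`--reps 1000` runs the full study), fully deterministic given a master seed
(per-replicate generators are seeded as `[seed, σ-index, SNR-index, rep]`).

## Numerical choices and degenerate inputs

- Clipping floors are selected array elements, never computed values: exact
  equality against the brute-force oracle is meaningful and tested.
- Argmax ties (spectra, supra-threshold runs) resolve to the first index.
- All-zero spectra/histograms have undefined summaries and return NaN
  sentinels rather than raising.
- Two-column CSV timestamps must be uniform to a relative 1e-6; the error
  names the maximum deviation.  One-column CSV requires an explicit rate.
- Gaussian smoothing over log frequency (`smooth_log_freq`, σ in natural-log
  Hz, default 0.06) renormalizes to preserve mass exactly.
- The β\* search errors out if the minimum touches the bracket boundary.
- Detrending is off by default; mean subtraction and a zero-phase
  Butterworth high-pass (cutoff strictly below Nyquist) are offered as
  conveniences only.

## Known limitations

- The calibrated β\* wavelet is extremely time-localized, so frequency
  resolution is poor (Heisenberg trade-off): global-spectrum peaks are
  broad, and summaries can sit a few grid voices off the true rate even
  noise-free.  No post-hoc refinement of the frequency distribution is
  provided.
- Mesa clipping assumes the events of interest repeat; it deliberately
  discards single-event energy, so it is the wrong tool when precise event
  times (spike sorting, point-process rate inference) are the goal.
- Clipping is amplitude-integrated: a low-amplitude high-power oscillatory
  artifact can drown out high-amplitude sparse spikes, in which case
  threshold detection is preferable.
- Cross-signal phase-difference analysis is enabled by the retained phases
  but not implemented here.
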