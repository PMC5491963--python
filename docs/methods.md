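# Methods note

This note documents the analysis model, its parameters, the synthetic
generator's realism and limits, and the numerical choices made in the
implementation. All quantitative statements here were computed with this
package (test suite and `scripts/acceptance.py`).

## Spectral analysis

Time–frequency power is estimated with complex Morlet wavelets

w(t, f) = A · exp(−t²/2σ_t²) · exp(2iπft),  σ_f = 1/(2πσ_t),  A = (σ_t√π)^(−1/2),

with a constant ratio f/σ_f = 7 so that relative bandwidth is the same
at every frequency. Kernels are truncated at ±4σ_t and renormalized to
unit energy (Σ|w|²·Δt = 1, verified to ±1e−6); the residual DC component
after truncation is below 1e−4 relative. Power is |convolution|², with
samples within the kernel half-length of either edge marked invalid
rather than silently kept. Normalized power divides by the scalar mean
5–10 Hz reference-band power over valid samples.

The band-power time series used for episode detection averages wavelet
power rows on a 4 Hz grid across the band. Rows share a single FFT of
the signal (padded to a fast length covering the longest kernel), which
is algebraically identical to per-row convolution (verified to ~1e−15
relative) and an order of magnitude faster.

## State segmentation

Recordings are split into non-overlapping 10 s bins (at least 3 full
bins required). A bin is labeled *theta* if its mean 2.5–4.5 Hz wavelet
power exceeds its mean 0.5–1.5 Hz power (ratio ≥ 1 on a 0.2 Hz
frequency grid), otherwise *slow*. Labels are invariant to voltage
scaling. On generated sessions with a known schedule the segmentation
recovers ≥ 95% of bin labels (98% typical at 600 s).

## Band-pass filtering and phase

Filters are zero-phase frequency-domain FIRs: the real FFT of the whole
trace is multiplied by a mask that is 1 in the passband and falls as a
raised cosine across the transition bands. Corner frequencies
(stop/pass/pass/stop, Hz): theta 1.5/2.5/4.5/5.5; gamma 28/30/100/102;
slow gamma 28/30/50/52; fast gamma 53/55/100/102. A band whose upper
stop edge reaches the Nyquist frequency is rejected rather than
silently truncated. Measured properties: band-center gain within 1 dB,
stop-edge attenuation > 40 dB, group delay 0 ± 1 sample.

Instantaneous phase is the angle of the Hilbert analytic signal of the
band-filtered trace, reported in degrees in [0, 360) with the convention
that an oscillation peak is 0° and a trough 180°.

## Theta troughs and gamma episodes

Theta troughs are strict local minima of the theta-filtered trace whose
neighboring trough spacing is consistent with a 2.5–4.5 Hz cycle
(period within [1/4.5, 1/2.5] s); minima closer than 200 ms are resolved
in favor of the deeper one.

Gamma episodes are detected on the band-averaged wavelet power series:
samples exceeding mean + 2 SD (computed over all valid samples of the
trace) are candidate regions; within each region, local amplitude
maxima of the band-filtered signal are taken over 160 ms windows;
duplicate maxima are deduplicated; maxima closer than 100 ms are
resolved greedily in favor of the larger amplitude; each surviving
maximum anchors a 400 ms analysis window. Restriction to a state mask
(e.g., theta bins only) is applied after detection so that thresholds
are estimated from the whole trace. On a 600 s noise trace with ~200
injected bursts the detector recovers ≥ 95% of bursts within ±10 ms at
< 5% false positives.

## Coupling and circular statistics

Session-level CFC chains segmentation → theta-state mask → gamma
episode detection → theta phase at episode maxima → mean resultant
vector. The resultant length of raw (unbinned) phases is the coupling
strength; 30°-bin phase histograms are display-only and never feed the
statistic. Results with fewer than 30 episodes are flagged `low_n`.

The Rayleigh test uses Z = nR² with the finite-n series correction
p ≈ exp(−Z)[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
requiring n ≥ 5. Its type-I error at α = 0.05 is calibrated (measured
0.035–0.065 over 2000 null runs of n = 100), and it agrees with an
independent implementation (pingouin) in the regime where both
approximations are accurate; for very small p the two approximations
deviate in relative terms, which is expected and inconsequential at any
practical significance level.

## Spike analysis

Waveform peak-to-trough width (peak to the following trough, in µs)
classifies units: > 230 µs putative pyramidal, < 230 µs putative
interneuron, exactly 230 µs unclassified. Phase locking uses spike
phases sampled from the reference band's phase series (nearest sample),
restricted to the theta-state mask, with a minimum of 50 spikes; the
locking strength is the resultant vector length and significance the
Rayleigh p < 0.05. Recovery tests confirm the estimator matches the von
Mises Bessel ratio I₁(κ)/I₀(κ) within ±0.03 at n = 5000, independent of
firing rate.

## Group statistics

Group comparisons use the two-sided Mann–Whitney U test (exact when the
smaller group has ≤ 8 tie-free observations, asymptotic otherwise),
verified against brute-force enumeration of all assignments for every
tie-free input with total n ≤ 10. Frequency-resolved comparisons
correct across frequencies with Benjamini–Hochberg FDR. Session metrics
can be aggregated to one value per animal before testing to avoid
pseudo-replication. Power/sample-size estimation is Monte-Carlo:
resample the two condition generators at increasing n until the
rejection rate reaches the target power (default 0.9).

## Synthetic generator: design and limits

Design decisions worth recording:

- **Burst phase law.** Burst theta phases follow a uniform/von Mises
  mixture: with probability m (modulation depth) a draw from
  vonMises(preferred phase, κ_burst = 8), else uniform. The population
  vector length is m·I₁(κ)/I₀(κ), linear in m and spanning [0, ~1).
  A multiplicative (cardioid-like) phase law was rejected because its
  resultant length saturates at 0.5 and cannot represent strong
  coupling.
- **Edge-safe eligibility.** A theta cycle is burst-eligible only if
  the whole cycle plus the burst envelope margin lies inside a theta
  epoch, and eligibility is decided *before* the phase is drawn.
  Deciding after the draw (dropping bursts that would cross an epoch
  boundary) measurably biases the m = 0 phase distribution away from
  uniform because epoch boundaries align with theta cycles.
- **Carrier coherence.** Burst centers snap to the nearest peak of a
  global 60 Hz clock and the burst carrier is that clock, so the
  latent gamma phase is consistent across bursts and gamma phase
  locking of spikes is well defined.
- **Spike trains** are Poisson processes thinned by mean-one von Mises
  gains in theta and gamma phase (applied only within theta states), so
  the long-run rate equals the nominal rate and locking strength is
  rate-independent.
- **Seeding.** Cohort session seeds derive from
  `SeedSequence([base_seed, group, animal, session])`; per-animal random
  effects jitter modulation depth (σ = 0.03) and amplitudes (lognormal
  σ = 0.05).

Known limits of realism: stationary sinusoidal theta (no frequency
drift or asymmetric cycles), a single gamma carrier frequency per band,
hard 10 s state boundaries, no electrode drift, artifacts, or
non-Poisson spike history effects (refractoriness, bursting). These
simplifications are deliberate: they keep every generated quantity
analytically predictable so the pipeline can be validated by parameter
recovery rather than by eyeballing.

## Scaled study conditions

The generator's defaults (300 s at 2 kHz, theta occupancy 0.165) mirror
the intended recording conditions. For two-cohort contrast experiments
(`scaled_cohort_params`) a desk-scale preset is used instead: 120 s
sessions at 500 Hz with occupancy 0.5, which yields ~70 gamma episodes
and > 150 theta-state spikes per unit per session while keeping a full
5 animals × 6 sessions × 2 groups replicate under 10 s of CPU. Under
the contrast (m = 0.8, κ = 1.5 vs m = 0.3, κ = 0.5) the session-level
CFC and unit-level locking comparisons are significant (p < 0.05) in
≥ 90% of replicate experiments, and in ≤ 10% of null replicates with
identical parameters.

## Numerical choices

- All phase math is radians internally; degrees [0, 360) at the API.
- FFT lengths are padded to `scipy.fft.next_fast_len`.
- Wavelet edge samples are masked invalid, not zero-filled.
- Exact Mann–Whitney p-values are clipped to ≤ 1.
- LFP bundles store little-endian float32 (binary) or 1e−6 µV-precision
  text (CSV); spike times at 1 ns precision; waveforms at 9 significant
  digits; every file is SHA-256 checksummed in `manifest.json`.
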