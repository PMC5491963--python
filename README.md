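# thetagamma

Analysis pipeline for theta–gamma cross-frequency coupling and spike
phase locking in local field potential (LFP) recordings, with a
ground-truth synthetic session generator for end-to-end validation.

## Scientific problem

Under urethane anesthesia, cortical activity alternates between a
slow-wave state (0.5–1.5 Hz dominated) and a theta state (2.5–4.5 Hz
dominated). During theta states, gamma oscillations (30–100 Hz) occur in
transient episodes whose timing is coupled to the phase of the ongoing
theta rhythm, and single neurons fire preferentially at particular theta
and gamma phases. Changes in the *strength* of this cross-frequency
coupling (CFC) and of spike phase locking are a sensitive readout of
circuit dysfunction, but estimating them correctly requires a chain of
steps — state segmentation, spectral normalization, episode detection,
circular statistics — each with pitfalls that can silently bias the
result.

This package implements that chain as a reproducible pipeline:

1. **Spectral analysis** (`thetagamma.spectral`): complex Morlet wavelet
   transforms with a constant center-frequency/bandwidth ratio of 7 and
   unit-energy kernels; power normalized to a 5–10 Hz reference band.
2. **State segmentation** (`thetagamma.states`): 10 s bins labeled theta
   or slow-wave by the ratio of 2.5–4.5 Hz to 0.5–1.5 Hz wavelet power.
3. **Rhythm events** (`thetagamma.events`): zero-phase frequency-domain
   band-pass filters; theta trough detection with cycle-period and
   200 ms separation rules; gamma episode detection at a mean + 2 SD
   band-power threshold with 160 ms local-maximum windows and a 100 ms
   minimum separation.
4. **Coupling** (`thetagamma.coupling`): theta phase (Hilbert analytic
   signal, peak = 0°) sampled at gamma amplitude maxima; coupling
   strength is the mean resultant vector length of those phases.
5. **Spikes** (`thetagamma.spikes`): waveform-width classification into
   putative pyramidal cells (> 230 µs peak-to-trough) and interneurons
   (< 230 µs); spike–LFP phase locking with the Rayleigh test.
6. **Statistics** (`thetagamma.stats`): Mann–Whitney U comparisons,
   Benjamini–Hochberg FDR across frequencies, per-animal aggregation,
   and Monte-Carlo power / sample-size estimation.
7. **Synthetic data** (`thetagamma.synth`): a session generator with an
   explicit ground-truth record — state schedule, gamma burst times and
   theta phases, per-unit tuning — so every estimator can be validated
   by parameter recovery.
8. **I/O and CLI** (`thetagamma.io`, `thetagamma.cli`): on-disk session
   bundles with checksums, and a `thetagamma` command with
   `simulate` / `analyze` / `compare` subcommands.

## Model of the synthetic generator

A session is a state schedule of whole 10 s bins (geometric dwell times
tuned to a target theta occupancy), carrying a 3.5 Hz theta cosine in
theta bins and a 1.0 Hz slow oscillation otherwise, plus 1/f background
noise and a white noise floor. In theta bins, gamma bursts (60 Hz
carrier, 80 ms Hann envelope) occur with a fixed probability per theta
cycle. Each burst's theta phase is drawn from a mixture law: with
probability *m* (the modulation depth) from a von Mises distribution
concentrated at the preferred phase, otherwise uniformly. The population
resultant vector length of burst phases is therefore
*m*·I₁(κ)/I₀(κ) — continuously tunable from 0 to ≈1. Spike trains are
Poisson processes thinned by mean-one von Mises gains in theta and gamma
phase, with waveform widths drawn from class-specific distributions
separated by a gap around the 230 µs classification threshold.

## Worked example

```python
from thetagamma import session_cfc, analyze_session
from thetagamma.synth import GeneratorParams, generate_session

params = GeneratorParams(duration_s=600.0, fs=500.0, theta_occupancy=0.8,
                         modulation_depth=0.8, seed=42)
session, truth = generate_session(params)

res = session_cfc(session)
print(f"vector length {res.vector_length:.3f} at {res.vector_angle:.1f} deg "
      f"from {res.n_events} gamma episodes")
```

prints

```
vector length 0.720 at 221.0 deg from 467 gamma episodes
```

against a generating preferred phase of 225° and a theoretical
population vector length of 0.8 · I₁(8)/I₀(8) ≈ 0.75. The full per-session
analysis on the same data:

```python
row, units = analyze_session(session, gamma_bands=("gamma",), band_powers=False)
```

yields a gamma episode rate of 1.17 s⁻¹ during theta states, and unit
metrics in which all four pyramidal units recover theta locking vector
lengths of 0.44–0.46 (theoretical I₁(1)/I₀(1) ≈ 0.446) and the
interneuron 0.59 (κ = 1.5 target ≈ 0.596).

The same pipeline from the command line:

```bash
thetagamma simulate --params params.json --seed 5 --out sim/
thetagamma analyze sim/group_a --out out_a/
thetagamma analyze sim/group_b --out out_b/
thetagamma compare out_a out_b --out cmp/
```

## Reproduction

`scripts/acceptance.py` runs the principal computations — a session
under the default study conditions, CFC and locking parameter recovery
under high- and low-coupling conditions, and a two-cohort contrast
experiment (5 animals × 6 sessions per group) plus a matched null
experiment — and writes the headline numbers as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With seed 1 this reports, among others, a session-level CFC contrast
p-value of 8.2e-11 and a unit-level theta-locking contrast p-value of
7.1e-41 between the high-coupling (m = 0.8, κ = 1.5) and low-coupling
(m = 0.3, κ = 0.5) cohorts, while the matched null experiment gives
p = 0.77 and p = 0.68. All randomness derives from `--seed`; the run
takes about 1–2 minutes on one CPU.

See `docs/methods.md` for the full methods note, including numerical
choices and known limitations of the generator.
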