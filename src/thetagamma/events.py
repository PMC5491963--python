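"""Bandpass filtering, theta-cycle selection and gamma-episode detection.

Filtering is acausal (zero phase shift) and performed in the frequency
domain: the FFT of the signal is multiplied by a real, symmetric mask that
is 0 outside the stopband edges, 1 inside the passband, with raised-cosine
transitions in between, and transformed back. Theta troughs are strict
local minima of the theta-filtered signal whose spacing corresponds to a
~3.5 Hz cycle period. Gamma episodes are windows of band power exceeding
2 SD of its time average; each episode is anchored at the amplitude maximum
of the band-filtered signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from .core import (
    AnalysisConfig,
    BandSpec,
    DegenerateInputError,
    InsufficientDataError,
    LfpTrace,
    NyquistError,
    PipelineError,
)
from .spectral import WaveletParams, band_power_timeseries

__all__ = [
    "EventSet",
    "bandpass",
    "detect_theta_troughs",
    "instantaneous_phase",
    "detect_gamma_episodes",
    "episode_rate",
]


@dataclass
class EventSet:
    """Detected event times (theta troughs or gamma amplitude maxima)."""

    kind: str  # {"theta_trough", "gamma_maximum"}
    times: np.ndarray  # seconds, strictly increasing
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    band: Optional[BandSpec] = None
    window_s: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise PipelineError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def _filter_mask(freqs: np.ndarray, spec: BandSpec) -> np.ndarray:
    """Raised-cosine bandpass response evaluated on a frequency grid."""
    h = np.zeros_like(freqs)
    f = np.abs(freqs)
    # rising transition stop_lo -> pass_lo
    rise = (f > spec.stop_lo) & (f < spec.pass_lo)
    h[rise] = 0.5 * (
        1.0 - np.cos(np.pi * (f[rise] - spec.stop_lo) / (spec.pass_lo - spec.stop_lo))
    )
    h[(f >= spec.pass_lo) & (f <= spec.pass_hi)] = 1.0
    fall = (f > spec.pass_hi) & (f < spec.stop_hi)
    h[fall] = 0.5 * (
        1.0 + np.cos(np.pi * (f[fall] - spec.pass_hi) / (spec.stop_hi - spec.pass_hi))
    )
    return h


def bandpass(trace: LfpTrace, spec: BandSpec) -> LfpTrace:
    """Zero-phase FIR bandpass of a trace; returns a new filtered trace."""
    if spec.stop_hi >= trace.fs / 2:
        raise NyquistError(
            f"stopband edge {spec.stop_hi} Hz at or above Nyquist ({trace.fs / 2} Hz)"
        )
    x = trace.samples
    if x.size == 0:
        raise PipelineError("empty trace")
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / trace.fs)
    y = np.fft.irfft(spectrum * _filter_mask(freqs, spec), n=x.size)
    return LfpTrace(
        samples=y,
        fs=trace.fs,
        channel_id=trace.channel_id,
        session_id=trace.session_id,
    )


def detect_theta_troughs(
    filtered_theta: LfpTrace, cfg: AnalysisConfig = AnalysisConfig()
) -> EventSet:
    """Theta troughs: strict local minima of the theta-filtered signal.

    A minimum is retained if its spacing to an adjacent minimum falls in the
    accepted cycle period range (the theta passband inverted, 222–400 ms),
    and retained minima must be separated by at least 200 ms (the deeper of
    a conflicting pair wins). Returns an empty set if nothing qualifies.
    """
    x = filtered_theta.samples
    fs = filtered_theta.fs
    mins = np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])) + 1
    if mins.size == 0:
        return EventSet(kind="theta_trough", times=np.empty(0))

    lo, hi = cfg.theta_period_range_s
    periods = np.diff(mins) / fs
    cycle = (periods >= lo) & (periods <= hi)
    keep = np.zeros(mins.size, dtype=bool)
    keep[:-1] |= cycle
    keep[1:] |= cycle
    cand = mins[keep]
    if cand.size == 0:
        return EventSet(kind="theta_trough", times=np.empty(0))

    # enforce the minimum separation, preferring the deeper trough
    sep = cfg.theta_trough_separation_ms / 1000.0 * fs
    order = np.lexsort((cand, x[cand]))  # depth ascending = deepest first
    accepted: list[int] = []
    for i in order:
        idx = cand[i]
        if all(abs(idx - a) >= sep for a in accepted):
            accepted.append(idx)
    accepted.sort()
    idx = np.asarray(accepted, dtype=int)
    return EventSet(kind="theta_trough", times=idx / fs, amplitudes=x[idx])


def instantaneous_phase(filtered: LfpTrace) -> np.ndarray:
    """Instantaneous phase (degrees, [0, 360)) of a band-limited signal.

    The analytic signal is obtained with the Hilbert transform; by
    convention the oscillation peak is 0 degrees and the trough 180.
    """
    x = filtered.samples
    if x.size == 0 or not np.any(x):
        raise DegenerateInputError("phase undefined for an all-zero signal")
    return np.mod(np.degrees(np.angle(hilbert(x))), 360.0)


def _window_maxima(filt: np.ndarray, supra: np.ndarray, half: int) -> np.ndarray:
    """Argmax of ``filt`` in a +/-``half``-sample window around each supra-
    threshold index; returns unique candidate positions."""
    win = 2 * half + 1
    out: list[np.ndarray] = []
    # process contiguous supra-threshold runs to share window scans
    breaks = np.flatnonzero(np.diff(supra) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [supra.size - 1]])
    n = filt.size
    for s, e in zip(starts, ends):
        a, b = supra[s], supra[e]
        lo = max(a - half, 0)
        hi = min(b + half, n - 1)
        seg = filt[lo : hi + 1]
        if seg.size < win:
            centers = supra[s : e + 1]
            for c in centers:
                w0 = max(c - half, 0)
                w1 = min(c + half, n - 1)
                out.append(np.array([w0 + int(np.argmax(filt[w0 : w1 + 1]))]))
            continue
        sw = sliding_window_view(seg, win)
        centers = supra[s : e + 1]
        pos = np.clip(centers - half, lo, hi + 1 - win) - lo
        out.append(sw[pos].argmax(axis=1) + pos + lo)
    if not out:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate(out))


def detect_gamma_episodes(
    trace: LfpTrace,
    band: BandSpec,
    cfg: AnalysisConfig = AnalysisConfig(),
    restrict_mask: Optional[np.ndarray] = None,
) -> EventSet:
    """Detect transient gamma oscillation episodes in one band.

    Procedure: (1) band-averaged time-varying wavelet power; (2) threshold
    at mean + 2 SD of that series over the whole recording; (3) 160 ms
    windows around supra-threshold samples; (4) amplitude maxima of the
    band-filtered signal within each window; (5) duplicates discarded and a
    100 ms minimum separation enforced (larger amplitude wins); (6) events
    outside ``restrict_mask`` dropped. Each retained event carries a 400 ms
    analysis window. The detector is invariant to overall voltage scaling.
    """
    if trace.duration < 10.0:
        raise InsufficientDataError("need at least 10 s of signal")
    params = WaveletParams(cfg.wavelet_ratio)
    power, valid = band_power_timeseries(
        trace, band.band, cfg.episode_power_freq_step, params
    )
    p = power[valid]
    thr = p.mean() + cfg.episode_sd_threshold * p.std()
    supra = np.flatnonzero((power > thr) & valid)
    if supra.size == 0:
        return EventSet(kind="gamma_maximum", times=np.empty(0), band=band,
                        window_s=cfg.episode_crop_ms / 1000.0)

    filt = bandpass(trace, band).samples
    half = int(round(cfg.episode_window_ms / 1000.0 * trace.fs / 2))
    cand = _window_maxima(filt, supra, half)

    # discard identical maxima values (overlap duplicates), earliest kept
    amps = filt[cand]
    _, first = np.unique(amps, return_index=True)
    cand = np.sort(cand[first])
    amps = filt[cand]

    # minimum separation: greedy by amplitude, larger wins, re-checked
    sep = cfg.episode_separation_ms / 1000.0 * trace.fs
    order = np.lexsort((cand, -amps))
    accepted: list[int] = []
    for i in order:
        idx = cand[i]
        if all(abs(idx - a) >= sep for a in accepted):
            accepted.append(idx)
    accepted.sort()
    idx = np.asarray(accepted, dtype=int)

    if restrict_mask is not None:
        restrict_mask = np.asarray(restrict_mask, dtype=bool)
        if restrict_mask.size != trace.samples.size:
            raise PipelineError("restrict_mask length does not match trace")
        idx = idx[restrict_mask[idx]]

    return EventSet(
        kind="gamma_maximum",
        times=idx / trace.fs,
        amplitudes=filt[idx],
        band=band,
        window_s=cfg.episode_crop_ms / 1000.0,
    )


def episode_rate(events: EventSet, mask_duration_s: float) -> float:
    """Events per second of (masked) recording time."""
    if mask_duration_s <= 0:
        raise PipelineError("mask duration must be positive")
    return len(events) / mask_duration_s
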