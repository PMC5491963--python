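"""Complex Morlet wavelet time–frequency analysis.

The time-resolved power spectrum is obtained by convolving the LFP with a
family of complex Morlet wavelets

    w(t, f) = A * exp(-t^2 / (2 sigma_t^2)) * exp(2 i pi f t)

with sigma_f = 1 / (2 pi sigma_t) and A = (sigma_t sqrt(pi))^(-1/2), so that
each wavelet has unit total energy. The family is characterized by a constant
ratio f / sigma_f (default 7): frequency resolution scales with the analysis
frequency.

Power is |convolution|^2 per (frequency, time) cell. Samples closer than
4 sigma_t to either edge of the trace are flagged invalid per frequency
(zero-padded convolution would otherwise leak edge artifacts); every
statistic in this module averages over valid cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import fftconvolve

from .core import (
    DegenerateInputError,
    EmptySelectionError,
    LfpTrace,
    NyquistError,
    PipelineError,
)

__all__ = [
    "WaveletParams",
    "TfrMatrix",
    "morlet_kernel",
    "wavelet_power",
    "band_power_timeseries",
    "normalize_power",
    "band_power",
    "theta_triggered_tfr",
    "band_freq_grid",
]

#: kernel support half-width in units of sigma_t (captures > 99.99% energy)
KERNEL_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True)
class WaveletParams:
    """Morlet family parameter: the constant ratio f / sigma_f."""

    ratio: float = 7.0

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise PipelineError(f"wavelet ratio must be > 0, got {self.ratio}")

    def sigma_t(self, f: float) -> float:
        """Temporal width (s) of the wavelet at frequency ``f``."""
        sigma_f = f / self.ratio
        return 1.0 / (2.0 * np.pi * sigma_f)


@dataclass
class TfrMatrix:
    """Time–frequency power matrix, indexed ``[frequency, time]``.

    ``valid`` marks cells unaffected by convolution edge effects; statistics
    must ignore invalid cells.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    normalized: bool = False
    reference_band: Optional[tuple[float, float]] = None
    n_triggers: Optional[int] = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise PipelineError("power shape does not match freqs x times")
        if self.valid.shape != self.power.shape:
            raise PipelineError("valid mask shape does not match power")

    def band_rows(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        rows = np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))
        if rows.size == 0:
            raise EmptySelectionError(
                f"band {band} contains no grid frequency in "
                f"[{self.freqs[0]:g}, {self.freqs[-1]:g}] Hz"
            )
        return rows


def band_freq_grid(band: tuple[float, float], step: float) -> np.ndarray:
    """Inclusive frequency grid covering ``band`` at ``step`` Hz spacing."""
    lo, hi = band
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def morlet_kernel(
    f: float, fs: float, params: WaveletParams = WaveletParams()
) -> np.ndarray:
    """Generate the complex Morlet kernel for frequency ``f`` at rate ``fs``.

    The kernel spans +/- 4 sigma_t and is renormalized after truncation so
    that its discrete total energy, sum(|w|^2) / fs, equals 1.
    """
    if f <= 0:
        raise PipelineError(f"analysis frequency must be > 0, got {f}")
    if f >= fs / 2:
        raise NyquistError(f"frequency {f} Hz at or above Nyquist ({fs / 2} Hz)")
    sigma_t = params.sigma_t(f)
    half = int(np.ceil(KERNEL_SUPPORT_SIGMAS * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    amp = (sigma_t * np.sqrt(np.pi)) ** -0.5
    w = amp * np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f * t)
    energy = np.sum(np.abs(w) ** 2) / fs
    return w / np.sqrt(energy)


def _edge_invalid_samples(f: float, fs: float, params: WaveletParams) -> int:
    return int(np.ceil(KERNEL_SUPPORT_SIGMAS * params.sigma_t(f) * fs))


def _power_row(x: np.ndarray, f: float, fs: float, params: WaveletParams) -> np.ndarray:
    kernel = morlet_kernel(f, fs, params)
    conv = fftconvolve(x, kernel, mode="same") / fs
    return np.abs(conv) ** 2


def wavelet_power(
    trace: LfpTrace,
    freqs: Sequence[float],
    params: WaveletParams = WaveletParams(),
) -> TfrMatrix:
    """Time-resolved wavelet power of a trace over a frequency grid."""
    x = trace.samples
    if x.size == 0:
        raise EmptySelectionError("empty trace")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= trace.fs / 2):
        raise NyquistError("analysis grid contains frequencies at or above Nyquist")
    n = x.size
    power = np.empty((freqs.size, n))
    valid = np.ones((freqs.size, n), dtype=bool)
    for i, f in enumerate(freqs):
        power[i] = _power_row(x, f, trace.fs, params)
        edge = min(_edge_invalid_samples(f, trace.fs, params), n)
        valid[i, :edge] = False
        valid[i, n - edge:] = False
    return TfrMatrix(power=power, freqs=freqs, times=trace.times, valid=valid)


def band_power_timeseries(
    trace: LfpTrace,
    band: tuple[float, float],
    freq_step: float,
    params: WaveletParams = WaveletParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged time-varying wavelet power, memory-light.

    Averages power rows across the band's frequency grid one row at a time
    instead of materializing a full TFR. Returns ``(power_series, valid)``
    where ``valid`` marks samples valid at every band frequency (the edge
    exclusion of the lowest frequency dominates).
    """
    x = trace.samples
    if x.size == 0:
        raise EmptySelectionError("empty trace")
    freqs = band_freq_grid(band, freq_step)
    if freqs[-1] >= trace.fs / 2:
        raise NyquistError(f"band {band} reaches Nyquist at fs={trace.fs}")
    fs = trace.fs
    n = x.size
    # share one signal FFT across all rows of the band
    kernels = [morlet_kernel(f, fs, params) for f in freqs]
    lmax = max(k.size for k in kernels)
    nfft = int(next_fast_len(n + lmax - 1))
    xf = np.fft.fft(x, nfft)
    acc = np.zeros(n)
    for k in kernels:
        y = np.fft.ifft(xf * np.fft.fft(k, nfft))
        start = (k.size - 1) // 2  # 'same' alignment
        acc += np.abs(y[start : start + n] / fs) ** 2
    acc /= freqs.size
    edge = min(_edge_invalid_samples(freqs[0], trace.fs, params), x.size)
    valid = np.ones(x.size, dtype=bool)
    valid[:edge] = False
    valid[x.size - edge:] = False
    return acc, valid


def normalize_power(tfr: TfrMatrix, reference_band: tuple[float, float]) -> TfrMatrix:
    """Divide the whole TFR by its scalar mean power in the reference band.

    The reference is the mean over reference-band frequencies and valid time
    points; the result is dimensionless, controlling for per-electrode
    impedance differences.
    """
    if tfr.normalized:
        raise PipelineError("TFR is already normalized")
    rows = tfr.band_rows(reference_band)
    sel = tfr.valid[rows]
    if not sel.any():
        raise EmptySelectionError("no valid samples in reference band")
    ref = float(tfr.power[rows][sel].mean())
    if ref == 0.0:
        raise DegenerateInputError("reference-band mean power is zero")
    return TfrMatrix(
        power=tfr.power / ref,
        freqs=tfr.freqs,
        times=tfr.times,
        valid=tfr.valid,
        normalized=True,
        reference_band=tuple(reference_band),
        n_triggers=tfr.n_triggers,
    )


def band_power(
    tfr: TfrMatrix,
    band: tuple[float, float],
    time_mask: Optional[np.ndarray] = None,
) -> float:
    """Mean power over band frequencies and unmasked valid time points."""
    rows = tfr.band_rows(band)
    sel = tfr.valid[rows]
    if time_mask is not None:
        time_mask = np.asarray(time_mask, dtype=bool)
        if time_mask.shape != tfr.times.shape:
            raise PipelineError("time_mask length does not match TFR times")
        sel = sel & time_mask[None, :]
    if not sel.any():
        raise EmptySelectionError("band/mask selects no valid samples")
    return float(tfr.power[rows][sel].mean())


def theta_triggered_tfr(
    trace: LfpTrace,
    trough_times: Sequence[float],
    window: tuple[float, float] = (-0.2, 0.3),
    band_grid: Optional[Sequence[float]] = None,
    params: WaveletParams = WaveletParams(),
) -> TfrMatrix:
    """Average time–frequency power in windows aligned to theta troughs.

    ``band_grid`` defaults to 2-Hz-wide band centers 3, 5, ..., 139 Hz.
    Triggers whose window (padded by the kernel support of each frequency's
    wavelet) would cross the trace boundary are skipped; ``n_triggers``
    records how many windows entered the average.
    """
    if band_grid is None:
        band_grid = np.arange(3.0, 140.0, 2.0)
    band_grid = np.asarray(band_grid, dtype=float)
    trough_times = np.asarray(trough_times, dtype=float)
    if trough_times.size == 0:
        raise EmptySelectionError("no trigger times supplied")
    fs = trace.fs
    i0 = int(np.floor(window[0] * fs))
    i1 = int(np.ceil(window[1] * fs))
    if i1 <= i0:
        raise PipelineError("window must have positive length")
    centers = np.round(trough_times * fs).astype(int)
    keep = (centers + i0 >= 0) & (centers + i1 < trace.samples.size)
    centers = centers[keep]
    if centers.size == 0:
        raise EmptySelectionError("no trigger window fits inside the trace")

    offsets = np.arange(i0, i1 + 1)
    avg = np.zeros((band_grid.size, offsets.size))
    valid = np.ones_like(avg, dtype=bool)
    n = trace.samples.size
    for i, f in enumerate(band_grid):
        row = _power_row(trace.samples, f, fs, params)
        edge = _edge_invalid_samples(f, fs, params)
        idx = centers[:, None] + offsets[None, :]
        avg[i] = row[idx].mean(axis=0)
        # a cell is valid only if every contributing sample was edge-safe
        bad = (idx < edge) | (idx >= n - edge)
        valid[i] = ~bad.any(axis=0)
    return TfrMatrix(
        power=avg,
        freqs=band_grid,
        times=offsets / fs,
        valid=valid,
        n_triggers=int(centers.size),
    )
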