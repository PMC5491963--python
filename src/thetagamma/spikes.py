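"""Spike waveform classification and spike–LFP phase locking.

Putative pyramidal cells are separated from putative interneurons by the
peak–trough width of the mean spike waveform (broad vs narrow, threshold
230 µs — the empirical width distribution is bimodal with a gap at
210–250 µs). Phase locking of a unit to a reference oscillation is the
mean resultant vector of the oscillation phases at its spike times, with
circular uniformity tested by the Rayleigh test (Z = n R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AnalysisConfig,
    DegenerateInputError,
    InsufficientDataError,
    PipelineError,
    SpikeUnit,
)
from .coupling import resultant_vector

__all__ = [
    "WaveformFeatures",
    "LockingResult",
    "waveform_features",
    "classify_unit",
    "firing_rate",
    "rayleigh_test",
    "spike_phase_locking",
]

PYRAMIDAL = "pyramidal"
INTERNEURON = "interneuron"
UNCLASSIFIED = "unclassified"


@dataclass
class WaveformFeatures:
    """Width features (µs) of a mean spike waveform."""

    half_max_width: float
    peak_trough_width: float
    channel_used: str = ""


@dataclass
class LockingResult:
    """Phase locking of one unit to one reference oscillation."""

    unit_id: str
    reference: str  # {"theta", "gamma", "slow_gamma", "fast_gamma"}
    vector_length: float
    vector_angle: float  # degrees
    n_spikes: int
    rayleigh_p: float

    @property
    def phase_locked(self) -> bool:
        return self.rayleigh_p < 0.05


def _interp_crossing(x: np.ndarray, i: int, j: int, level: float) -> float:
    """Fractional index where x crosses ``level`` between samples i and j."""
    if x[j] == x[i]:
        return float(i)
    return i + (level - x[i]) / (x[j] - x[i]) * (j - i)


def waveform_features(unit: SpikeUnit) -> WaveformFeatures:
    """Half-maximum width and peak–trough width of the mean waveform (µs).

    The main peak is the sample of largest absolute amplitude (the waveform
    is flipped if that extremum is negative, so the peak is always
    positive-going). Half-max crossings are located by linear
    interpolation; the trough is the minimum after the peak.
    """
    if unit.mean_waveform is None or len(unit.mean_waveform) < 8:
        raise DegenerateInputError(f"unit {unit.unit_id!r}: no usable mean waveform")
    w = unit.mean_waveform.astype(float)
    if np.ptp(w) == 0:
        raise DegenerateInputError(f"unit {unit.unit_id!r}: flat waveform")
    if abs(w.min()) > abs(w.max()):
        w = -w
    dt_us = 1e6 / unit.waveform_fs
    peak = int(np.argmax(w))
    half = w[peak] / 2.0

    # walk outwards from the peak to the half-max crossings
    i = peak
    while i > 0 and w[i - 1] >= half:
        i -= 1
    left = _interp_crossing(w, i - 1, i, half) if i > 0 else 0.0
    j = peak
    n = w.size
    while j < n - 1 and w[j + 1] >= half:
        j += 1
    right = _interp_crossing(w, j, j + 1, half) if j < n - 1 else float(n - 1)
    half_max_width = (right - left) * dt_us

    after = w[peak:]
    if after.size < 2:
        raise DegenerateInputError(
            f"unit {unit.unit_id!r}: peak at waveform end, no trough"
        )
    trough = peak + int(np.argmin(after))
    peak_trough_width = (trough - peak) * dt_us
    if peak_trough_width <= 0 or half_max_width <= 0:
        raise DegenerateInputError(f"unit {unit.unit_id!r}: degenerate waveform widths")
    return WaveformFeatures(
        half_max_width=half_max_width,
        peak_trough_width=peak_trough_width,
        channel_used=getattr(unit, "channel_id", ""),
    )


def classify_unit(
    features: WaveformFeatures, threshold_us: float = 230.0
) -> str:
    """Broad/narrow waveform classification by peak–trough width.

    Width above the threshold -> putative pyramidal cell; below ->
    putative interneuron; exactly at the boundary -> unclassified.
    """
    w = features.peak_trough_width
    if w > threshold_us:
        return PYRAMIDAL
    if w < threshold_us:
        return INTERNEURON
    return UNCLASSIFIED


def firing_rate(unit: SpikeUnit, mask: np.ndarray, fs: float) -> float:
    """Mean firing rate (Hz) inside a per-sample state mask."""
    mask = np.asarray(mask, dtype=bool)
    dur = mask.sum() / fs
    if dur <= 0:
        raise PipelineError("mask selects zero duration")
    idx = np.round(unit.spike_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < mask.size)]
    return float(mask[idx].sum() / dur)


def rayleigh_test(phases_deg) -> float:
    """Rayleigh test p-value for circular uniformity.

    Z = n R^2 with R the resultant length; the p-value uses the standard
    finite-n series correction, clipped to (0, 1].
    """
    phases = np.asarray(phases_deg, dtype=float)
    n = phases.size
    if n < 5:
        raise InsufficientDataError(f"Rayleigh test needs n >= 5, got {n}")
    r, _ = resultant_vector(phases)
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def spike_phase_locking(
    unit: SpikeUnit,
    phase_series: np.ndarray,
    fs: float,
    mask: np.ndarray | None = None,
    reference: str = "theta",
    min_spikes: int = 50,
) -> LockingResult:
    """Phase locking of a unit to a per-sample reference phase series.

    Spikes are mapped to their nearest LFP sample; only spikes inside
    ``mask`` (e.g. the theta-state mask) are used. Raises
    ``InsufficientDataError`` if fewer than ``min_spikes`` remain.
    """
    idx = np.round(unit.spike_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < phase_series.size)]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        idx = idx[mask[idx]]
    if idx.size < min_spikes:
        raise InsufficientDataError(
            f"unit {unit.unit_id!r}: {idx.size} spikes in mask, "
            f"need >= {min_spikes} for locking"
        )
    phases = phase_series[idx]
    length, angle = resultant_vector(phases)
    return LockingResult(
        unit_id=unit.unit_id,
        reference=reference,
        vector_length=length,
        vector_angle=angle,
        n_spikes=int(idx.size),
        rayleigh_p=rayleigh_test(phases),
    )
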