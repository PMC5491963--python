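"""Shared data model, units and configuration for the LFP/spike pipeline.

Conventions used throughout the package:

* time in seconds, voltage in microvolts, frequency in Hz;
* oscillation phase is stored internally in radians and reported externally
  in degrees on ``[0, 360)``, with the oscillation *peak* at 0 degrees;
* genotype (or any cohort label) is an opaque group tag — no analysis
  branches on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PipelineError",
    "NyquistError",
    "EmptySelectionError",
    "InsufficientDataError",
    "DegenerateInputError",
    "BandSpec",
    "LfpTrace",
    "SpikeUnit",
    "Session",
    "AnalysisConfig",
    "validate_session",
    "wrap_degrees",
]


class PipelineError(ValueError):
    """Base class for analysis errors raised by this package."""


class NyquistError(PipelineError):
    """An analysis frequency at or above the Nyquist frequency was requested."""


class EmptySelectionError(PipelineError):
    """A selection (mask, band, event set) contains no usable samples."""


class InsufficientDataError(PipelineError):
    """Input is too short / too sparse for the requested analysis."""


class DegenerateInputError(PipelineError):
    """Input is degenerate (all-zero signal, flat waveform, zero reference)."""


def wrap_degrees(deg):
    """Wrap angles (degrees) onto ``[0, 360)``."""
    return np.mod(deg, 360.0)


@dataclass(frozen=True)
class BandSpec:
    """Corner frequencies of a zero-phase FIR bandpass filter.

    ``stop_lo < pass_lo < pass_hi < stop_hi``; the response is 0 outside
    the stopband edges, 1 inside the passband, with raised-cosine
    transitions in between.
    """

    stop_lo: float
    pass_lo: float
    pass_hi: float
    stop_hi: float
    name: str = ""

    def __post_init__(self) -> None:
        edges = (self.stop_lo, self.pass_lo, self.pass_hi, self.stop_hi)
        if not (edges[0] < edges[1] < edges[2] < edges[3]):
            raise PipelineError(
                f"band corner frequencies must be strictly increasing, got {edges}"
            )

    @property
    def band(self) -> tuple[float, float]:
        return (self.pass_lo, self.pass_hi)

    @property
    def center(self) -> float:
        return 0.5 * (self.pass_lo + self.pass_hi)


@dataclass
class LfpTrace:
    """One channel's voltage samples (µV) with its sampling rate."""

    samples: np.ndarray
    fs: float = 2000.0
    channel_id: str = "ch0"
    session_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class SpikeUnit:
    """A sorted single unit: spike times plus its mean extracellular waveform.

    ``mean_waveform`` is sampled at ``waveform_fs`` (default 32 kHz) over a
    1 ms span; ``layer`` and ``cell_class`` are optional labels.
    """

    unit_id: str
    spike_times: np.ndarray
    mean_waveform: Optional[np.ndarray] = None
    waveform_fs: float = 32000.0
    layer: str = "unknown"
    cell_class: str = "unclassified"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.mean_waveform is not None:
            self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class Session:
    """A recording session: one or more LFP channels plus sorted units."""

    lfp: list[LfpTrace]
    units: list[SpikeUnit] = field(default_factory=list)
    animal_id: str = ""
    genotype: str = ""
    session_id: str = ""

    @property
    def fs(self) -> float:
        return self.lfp[0].fs

    @property
    def duration(self) -> float:
        return max(t.duration for t in self.lfp)

    def trace(self, channel_id: Optional[str] = None) -> LfpTrace:
        """Return the named channel (default: the first one)."""
        if channel_id is None:
            return self.lfp[0]
        for t in self.lfp:
            if t.channel_id == channel_id:
                return t
        raise KeyError(f"no channel {channel_id!r} in session {self.session_id!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """All numeric constants of the analysis, in one place.

    Defaults are the anesthetized-recording values used throughout: theta at
    2.5–4.5 Hz, slow waves at 0.5–1.5 Hz, gamma at 30–100 Hz split into slow
    (30–50 Hz) and fast (55–100 Hz) sub-bands, power normalized to the
    5–10 Hz reference band, 10 s state bins, episodes at 2 SD above mean
    band power, and the 230 µs peak–trough width threshold separating
    putative pyramidal cells from interneurons.
    """

    theta_band: tuple[float, float] = (2.5, 4.5)
    slow_band: tuple[float, float] = (0.5, 1.5)
    gamma_band: tuple[float, float] = (30.0, 100.0)
    slow_gamma_band: tuple[float, float] = (30.0, 50.0)
    fast_gamma_band: tuple[float, float] = (55.0, 100.0)
    reference_band: tuple[float, float] = (5.0, 10.0)

    state_bin_s: float = 10.0
    min_state_bins: int = 3

    episode_sd_threshold: float = 2.0
    episode_window_ms: float = 160.0
    episode_separation_ms: float = 100.0
    episode_crop_ms: float = 400.0
    episode_power_freq_step: float = 4.0

    theta_trough_separation_ms: float = 200.0
    # accepted theta-cycle period range: inverse of the theta passband
    theta_period_range_s: tuple[float, float] = (1.0 / 4.5, 1.0 / 2.5)

    phase_hist_bin_deg: float = 30.0
    pyr_int_width_threshold_us: float = 230.0

    wavelet_ratio: float = 7.0
    low_freq_step: float = 0.2
    min_events_cfc: int = 30
    min_spikes_locking: int = 50

    theta_filter: BandSpec = field(
        default_factory=lambda: BandSpec(1.5, 2.5, 4.5, 5.5, "theta")
    )
    gamma_filter: BandSpec = field(
        default_factory=lambda: BandSpec(28.0, 30.0, 100.0, 102.0, "gamma")
    )
    slow_gamma_filter: BandSpec = field(
        default_factory=lambda: BandSpec(28.0, 30.0, 50.0, 52.0, "slow_gamma")
    )
    fast_gamma_filter: BandSpec = field(
        default_factory=lambda: BandSpec(53.0, 55.0, 100.0, 102.0, "fast_gamma")
    )

    def __post_init__(self) -> None:
        for name in (
            "theta_band",
            "slow_band",
            "gamma_band",
            "slow_gamma_band",
            "fast_gamma_band",
            "reference_band",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise PipelineError(f"{name}: need low < high, got ({lo}, {hi})")
        for name in ("state_bin_s", "episode_window_ms", "episode_separation_ms",
                     "episode_crop_ms", "theta_trough_separation_ms"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")

    def gamma_filter_for(self, band_name: str) -> BandSpec:
        """Look up a gamma filter spec by its short name."""
        table = {
            "gamma": self.gamma_filter,
            "slow_gamma": self.slow_gamma_filter,
            "fast_gamma": self.fast_gamma_filter,
        }
        try:
            return table[band_name]
        except KeyError:
            raise KeyError(f"unknown gamma band {band_name!r}") from None

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def validate_session(session: Session) -> list[str]:
    """Check type invariants; return one human-readable issue per violation.

    Returns an empty list iff the session is well formed. Never raises and
    never mutates its input.
    """
    issues: list[str] = []
    if not session.lfp:
        issues.append(f"session {session.session_id!r}: no LFP traces")
        return issues

    fs_set = {t.fs for t in session.lfp}
    if len(fs_set) > 1:
        issues.append(
            f"session {session.session_id!r}: traces have mixed sampling rates {sorted(fs_set)}"
        )

    max_dur = 0.0
    for t in session.lfp:
        if not t.fs > 0:
            issues.append(f"trace {t.channel_id!r}: fs must be > 0, got {t.fs}")
            continue
        if t.samples.ndim != 1:
            issues.append(f"trace {t.channel_id!r}: samples must be 1-D")
        if t.samples.size and not np.all(np.isfinite(t.samples)):
            issues.append(f"trace {t.channel_id!r}: non-finite samples")
        max_dur = max(max_dur, t.duration)

    for u in session.units:
        if u.spike_times.size and np.any(np.diff(u.spike_times) < 0):
            issues.append(f"unit {u.unit_id!r}: spike_times not nondecreasing")
        if u.spike_times.size:
            if u.spike_times[0] < 0 or (max_dur > 0 and u.spike_times[-1] > max_dur):
                issues.append(
                    f"unit {u.unit_id!r}: spike_times outside [0, {max_dur:.3f}] s"
                )
        if u.mean_waveform is not None:
            expected = int(round(u.waveform_fs * 1e-3))
            if len(u.mean_waveform) != expected:
                issues.append(
                    f"unit {u.unit_id!r}: mean_waveform length {len(u.mean_waveform)} "
                    f"!= {expected} (1 ms at {u.waveform_fs:g} Hz)"
                )
    return issues
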