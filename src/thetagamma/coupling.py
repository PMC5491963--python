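"""Theta–gamma cross-frequency coupling.

Coupling is quantified by collecting the theta phase at which each detected
gamma amplitude maximum occurs and computing the mean resultant vector of
those phases. The vector length (0 = gamma maxima uniformly spread over the
theta cycle, 1 = all at one phase) indexes coupling strength; the vector
angle is the preferred theta phase. Phase histograms (30-degree bins) are
produced for display and serialization; the resultant vector itself is
always computed from the raw, unbinned phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    AnalysisConfig,
    BandSpec,
    EmptySelectionError,
    Session,
)
from .events import bandpass, detect_gamma_episodes, instantaneous_phase
from .states import THETA, segment_states, state_mask

__all__ = [
    "PhaseHistogram",
    "CouplingResult",
    "phases_at_events",
    "phase_histogram",
    "resultant_vector",
    "session_cfc",
]


@dataclass
class PhaseHistogram:
    """Normalized phase counts in 30-degree bins over [0, 360)."""

    bin_edges: np.ndarray
    normalized_counts: np.ndarray
    n_events: int


@dataclass
class CouplingResult:
    """Per-session coupling strength for one gamma band."""

    vector_length: float
    vector_angle: float  # degrees, [0, 360)
    n_events: int
    session_id: str = ""
    band_name: str = ""
    low_n: bool = False


def phases_at_events(
    phase_series: np.ndarray,
    event_times: Sequence[float],
    fs: float,
) -> np.ndarray:
    """Phase (degrees) at the nearest LFP sample of each event time.

    Events outside the phase-series support are dropped; the caller can
    compare input and output lengths to see how many.
    """
    event_times = np.asarray(event_times, dtype=float)
    idx = np.round(event_times * fs).astype(int)
    ok = (idx >= 0) & (idx < phase_series.size)
    return phase_series[idx[ok]]


def phase_histogram(phases_deg: Sequence[float], bin_deg: float = 30.0) -> PhaseHistogram:
    """Histogram of phases into ``bin_deg``-wide bins, normalized to sum 1."""
    phases_deg = np.asarray(phases_deg, dtype=float)
    if phases_deg.size == 0:
        raise EmptySelectionError("no phases to histogram")
    edges = np.arange(0.0, 360.0 + bin_deg / 2, bin_deg)
    counts, _ = np.histogram(np.mod(phases_deg, 360.0), bins=edges)
    return PhaseHistogram(
        bin_edges=edges,
        normalized_counts=counts / phases_deg.size,
        n_events=int(phases_deg.size),
    )


def resultant_vector(phases_deg: Sequence[float]) -> tuple[float, float]:
    """Mean resultant vector of a circular sample.

    Returns ``(length, angle_deg)`` where length is in [0, 1] and angle is
    the circular mean on [0, 360). Computed from raw phases.
    """
    phases = np.radians(np.asarray(phases_deg, dtype=float))
    if phases.size == 0:
        raise EmptySelectionError("no phases")
    z = np.exp(1j * phases).mean()
    return float(np.abs(z)), float(np.mod(np.degrees(np.angle(z)), 360.0))


def session_cfc(
    session: Session,
    gamma_band: Optional[BandSpec] = None,
    cfg: AnalysisConfig = AnalysisConfig(),
    channel_id: Optional[str] = None,
) -> CouplingResult:
    """Theta–gamma coupling strength of one session.

    Chains state segmentation -> theta-state mask -> gamma-episode detection
    (restricted to theta states) -> theta phase extraction -> resultant
    vector of the theta phases of gamma maxima. Results with fewer than
    ``cfg.min_events_cfc`` events are flagged ``low_n``.
    """
    if gamma_band is None:
        gamma_band = cfg.gamma_filter
    trace = session.trace(channel_id)
    seg = segment_states(trace, cfg)
    mask = state_mask(seg, THETA, trace.fs, n_samples=trace.samples.size)
    if not mask.any():
        raise EmptySelectionError(
            f"session {session.session_id!r}: no theta-state bins"
        )
    episodes = detect_gamma_episodes(trace, gamma_band, cfg, restrict_mask=mask)
    if len(episodes) == 0:
        raise EmptySelectionError(
            f"session {session.session_id!r}: no gamma episodes in theta state"
        )
    theta_phase = instantaneous_phase(bandpass(trace, cfg.theta_filter))
    phases = phases_at_events(theta_phase, episodes.times, trace.fs)
    length, angle = resultant_vector(phases)
    return CouplingResult(
        vector_length=length,
        vector_angle=angle,
        n_events=int(phases.size),
        session_id=session.session_id,
        band_name=gamma_band.name or "gamma",
        low_n=phases.size < cfg.min_events_cfc,
    )
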