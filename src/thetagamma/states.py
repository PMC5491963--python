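"""Brain-state segmentation of anesthetized LFP recordings.

Under urethane anesthesia the cortex alternates spontaneously between a
"theta state" (2.5–4.5 Hz oscillations) and a "slow-wave state"
(0.5–1.5 Hz). The recording is divided into 10 s bins; each bin is labeled
theta if the ratio of mean theta-band to mean slow-band wavelet power is
>= 1, slow otherwise. All gamma and spike analyses downstream are restricted
to theta-state samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, InsufficientDataError, LfpTrace, PipelineError
from .spectral import WaveletParams, band_power_timeseries

__all__ = ["StateSegmentation", "segment_states", "emergence_rate", "state_mask"]

THETA = "theta"
SLOW = "slow"


@dataclass
class StateSegmentation:
    """Per-bin theta/slow labels with the power ratio that produced them."""

    bin_edges: np.ndarray  # length n_bins + 1, seconds
    labels: np.ndarray  # length n_bins, dtype str
    ratio: np.ndarray  # length n_bins, theta/slow power ratio
    bin_s: float

    @property
    def n_bins(self) -> int:
        return len(self.labels)


def segment_states(
    trace: LfpTrace, cfg: AnalysisConfig = AnalysisConfig()
) -> StateSegmentation:
    """Label each 10 s bin of a trace as theta or slow-wave state.

    Per-bin power is the mean raw wavelet power over the band's frequency
    grid (0.2 Hz spacing) within the bin; the final partial bin is dropped.
    Deterministic; requires at least ``cfg.min_state_bins`` full bins.
    """
    bin_len = int(round(cfg.state_bin_s * trace.fs))
    n_bins = trace.samples.size // bin_len
    if n_bins < cfg.min_state_bins:
        raise InsufficientDataError(
            f"trace of {trace.duration:.1f} s has {n_bins} full "
            f"{cfg.state_bin_s:g} s bins; need >= {cfg.min_state_bins}"
        )
    params = WaveletParams(cfg.wavelet_ratio)
    theta_p, theta_ok = band_power_timeseries(
        trace, cfg.theta_band, cfg.low_freq_step, params
    )
    slow_p, slow_ok = band_power_timeseries(
        trace, cfg.slow_band, cfg.low_freq_step, params
    )

    ratio = np.empty(n_bins)
    for b in range(n_bins):
        sl = slice(b * bin_len, (b + 1) * bin_len)
        # edge-invalid samples excluded where possible; fall back to all
        # samples for bins fully inside an edge region (short traces)
        tsel = theta_ok[sl]
        ssel = slow_ok[sl]
        tp = theta_p[sl][tsel].mean() if tsel.any() else theta_p[sl].mean()
        sp = slow_p[sl][ssel].mean() if ssel.any() else slow_p[sl].mean()
        if sp == 0.0:
            ratio[b] = np.inf
        else:
            ratio[b] = tp / sp
    labels = np.where(ratio >= 1.0, THETA, SLOW)
    edges = cfg.state_bin_s * np.arange(n_bins + 1)
    return StateSegmentation(bin_edges=edges, labels=labels, ratio=ratio,
                             bin_s=cfg.state_bin_s)


def emergence_rate(seg: StateSegmentation, state: str = THETA) -> float:
    """Fraction of bins spent in ``state``, in [0, 1]."""
    if seg.n_bins == 0:
        raise PipelineError("empty segmentation")
    return float(np.mean(seg.labels == state))


def state_mask(seg: StateSegmentation, state: str, fs: float,
               n_samples: int | None = None) -> np.ndarray:
    """Per-sample boolean mask of the samples belonging to ``state`` bins.

    The partial final bin (beyond the last bin edge) is masked out. If
    ``n_samples`` is given the mask is padded/truncated to that length.
    """
    bin_len = int(round(seg.bin_s * fs))
    mask = np.repeat(seg.labels == state, bin_len)
    if n_samples is not None:
        if n_samples < mask.size:
            mask = mask[:n_samples]
        elif n_samples > mask.size:
            mask = np.concatenate([mask, np.zeros(n_samples - mask.size, dtype=bool)])
    return mask
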