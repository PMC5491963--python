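"""End-to-end session analysis: one call from raw session to metric tables.

``analyze_session`` runs the full chain — state segmentation, normalized
band power, gamma-episode detection and theta–gamma coupling per band, and
per-unit classification, firing rate and phase locking — and returns flat
records ready for CSV serialization and group statistics.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisConfig, InsufficientDataError, Session
from .coupling import phases_at_events, resultant_vector
from .events import bandpass, detect_gamma_episodes, instantaneous_phase
from .spectral import WaveletParams, band_power_timeseries
from .spikes import classify_unit, firing_rate, spike_phase_locking, waveform_features
from .states import THETA, emergence_rate, segment_states, state_mask
from .stats import compare_groups, GroupComparison

__all__ = ["analyze_session", "analyze_sessions", "compare_cohorts"]

GAMMA_BANDS = ("gamma", "slow_gamma", "fast_gamma")


def cohort_contrast_pvalues(
    params_a,
    params_b,
    base_seed: int,
    n_animals: int = 5,
    sessions_per_animal: int = 6,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> dict[str, float]:
    """Generate two cohorts and return the key group-contrast p-values.

    Runs the session-level theta–gamma coupling comparison and the
    unit-level (pyramidal) theta/gamma locking comparisons for one
    replicate experiment. Only the broad gamma band is analyzed.
    """
    from .synth import generate_cohort

    ca, cb = generate_cohort(params_a, params_b, n_animals=n_animals,
                             sessions_per_animal=sessions_per_animal,
                             base_seed=base_seed)
    sa, ua = analyze_sessions(ca.sessions, cfg, gamma_bands=("gamma",),
                              band_powers=False)
    sb, ub = analyze_sessions(cb.sessions, cfg, gamma_bands=("gamma",),
                              band_powers=False)
    out: dict[str, float] = {}
    for c in compare_cohorts(sa, sb, ua, ub,
                             session_metrics=("gamma_cfc_vl",),
                             unit_metrics=("theta_vl", "gamma_vl")):
        out[c.metric] = c.p_value
    return out


def _masked_mean(series: np.ndarray, valid: np.ndarray, mask: np.ndarray) -> float:
    sel = valid & mask
    return float(series[sel].mean()) if sel.any() else float("nan")


def analyze_session(
    session: Session,
    cfg: AnalysisConfig = AnalysisConfig(),
    channel_id: Optional[str] = None,
    lock_references: Sequence[str] = ("theta", "gamma"),
    gamma_bands: Sequence[str] = GAMMA_BANDS,
    band_powers: bool = True,
) -> tuple[dict, list[dict]]:
    """Analyze one session; returns (session_metrics, per_unit_metrics).

    Session metrics: theta-state emergence rate, normalized band powers
    (reference 5–10 Hz) during theta states, and per gamma band the episode
    rate plus coupling vector length/angle. Unit metrics: waveform widths,
    class, theta-state firing rate, and phase locking to each requested
    reference band (skipped units are reported with a reason).
    """
    trace = session.trace(channel_id)
    fs = trace.fs
    params = WaveletParams(cfg.wavelet_ratio)

    seg = segment_states(trace, cfg)
    mask = state_mask(seg, THETA, fs, n_samples=trace.samples.size)
    theta_dur = mask.sum() / fs

    row: dict = {
        "session_id": session.session_id,
        "animal_id": session.animal_id,
        "genotype": session.genotype,
        "theta_rate": emergence_rate(seg, THETA),
        "theta_duration_s": theta_dur,
    }

    if theta_dur > 0:
        if band_powers:
            ref_p, ref_ok = band_power_timeseries(trace, cfg.reference_band, 0.5, params)
            ref = _masked_mean(ref_p, ref_ok, mask)
            for name in gamma_bands:
                band = getattr(cfg, f"{name}_band")
                p, ok = band_power_timeseries(trace, band, cfg.episode_power_freq_step, params)
                raw = _masked_mean(p, ok, mask)
                row[f"{name}_norm_power"] = raw / ref if ref and np.isfinite(ref) else float("nan")

        theta_phase = instantaneous_phase(bandpass(trace, cfg.theta_filter))
        for name in gamma_bands:
            spec = cfg.gamma_filter_for(name)
            episodes = detect_gamma_episodes(trace, spec, cfg, restrict_mask=mask)
            row[f"{name}_episode_rate"] = len(episodes) / theta_dur
            if len(episodes):
                phases = phases_at_events(theta_phase, episodes.times, fs)
                vl, ang = resultant_vector(phases)
            else:
                vl, ang = float("nan"), float("nan")
            row[f"{name}_cfc_vl"] = vl
            row[f"{name}_cfc_angle"] = ang
            row[f"{name}_n_episodes"] = len(episodes)
    else:
        theta_phase = None

    phase_by_ref: dict[str, np.ndarray] = {}
    if theta_dur > 0:
        phase_by_ref["theta"] = theta_phase
        for name in gamma_bands:
            if name in lock_references:
                phase_by_ref[name] = instantaneous_phase(
                    bandpass(trace, cfg.gamma_filter_for(name))
                )

    unit_rows: list[dict] = []
    for unit in session.units:
        urow: dict = {
            "session_id": session.session_id,
            "animal_id": session.animal_id,
            "genotype": session.genotype,
            "unit_id": unit.unit_id,
            "layer": unit.layer,
        }
        try:
            feats = waveform_features(unit)
            urow["half_max_width_us"] = feats.half_max_width
            urow["peak_trough_width_us"] = feats.peak_trough_width
            urow["cell_class"] = classify_unit(feats, cfg.pyr_int_width_threshold_us)
        except Exception as exc:  # degenerate waveform: keep the unit, flag it
            urow["cell_class"] = "unclassified"
            urow["classification_issue"] = str(exc)
        if theta_dur > 0:
            urow["theta_firing_rate"] = firing_rate(unit, mask, fs)
        for ref_name in lock_references:
            series = phase_by_ref.get(ref_name)
            if series is None:
                continue
            try:
                lr = spike_phase_locking(
                    unit, series, fs, mask=mask, reference=ref_name,
                    min_spikes=cfg.min_spikes_locking,
                )
                urow[f"{ref_name}_vl"] = lr.vector_length
                urow[f"{ref_name}_angle"] = lr.vector_angle
                urow[f"{ref_name}_rayleigh_p"] = lr.rayleigh_p
                urow[f"{ref_name}_locked"] = lr.phase_locked
                urow[f"{ref_name}_n_spikes"] = lr.n_spikes
            except InsufficientDataError as exc:
                urow[f"{ref_name}_skip_reason"] = str(exc)
        unit_rows.append(urow)

    return row, unit_rows


def analyze_sessions(
    sessions: Sequence[Session],
    cfg: AnalysisConfig = AnalysisConfig(),
    lock_references: Sequence[str] = ("theta", "gamma"),
    gamma_bands: Sequence[str] = GAMMA_BANDS,
    band_powers: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze many sessions into (session table, unit table)."""
    srows, urows = [], []
    for s in sessions:
        row, units = analyze_session(s, cfg, lock_references=lock_references,
                                     gamma_bands=gamma_bands, band_powers=band_powers)
        srows.append(row)
        urows.extend(units)
    return pd.DataFrame(srows), pd.DataFrame(urows)


def compare_cohorts(
    sessions_a: pd.DataFrame,
    sessions_b: pd.DataFrame,
    units_a: pd.DataFrame,
    units_b: pd.DataFrame,
    session_metrics: Sequence[str] = ("theta_rate", "gamma_norm_power",
                                      "gamma_episode_rate", "gamma_cfc_vl"),
    unit_metrics: Sequence[str] = ("theta_vl", "gamma_vl"),
    cell_class: str = "pyramidal",
) -> list[GroupComparison]:
    """Mann–Whitney comparisons of the standard session and unit metrics."""
    out: list[GroupComparison] = []
    for m in session_metrics:
        if m not in sessions_a or m not in sessions_b:
            continue
        a = sessions_a[m].dropna().to_numpy()
        b = sessions_b[m].dropna().to_numpy()
        if a.size and b.size:
            out.append(compare_groups(m, a, b, aggregation_level="session"))
    for m in unit_metrics:
        if m not in units_a or m not in units_b:
            continue
        ua = units_a[units_a.get("cell_class") == cell_class]
        ub = units_b[units_b.get("cell_class") == cell_class]
        a = ua[m].dropna().to_numpy()
        b = ub[m].dropna().to_numpy()
        if a.size and b.size:
            out.append(
                compare_groups(f"{cell_class}_{m}", a, b, aggregation_level="unit")
            )
    return out
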