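"""Synthetic urethane-anesthesia-like sessions with known ground truth.

Every analysis stage in this package is validated by parameter recovery on
surrogate data, since no recorded data ship with it. A generated session
contains:

* a state schedule alternating theta (3.5 Hz) and slow-wave (1 Hz)
  epochs, quantized to the 10 s bins the segmentation uses, with a
  controllable long-run theta occupancy;
* gamma bursts (raised-cosine envelope on a gamma carrier) occurring only
  in theta epochs, whose theta phase is drawn from a uniform/von Mises
  mixture: with probability ``m`` (the modulation depth) the phase comes
  from a concentrated von Mises at the preferred phase, otherwise it is
  uniform. The population resultant length is therefore
  ``m * I1(kappa_burst)/I0(kappa_burst)`` — 0 at m = 0, ~0.94 at m = 1 —
  monotone in m over its whole range (a pure cardioid occurrence law
  would cap it at 0.5, too weak to emulate strong coupling);
* 1/f^alpha background noise plus a white floor;
* spiking units of two waveform classes (broad "pyramidal", narrow
  "interneuron", widths bimodal with a gap at 210–250 µs) firing as
  Poisson processes modulated by von Mises tuning to the latent theta and
  gamma phases (burst carriers share a global gamma clock, so the latent
  gamma phase matches the signal inside bursts).

All randomness flows from ``params.seed``; the same seed reproduces the
session byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import i0

from .core import LfpTrace, PipelineError, Session, SpikeUnit

__all__ = [
    "GammaBurstParams",
    "UnitClassParams",
    "GeneratorParams",
    "GroundTruth",
    "Cohort",
    "generate_session",
    "generate_cohort",
]

WAVEFORM_FS = 32000.0
WAVEFORM_SAMPLES = 32  # 1 ms span


@dataclass(frozen=True)
class GammaBurstParams:
    """One gamma band of transient bursts."""

    center_freq: float = 60.0  # Hz, carrier
    bursts_per_cycle: float = 0.35  # occurrence probability per theta cycle
    burst_duration_ms: float = 80.0
    amplitude: float = 60.0  # µV envelope peak


@dataclass(frozen=True)
class UnitClassParams:
    """One spike class (waveform width population + phase tuning)."""

    n_units: int = 4
    firing_rate: float = 6.5  # Hz, mean during theta state
    kappa_theta: float = 1.0
    kappa_gamma: float = 1.0
    mu_theta_deg: float = 200.0
    mu_gamma_deg: float = 180.0  # gamma trough
    width_mean_us: float = 340.0
    width_sd_us: float = 35.0
    width_range_us: tuple[float, float] = (270.0, 450.0)


@dataclass(frozen=True)
class GeneratorParams:
    """Full configuration of one synthetic session."""

    duration_s: float = 300.0
    fs: float = 2000.0
    state_bin_s: float = 10.0
    theta_occupancy: float = 0.165
    mean_theta_dwell_s: float = 20.0
    theta_freq: float = 3.5
    theta_amp: float = 100.0
    slow_freq: float = 1.0
    slow_amp: float = 200.0
    gamma: GammaBurstParams = field(default_factory=GammaBurstParams)
    modulation_depth: float = 0.5  # m in [0, 1]
    preferred_phase_deg: float = 225.0  # falling phase toward theta trough
    kappa_burst: float = 8.0
    noise_alpha: float = 1.0
    noise_level: float = 30.0  # µV std of 1/f component
    white_floor: float = 8.0  # µV std of white component
    pyramidal: UnitClassParams = field(default_factory=UnitClassParams)
    interneuron: UnitClassParams = field(
        default_factory=lambda: UnitClassParams(
            n_units=1,
            firing_rate=8.3,
            kappa_theta=1.5,
            kappa_gamma=1.5,
            mu_theta_deg=340.0,
            mu_gamma_deg=200.0,
            width_mean_us=160.0,
            width_sd_us=25.0,
            width_range_us=(100.0, 200.0),
        )
    )
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if not 0.0 <= self.modulation_depth <= 1.0:
            bad.append("modulation_depth must be in [0, 1]")
        if not 0.0 < self.theta_occupancy < 1.0:
            bad.append("theta_occupancy must be in (0, 1)")
        if self.kappa_burst < 0:
            bad.append("kappa_burst must be >= 0")
        for name in ("theta_amp", "slow_amp", "noise_level", "white_floor"):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        if self.gamma.amplitude < 0:
            bad.append("gamma.amplitude must be >= 0")
        for cls in (self.pyramidal, self.interneuron):
            if cls.kappa_theta < 0 or cls.kappa_gamma < 0:
                bad.append("unit kappa values must be >= 0")
        if bad:
            raise PipelineError("invalid generator params: " + "; ".join(bad))

    def replace(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the generator actually did — the oracle for recovery tests."""

    state_labels: np.ndarray  # per 10 s bin, {"theta", "slow"}
    burst_times: np.ndarray  # s, burst envelope centers
    burst_phases_deg: np.ndarray  # theta phase at each burst center
    units: list[dict]  # per-unit class, rate, kappas, mus, width_us
    params: GeneratorParams

    @property
    def theta_occupancy(self) -> float:
        return float(np.mean(self.state_labels == "theta"))


@dataclass
class Cohort:
    sessions: list[Session]
    truths: list[GroundTruth]


def _state_schedule(rng: np.random.Generator, n_bins: int,
                    params: GeneratorParams) -> np.ndarray:
    """Alternating dwell schedule quantized to whole state bins.

    Dwell lengths are geometric in bins; mean slow dwell is derived from the
    theta dwell and the target occupancy so that long-run occupancy matches.
    """
    occ = params.theta_occupancy
    mean_theta_bins = max(params.mean_theta_dwell_s / params.state_bin_s, 1.0)
    mean_slow_bins = max(mean_theta_bins * (1.0 - occ) / occ, 1.0)
    labels = np.empty(n_bins, dtype=object)
    state = "theta" if rng.random() < occ else "slow"
    i = 0
    while i < n_bins:
        mean = mean_theta_bins if state == "theta" else mean_slow_bins
        dwell = rng.geometric(1.0 / mean)
        labels[i : i + dwell] = state
        i += dwell
        state = "slow" if state == "theta" else "theta"
    return labels.astype(str)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _sample_burst_phase(rng: np.random.Generator, params: GeneratorParams) -> float:
    """Theta phase (deg) for one burst: von Mises with prob m, else uniform."""
    if rng.random() < params.modulation_depth:
        mu = np.radians(params.preferred_phase_deg)
        return float(np.degrees(rng.vonmises(mu, params.kappa_burst)) % 360.0)
    return float(rng.uniform(0.0, 360.0))


def _make_waveform(width_us: float) -> np.ndarray:
    """Mean spike waveform (µV) with a given peak-to-trough width."""
    t = np.arange(WAVEFORM_SAMPLES) / WAVEFORM_FS * 1e6  # µs
    t_peak = 250.0
    w = 80.0 * np.exp(-((t - t_peak) ** 2) / (2 * 60.0**2))
    w -= 45.0 * np.exp(-((t - t_peak - width_us) ** 2) / (2 * 100.0**2))
    return w


def _von_mises_gain(phase_rad: np.ndarray, mu_rad: float, kappa: float) -> np.ndarray:
    """Mean-one multiplicative von Mises rate modulation."""
    if kappa == 0:
        return np.ones_like(phase_rad)
    return np.exp(kappa * np.cos(phase_rad - mu_rad)) / i0(kappa)


def _generate_unit(
    rng: np.random.Generator,
    unit_id: str,
    cls_name: str,
    cls: UnitClassParams,
    theta_mask: np.ndarray,
    theta_phase_rad: np.ndarray,
    gamma_phase_rad: np.ndarray,
    fs: float,
) -> tuple[SpikeUnit, dict]:
    n = theta_mask.size
    duration = n / fs
    mu_t = np.radians(cls.mu_theta_deg)
    mu_g = np.radians(cls.mu_gamma_deg)
    lam_max = (
        cls.firing_rate
        * (np.exp(cls.kappa_theta) / i0(cls.kappa_theta) if cls.kappa_theta else 1.0)
        * (np.exp(cls.kappa_gamma) / i0(cls.kappa_gamma) if cls.kappa_gamma else 1.0)
    )
    # homogeneous candidates at lam_max, thinned by the phase-tuned rate
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, n_cand))
    idx = np.minimum((t_cand * fs).astype(int), n - 1)
    lam = np.full(t_cand.size, cls.firing_rate)
    in_theta = theta_mask[idx]
    lam[in_theta] *= _von_mises_gain(theta_phase_rad[idx[in_theta]], mu_t, cls.kappa_theta)
    lam[in_theta] *= _von_mises_gain(gamma_phase_rad[idx[in_theta]], mu_g, cls.kappa_gamma)
    keep = rng.uniform(0.0, lam_max, t_cand.size) < lam
    spikes = t_cand[keep]

    width = float(
        np.clip(
            rng.normal(cls.width_mean_us, cls.width_sd_us),
            *cls.width_range_us,
        )
    )
    unit = SpikeUnit(
        unit_id=unit_id,
        spike_times=spikes,
        mean_waveform=_make_waveform(width),
        waveform_fs=WAVEFORM_FS,
    )
    truth = {
        "unit_id": unit_id,
        "cell_class": cls_name,
        "firing_rate": cls.firing_rate,
        "kappa_theta": cls.kappa_theta,
        "kappa_gamma": cls.kappa_gamma,
        "mu_theta_deg": cls.mu_theta_deg,
        "mu_gamma_deg": cls.mu_gamma_deg,
        "width_us": width,
    }
    return unit, truth


def generate_session(
    params: GeneratorParams,
    session_id: str = "synthetic",
    animal_id: str = "A0",
    genotype: str = "synthetic",
) -> tuple[Session, GroundTruth]:
    """Generate one session and the ground-truth record describing it."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    bin_len = int(round(params.state_bin_s * fs))
    n_bins = int(params.duration_s // params.state_bin_s)
    if n_bins < 1:
        raise PipelineError("duration shorter than one state bin")
    n = n_bins * bin_len
    t = np.arange(n) / fs

    labels = _state_schedule(rng, n_bins, params)
    theta_mask = np.repeat(labels == "theta", bin_len)

    theta_phase_rad = 2.0 * np.pi * params.theta_freq * t  # peak at phase 0
    gamma_phase_rad = 2.0 * np.pi * params.gamma.center_freq * t

    lfp = np.where(
        theta_mask,
        params.theta_amp * np.cos(theta_phase_rad),
        params.slow_amp * np.cos(2.0 * np.pi * params.slow_freq * t),
    )

    # gamma bursts in theta epochs, phase-placed per theta cycle
    g = params.gamma
    half_burst = g.burst_duration_ms / 2000.0
    burst_times: list[float] = []
    burst_phases: list[float] = []
    cycle = 1.0 / params.theta_freq
    n_cycles = int(np.floor(n / fs / cycle))
    env_len = int(round(g.burst_duration_ms / 1000.0 * fs))
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(env_len) / (env_len - 1)))
    # a cycle is burst-eligible only if the whole cycle plus the envelope
    # margin sits inside a theta epoch; eligibility is decided *before* the
    # phase is drawn, so burst phases stay exactly uniform at m = 0
    margin = int(np.ceil((half_burst + 0.5 / g.center_freq) * fs))
    for k in range(n_cycles):
        c0 = int(np.floor(k * cycle * fs)) - margin
        c1 = int(np.ceil((k + 1) * cycle * fs)) + margin
        if c0 < 0 or c1 > n or not theta_mask[c0:c1].all():
            continue
        if rng.random() >= g.bursts_per_cycle:
            continue
        phase = _sample_burst_phase(rng, params)
        t_c = (k + phase / 360.0) * cycle
        # snap the center to a peak of the global gamma clock so the latent
        # gamma phase matches the burst carrier
        t_c = np.round(t_c * g.center_freq) / g.center_freq
        i_c = int(round(t_c * fs))
        i0_, i1_ = i_c - env_len // 2, i_c - env_len // 2 + env_len
        seg = slice(i0_, i1_)
        amp = g.amplitude * rng.lognormal(0.0, 0.1)
        lfp[seg] += amp * envelope * np.cos(gamma_phase_rad[seg])
        burst_times.append(i_c / fs)
        burst_phases.append(float(np.degrees(theta_phase_rad[i_c]) % 360.0))

    lfp = lfp + params.noise_level * _pink_noise(rng, n, fs, params.noise_alpha)
    lfp = lfp + params.white_floor * rng.standard_normal(n)

    units: list[SpikeUnit] = []
    unit_truths: list[dict] = []
    counter = 0
    for cls_name, cls in (("pyramidal", params.pyramidal),
                          ("interneuron", params.interneuron)):
        for _ in range(cls.n_units):
            unit, truth = _generate_unit(
                rng, f"{session_id}-u{counter}", cls_name, cls,
                theta_mask, theta_phase_rad % (2 * np.pi),
                gamma_phase_rad % (2 * np.pi), fs,
            )
            units.append(unit)
            unit_truths.append(truth)
            counter += 1

    session = Session(
        lfp=[LfpTrace(samples=lfp, fs=fs, channel_id="ch0", session_id=session_id)],
        units=units,
        animal_id=animal_id,
        genotype=genotype,
        session_id=session_id,
    )
    truth = GroundTruth(
        state_labels=labels,
        burst_times=np.asarray(burst_times),
        burst_phases_deg=np.asarray(burst_phases),
        units=unit_truths,
        params=params,
    )
    return session, truth


def _jitter_params(
    params: GeneratorParams, rng: np.random.Generator
) -> GeneratorParams:
    """Small per-animal random effects on modulation depth and amplitudes."""
    m = float(np.clip(params.modulation_depth + rng.normal(0.0, 0.03), 0.0, 1.0))
    scale = float(rng.lognormal(0.0, 0.05))
    return params.replace(
        modulation_depth=m,
        gamma=replace(params.gamma, amplitude=params.gamma.amplitude * scale),
        theta_amp=params.theta_amp * scale,
    )


def scaled_cohort_params(
    modulation_depth: float,
    kappa: float,
    seed: int = 0,
) -> GeneratorParams:
    """Desk-scale cohort study conditions for group-contrast experiments.

    120 s sessions at fs = 500 Hz with theta occupancy 0.5: long enough for
    ~70 gamma episodes and >150 theta-state spikes per unit per session,
    small enough that full two-cohort replicate experiments run on one CPU.
    ``kappa`` sets both theta and gamma spike tuning of every unit class.
    """
    p = GeneratorParams(
        duration_s=120.0,
        fs=500.0,
        theta_occupancy=0.5,
        modulation_depth=modulation_depth,
        seed=seed,
    )
    return p.replace(
        pyramidal=replace(p.pyramidal, kappa_theta=kappa, kappa_gamma=kappa),
        interneuron=replace(p.interneuron, kappa_theta=kappa, kappa_gamma=kappa),
    )


def generate_cohort(
    params_a: GeneratorParams,
    params_b: GeneratorParams,
    n_animals: int = 5,
    sessions_per_animal: int = 6,
    base_seed: int = 0,
) -> tuple[Cohort, Cohort]:
    """Generate two cohorts with per-animal random effects.

    Seeds are derived from ``base_seed`` with a counter scheme
    (group, animal, session), so cohorts are reproducible and sessions
    mutually independent.
    """
    if n_animals < 1 or sessions_per_animal < 1:
        raise PipelineError("counts must be >= 1")
    cohorts = []
    for gi, (group, params) in enumerate((("A", params_a), ("B", params_b))):
        sessions: list[Session] = []
        truths: list[GroundTruth] = []
        for ai in range(n_animals):
            ss = np.random.SeedSequence([base_seed, gi, ai])
            animal_rng = np.random.default_rng(ss)
            animal_params = _jitter_params(params, animal_rng)
            animal_id = f"{group}{ai}"
            for si in range(sessions_per_animal):
                seed = int(
                    np.random.SeedSequence([base_seed, gi, ai, si]).generate_state(1)[0]
                )
                sp = animal_params.replace(seed=seed)
                sess, truth = generate_session(
                    sp,
                    session_id=f"{animal_id}-s{si}",
                    animal_id=animal_id,
                    genotype=group,
                )
                sessions.append(sess)
                truths.append(truth)
        cohorts.append(Cohort(sessions=sessions, truths=truths))
    return cohorts[0], cohorts[1]
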