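import numpy as np
import pytest
from scipy.special import i0, i1

from thetagamma import rayleigh_test, resultant_vector, waveform_features
from thetagamma.core import PipelineError
from thetagamma.synth import (
    GammaBurstParams,
    GeneratorParams,
    UnitClassParams,
    generate_cohort,
    generate_session,
    scaled_cohort_params,
)

NO_UNITS = dict(pyramidal=UnitClassParams(n_units=0),
                interneuron=UnitClassParams(n_units=0))


def _lfp_params(**kw):
    base = dict(duration_s=120.0, fs=500.0, theta_occupancy=0.5, seed=0)
    base.update(NO_UNITS)
    base.update(kw)
    return GeneratorParams(**base)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        p = GeneratorParams(duration_s=60.0, fs=500.0, theta_occupancy=0.5, seed=42)
        s1, t1 = generate_session(p)
        s2, t2 = generate_session(p)
        np.testing.assert_array_equal(s1.lfp[0].samples, s2.lfp[0].samples)
        np.testing.assert_array_equal(t1.burst_times, t2.burst_times)
        assert len(s1.units) == len(s2.units)
        for u1, u2 in zip(s1.units, s2.units):
            np.testing.assert_array_equal(u1.spike_times, u2.spike_times)
            np.testing.assert_array_equal(u1.mean_waveform, u2.mean_waveform)

    def test_different_seeds_differ(self):
        p = _lfp_params(seed=1)
        s1, _ = generate_session(p)
        s2, _ = generate_session(p.replace(seed=2))
        assert not np.array_equal(s1.lfp[0].samples, s2.lfp[0].samples)

    def test_cohort_reproducible(self):
        pa = scaled_cohort_params(0.8, 1.5).replace(duration_s=30.0, **NO_UNITS)
        pb = scaled_cohort_params(0.3, 0.5).replace(duration_s=30.0, **NO_UNITS)
        a1, b1 = generate_cohort(pa, pb, n_animals=2, sessions_per_animal=2,
                                 base_seed=7)
        a2, _ = generate_cohort(pa, pb, n_animals=2, sessions_per_animal=2,
                                base_seed=7)
        for s1, s2 in zip(a1.sessions, a2.sessions):
            np.testing.assert_array_equal(s1.lfp[0].samples, s2.lfp[0].samples)
        # different base seed gives different data
        a3, _ = generate_cohort(pa, pb, n_animals=2, sessions_per_animal=2,
                                base_seed=8)
        assert not np.array_equal(a1.sessions[0].lfp[0].samples,
                                  a3.sessions[0].lfp[0].samples)


class TestValidation:
    def test_bad_modulation_depth_named(self):
        with pytest.raises(PipelineError, match="modulation_depth"):
            generate_session(_lfp_params(modulation_depth=1.5))

    def test_bad_occupancy_named(self):
        with pytest.raises(PipelineError, match="theta_occupancy"):
            generate_session(_lfp_params(theta_occupancy=1.0))

    def test_multiple_errors_all_reported(self):
        with pytest.raises(PipelineError, match="modulation_depth") as exc:
            _lfp_params(modulation_depth=-0.1, noise_level=-1.0).validate()
        assert "noise_level" in str(exc.value)

    def test_too_short_duration_rejected(self):
        with pytest.raises(PipelineError):
            generate_session(_lfp_params(duration_s=5.0))

    def test_bad_cohort_counts_rejected(self):
        p = _lfp_params()
        with pytest.raises(PipelineError):
            generate_cohort(p, p, n_animals=0)


class TestBurstPhaseLaw:
    def test_zero_modulation_phases_uniform(self):
        p = _lfp_params(duration_s=1200.0, modulation_depth=0.0, seed=5)
        _, truth = generate_session(p)
        assert truth.burst_times.size > 300
        assert rayleigh_test(truth.burst_phases_deg) > 0.01

    def test_mixture_law_vector_length(self):
        # population vector length of the burst-phase law is
        # m * I1(kappa_burst) / I0(kappa_burst)
        m, kappa = 0.8, 8.0
        p = _lfp_params(duration_s=2400.0, modulation_depth=m,
                        kappa_burst=kappa, seed=6)
        _, truth = generate_session(p)
        expected = m * i1(kappa) / i0(kappa)
        vl, angle = resultant_vector(truth.burst_phases_deg)
        assert vl == pytest.approx(expected, abs=0.04)
        diff = (angle - p.preferred_phase_deg + 180) % 360 - 180
        assert abs(diff) <= 10.0

    def test_vector_length_monotone_in_m(self):
        vls = []
        for m in (0.0, 0.4, 0.8):
            _, truth = generate_session(
                _lfp_params(duration_s=600.0, modulation_depth=m, seed=9))
            vls.append(resultant_vector(truth.burst_phases_deg)[0])
        assert vls[0] < vls[1] < vls[2]

    def test_bursts_only_in_theta_epochs(self):
        p = _lfp_params(duration_s=300.0, theta_occupancy=0.4, seed=10)
        _, truth = generate_session(p)
        bin_idx = (truth.burst_times // p.state_bin_s).astype(int)
        assert (truth.state_labels[bin_idx] == "theta").all()


class TestUnits:
    def test_spike_theta_tuning_recovers_bessel_ratio(self):
        kappa = 1.5
        p = GeneratorParams(
            duration_s=600.0, fs=500.0, theta_occupancy=0.8, seed=11,
            gamma=GammaBurstParams(amplitude=0.0),
            pyramidal=UnitClassParams(n_units=3, kappa_theta=kappa,
                                      kappa_gamma=0.0, firing_rate=6.5),
            interneuron=UnitClassParams(n_units=0),
        )
        sess, truth = generate_session(p)
        bin_len = p.state_bin_s
        theta_bins = set(np.flatnonzero(truth.state_labels == "theta"))
        phases = []
        for unit in sess.units:
            for t in unit.spike_times:
                if int(t // bin_len) in theta_bins:
                    phases.append((360.0 * p.theta_freq * t) % 360.0)
        vl, angle = resultant_vector(np.asarray(phases))
        assert vl == pytest.approx(i1(kappa) / i0(kappa), abs=0.04)
        diff = (angle - p.pyramidal.mu_theta_deg + 180) % 360 - 180
        assert abs(diff) <= 10.0

    def test_untuned_spikes_uniform(self):
        p = GeneratorParams(
            duration_s=600.0, fs=500.0, theta_occupancy=0.8, seed=12,
            gamma=GammaBurstParams(amplitude=0.0),
            pyramidal=UnitClassParams(n_units=2, kappa_theta=0.0,
                                      kappa_gamma=0.0),
            interneuron=UnitClassParams(n_units=0),
        )
        sess, _ = generate_session(p)
        phases = (360.0 * p.theta_freq * sess.units[0].spike_times) % 360.0
        assert resultant_vector(phases)[0] < 0.05

    def test_waveform_widths_respect_class_ranges(self):
        p = GeneratorParams(duration_s=60.0, fs=500.0, theta_occupancy=0.5,
                            seed=13)
        sess, truth = generate_session(p)
        assert len(sess.units) == 5  # 4 pyramidal + 1 interneuron defaults
        for unit, ut in zip(sess.units, truth.units):
            feats = waveform_features(unit)
            lo, hi = ((270.0, 450.0) if ut["cell_class"] == "pyramidal"
                      else (100.0, 200.0))
            tol = 2e6 / unit.waveform_fs  # sampling granularity
            assert lo - tol <= feats.peak_trough_width <= hi + tol

    def test_firing_rate_near_target_in_theta(self):
        p = GeneratorParams(
            duration_s=1200.0, fs=500.0, theta_occupancy=0.8, seed=14,
            gamma=GammaBurstParams(amplitude=0.0),
            pyramidal=UnitClassParams(n_units=1, firing_rate=6.5,
                                      kappa_theta=0.0, kappa_gamma=0.0),
            interneuron=UnitClassParams(n_units=0),
        )
        sess, _ = generate_session(p)
        # mean-one tuning gain: long-run rate equals the target everywhere
        rate = sess.units[0].spike_times.size / p.duration_s
        assert rate == pytest.approx(6.5, rel=0.1)


class TestCohortBookkeeping:
    def test_sizes_ids_and_genotypes(self):
        pa = _lfp_params(duration_s=30.0)
        a, b = generate_cohort(pa, pa.replace(modulation_depth=0.3),
                               n_animals=5, sessions_per_animal=6, base_seed=3)
        for cohort, group in ((a, "A"), (b, "B")):
            assert len(cohort.sessions) == 30 and len(cohort.truths) == 30
            animals = {s.animal_id for s in cohort.sessions}
            assert animals == {f"{group}{i}" for i in range(5)}
            assert all(s.genotype == group for s in cohort.sessions)
            ids = [s.session_id for s in cohort.sessions]
            assert len(set(ids)) == 30

    def test_sessions_mutually_distinct(self):
        pa = _lfp_params(duration_s=30.0)
        a, _ = generate_cohort(pa, pa, n_animals=2, sessions_per_animal=3,
                               base_seed=4)
        sigs = {s.lfp[0].samples.tobytes() for s in a.sessions}
        assert len(sigs) == 6
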