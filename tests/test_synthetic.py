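import numpy as np
import pytest
from scipy import stats as sps

from oscphen.aperiodic import fit_knee, fit_linear, subtract
from oscphen.io_preprocess import InvalidConfigError, segment
from oscphen.spectral import multitaper_psd, taper_params
from oscphen.synthetic import (
    AperiodicParams,
    CohortSpec,
    PacParams,
    PeakParams,
    SimulationConfig,
    add_bursty_oscillation,
    gen_aperiodic_series,
    gen_cohort,
    gen_pac_series,
    gen_piezo,
    gen_recording,
)


class TestConfigValidation:
    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(duration=0.0)

    def test_negative_knee_rejected(self):
        with pytest.raises(InvalidConfigError):
            AperiodicParams(knee=-1.0)

    def test_kappa_out_of_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            PacParams(coupling_strength=1.5)

    def test_cohort_counts_validated(self):
        with pytest.raises(InvalidConfigError):
            CohortSpec(n_subjects=0)


class TestGenAperiodicSeries:
    def test_slope_recovery_20_seeds(self):
        slopes = []
        for s in range(20):
            cfg = SimulationConfig(sampling_rate=1000.0, duration=60.0,
                                   aperiodic=AperiodicParams(b=1.0, m=-2.0), seed=s)
            rec = gen_aperiodic_series(cfg)
            _, avg = multitaper_psd(segment(rec, 5.0), taper_params(2.0, 5.0))
            band = avg.band(2.0, 100.0)
            slopes.append(np.polyfit(np.log10(band.freqs), band.log_power, 1)[0])
        assert np.mean(slopes) == pytest.approx(-2.0, abs=0.1)

    def test_flat_spectrum_has_lower_log_variance(self):
        def log_var(m, seed):
            cfg = SimulationConfig(sampling_rate=1000.0, duration=60.0,
                                   aperiodic=AperiodicParams(b=0.0, m=m), seed=seed)
            rec = gen_aperiodic_series(cfg)
            _, avg = multitaper_psd(segment(rec, 5.0), taper_params(2.0, 5.0))
            return np.var(avg.band(2.0, 100.0).log_power)

        assert log_var(0.0, 0) < min(log_var(-2.0, s) for s in range(3))

    def test_knee_value_at_1hz(self):
        vals = []
        for s in range(3):
            cfg = SimulationConfig(sampling_rate=1000.0, duration=60.0,
                                   aperiodic=AperiodicParams(b=1.0, m=-2.0, knee=25.0),
                                   highpass_hz=0.25, seed=s)
            rec = gen_aperiodic_series(cfg)
            _, avg = multitaper_psd(segment(rec, 5.0), taper_params(2.0, 5.0))
            vals.append(avg.log_power[np.argmin(np.abs(avg.freqs - 1.0))])
        assert np.mean(vals) == pytest.approx(1.0 - np.log10(26.0), abs=0.15)

    def test_determinism(self):
        cfg = SimulationConfig(sampling_rate=500.0, duration=10.0, seed=42)
        a = gen_aperiodic_series(cfg)
        b = gen_aperiodic_series(cfg)
        assert np.array_equal(a.samples, b.samples)


class TestAddBurstyOscillation:
    def _background(self, seed=0, duration=100.0):
        cfg = SimulationConfig(sampling_rate=500.0, duration=duration,
                               aperiodic=AperiodicParams(b=-2.0, m=-1.0), seed=seed)
        return cfg, gen_aperiodic_series(cfg)

    def test_zero_rate_identity(self):
        cfg, rec = self._background()
        out, intervals = add_bursty_oscillation(
            rec, PeakParams(center_freq=5.0, burst_rate=0.0), seed=1)
        assert intervals == []
        assert np.array_equal(out.samples, rec.samples)

    def test_burst_count_within_poisson_99_interval(self):
        cfg, rec = self._background()
        _, intervals = add_bursty_oscillation(
            rec, PeakParams(center_freq=5.0, burst_rate=0.5,
                            burst_mean_duration=0.4), seed=7,
            background_log_psd=-3.0)
        lo, hi = sps.poisson.ppf([0.005, 0.995], 50)
        assert lo <= len(intervals) <= hi

    def test_injected_peak_visible_downstream(self):
        cfg = SimulationConfig(sampling_rate=500.0, duration=150.0,
                               aperiodic=AperiodicParams(b=1.0, m=-2.0), seed=5)
        rec = gen_aperiodic_series(cfg)
        rec, _ = add_bursty_oscillation(
            rec, PeakParams(center_freq=5.0, height=0.5, burst_rate=0.5,
                            burst_mean_duration=0.5), seed=6,
            background_log_psd=cfg.aperiodic.log_psd(np.array([5.0]))[0])
        _, avg = multitaper_psd(segment(rec, 5.0), taper_params(2.0, 5.0))
        fit = fit_linear(avg, f_lo=2.0, f_hi=55.0)
        per = subtract(avg, fit)
        window = (per.freqs >= 3.0) & (per.freqs <= 10.0)
        peak_f = per.freqs[window][np.argmax(per.residual[window])]
        assert 4.0 <= peak_f <= 6.0

    def test_band_outside_nyquist_errors(self):
        _, rec = self._background()
        with pytest.raises(InvalidConfigError):
            add_bursty_oscillation(rec, PeakParams(center_freq=260.0), seed=1)

    def test_ground_truth_intervals_recorded(self):
        _, rec = self._background()
        _, intervals = add_bursty_oscillation(
            rec, PeakParams(center_freq=5.0, burst_rate=0.5), seed=2,
            background_log_psd=-3.0)
        assert all(0 <= a < b <= 100.0 for a, b in intervals)


class TestGenPacSeries:
    def test_requires_pac_config(self):
        with pytest.raises(InvalidConfigError):
            gen_pac_series(SimulationConfig())

    def test_phase_freq_constraint(self):
        cfg = SimulationConfig(pac=PacParams(phase_freq=30.0, amp_freq=40.0))
        with pytest.raises(InvalidConfigError):
            gen_pac_series(cfg)

    def test_determinism(self):
        cfg = SimulationConfig(sampling_rate=500.0, duration=10.0,
                               pac=PacParams(), seed=3)
        assert np.array_equal(gen_pac_series(cfg).samples, gen_pac_series(cfg).samples)


class TestGenCohort:
    base = SimulationConfig(sampling_rate=250.0, duration=5.0,
                            aperiodic=AperiodicParams(b=1.0, m=-2.0),
                            peaks=(PeakParams(center_freq=5.0, height=0.5,
                                              burst_rate=None),), seed=0)

    def test_zero_sd_no_effects_shares_parameters(self):
        spec = CohortSpec(n_groups=2, n_subjects=3, n_epochs=2,
                          subject_sd=0.0, seed=1)
        cohort = gen_cohort(spec, self.base)
        params = [
            s["params"] for g in cohort.truth["groups"].values()
            for s in g["subjects"].values()
        ]
        assert all(p == params[0] for p in params)

    def test_same_seed_bit_identical(self):
        spec = CohortSpec(n_groups=2, n_subjects=2, n_epochs=2,
                          subject_sd=0.1, seed=9)
        a = gen_cohort(spec, self.base)
        b = gen_cohort(spec, self.base)
        for g in a.signals:
            for s in a.signals[g]:
                for ra, rb in zip(a.signals[g][s], b.signals[g][s]):
                    assert np.array_equal(ra.samples, rb.samples)

    def test_group_effect_applied(self):
        spec = CohortSpec(n_groups=2, n_subjects=2, n_epochs=1, subject_sd=0.0,
                          group_effects=({"aperiodic.b": 1.0}, {}), seed=2)
        cohort = gen_cohort(spec, self.base)
        b0 = next(iter(cohort.truth["groups"]["group0"]["subjects"].values()))["params"]["b"]
        b1 = next(iter(cohort.truth["groups"]["group1"]["subjects"].values()))["params"]["b"]
        assert b0 == pytest.approx(b1 + 1.0)

    def test_hierarchy_shape(self):
        spec = CohortSpec(n_groups=2, n_subjects=3, n_epochs=4, seed=3)
        cohort = gen_cohort(spec, self.base)
        assert len(cohort.signals) == 2
        for g in cohort.signals.values():
            assert len(g) == 3
            for epochs in g.values():
                assert len(epochs) == 4


class TestGenRecording:
    def test_composite_truth_structure(self):
        cfg = SimulationConfig(
            sampling_rate=500.0, duration=20.0,
            aperiodic=AperiodicParams(b=0.0, m=-2.0),
            peaks=(PeakParams(center_freq=6.0, burst_rate=0.5),),
            pac=PacParams(), seed=4)
        rec, truth = gen_recording(cfg)
        assert truth["aperiodic"]["m"] == -2.0
        assert len(truth["peaks"]) == 1
        assert "pac" in truth
        assert len(rec.samples) == cfg.n_samples

    def test_determinism(self):
        cfg = SimulationConfig(sampling_rate=500.0, duration=10.0,
                               peaks=(PeakParams(center_freq=6.0, burst_rate=0.5),),
                               seed=5)
        a, _ = gen_recording(cfg)
        b, _ = gen_recording(cfg)
        assert np.array_equal(a.samples, b.samples)


class TestGenPiezo:
    def test_zero_rate_no_bouts(self):
        trace, truth = gen_piezo(50.0, 0.0, 1.0, 5.0, seed=1, sampling_rate=500.0)
        assert truth == []
        assert trace.max() < 2.0

    def test_non_negative_trace(self):
        trace, _ = gen_piezo(50.0, 0.5, 0.5, 5.0, seed=2, sampling_rate=500.0)
        assert (trace >= 0).all()

    def test_truth_intervals_within_duration(self):
        _, truth = gen_piezo(50.0, 0.5, 0.5, 5.0, seed=3, sampling_rate=500.0)
        assert truth
        assert all(0 <= a < b <= 50.0 for a, b in truth)


class TestSpectralRecoveryLoop:
    """Round-trip invariant: generator parameters recovered by the fits."""

    def test_linear_loop_10_seeds(self):
        ms, bs = [], []
        for s in range(10):
            cfg = SimulationConfig(sampling_rate=1000.0, duration=150.0,
                                   aperiodic=AperiodicParams(b=1.0, m=-2.0), seed=s)
            rec = gen_aperiodic_series(cfg)
            _, avg = multitaper_psd(segment(rec, 5.0), taper_params(2.0, 5.0))
            fit = fit_linear(avg, f_lo=3.0, f_hi=55.0)
            ms.append(fit.m)
            bs.append(fit.b)
        assert np.mean(ms) == pytest.approx(-2.0, abs=0.15)
        assert np.mean(bs) == pytest.approx(1.0, abs=0.2)

    def test_knee_loop_10_seeds(self):
        log_ks = []
        for s in range(10):
            cfg = SimulationConfig(sampling_rate=1000.0, duration=150.0,
                                   aperiodic=AperiodicParams(b=2.0, m=-2.0, knee=25.0),
                                   seed=s)
            rec = gen_aperiodic_series(cfg)
            _, avg = multitaper_psd(segment(rec, 5.0), taper_params(2.0, 5.0))
            log_ks.append(np.log10(max(fit_knee(avg).knee, 1e-12)))
        assert np.mean(log_ks) == pytest.approx(np.log10(25.0), abs=0.3)
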