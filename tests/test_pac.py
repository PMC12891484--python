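import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscphen.io_preprocess import InvalidConfigError, segment
from oscphen.pac import (
    BandGrid,
    bandpass_analytic,
    comodulogram,
    mismatch_pairing,
    modulation_index,
    noise_comodulogram,
    pairwise_noise_mi,
    phase_amp_distribution,
)
from oscphen.synthetic import (
    AperiodicParams,
    PacParams,
    SimulationConfig,
    analytic_pa,
    gen_aperiodic_series,
    gen_pac_series,
)

FS = 500.0


class TestBandGrid:
    def test_counts(self):
        g = BandGrid.default()
        assert len(g.phase_bands) == 6
        assert len(g.amp_bands) == 26

    def test_widths_and_ranges(self):
        g = BandGrid.default()
        assert all(hi - lo == 2.0 for lo, hi in g.phase_bands)
        assert all(hi - lo == 4.0 for lo, hi in g.amp_bands)
        assert g.phase_bands[0][0] == 2.0 and g.phase_bands[-1][1] == 9.0
        assert g.amp_bands[0][0] == 10.0 and g.amp_bands[-1][0] == 60.0


class TestBandpassAnalytic:
    def _tone(self, freq, seconds=10.0):
        t = np.arange(int(FS * seconds)) / FS
        return np.cos(2 * np.pi * freq * t), t

    def test_in_band_tone_constant_amplitude(self):
        x, _ = self._tone(5.0)
        amp, _ = bandpass_analytic(x, (4.0, 6.0), FS)
        core = amp[len(amp) // 10: -len(amp) // 10]
        assert np.std(core) / np.mean(core) < 0.05

    def test_out_of_band_tone_suppressed(self):
        x_in, _ = self._tone(5.0)
        x_out, _ = self._tone(20.0)
        amp_in, _ = bandpass_analytic(x_in, (4.0, 6.0), FS)
        amp_out, _ = bandpass_analytic(x_out, (4.0, 6.0), FS)
        sl = slice(len(amp_in) // 10, -len(amp_in) // 10)
        assert np.mean(amp_out[sl]) < 0.05 * np.mean(amp_in[sl])

    def test_phase_zero_at_cosine_peaks(self):
        x, t = self._tone(5.0)
        _, phase = bandpass_analytic(x, (4.0, 6.0), FS)
        peaks = np.nonzero((np.diff(np.sign(np.diff(x))) < 0))[0] + 1
        core = peaks[(peaks > len(x) // 10) & (peaks < 9 * len(x) // 10)]
        assert np.all(np.abs(phase[core]) < 0.1)

    def test_short_epoch_errors(self):
        with pytest.raises(InvalidConfigError):
            bandpass_analytic(np.zeros(100), (2.0, 4.0), FS)

    def test_band_outside_nyquist_errors(self):
        with pytest.raises(InvalidConfigError):
            bandpass_analytic(np.zeros(5000), (200.0, 300.0), FS)


class TestPhaseAmpDistribution:
    def test_uniform_limit(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 200000)
        pa = phase_amp_distribution(phase, np.ones(200000))
        assert np.allclose(pa.pa, 1 / 18, atol=0.001)

    def test_delta_limit(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 10000)
        edges = np.linspace(-np.pi, np.pi, 19)
        amp = ((phase > edges[5]) & (phase <= edges[6])).astype(float)
        pa = phase_amp_distribution(phase, amp)
        assert pa.pa[5] == pytest.approx(1.0)

    def test_cosine_modulation_matches_closed_form(self):
        phase = np.linspace(-np.pi + 1e-9, np.pi, 500000)
        amp = 1 + np.cos(phase)
        pa = phase_amp_distribution(phase, amp)
        expected = analytic_pa(1.0)
        # ±2% of the distribution's scale (relative tolerance is meaningless
        # at the near-zero trough bin)
        assert np.allclose(pa.pa, expected, atol=0.02 * expected.max())

    def test_all_zero_amplitude_warns_uniform(self):
        with pytest.warns(UserWarning):
            pa = phase_amp_distribution(np.linspace(-3, 3, 100), np.zeros(100))
        assert np.allclose(pa.pa, 1 / 18)

    def test_sums_to_one(self, rng):
        pa = phase_amp_distribution(
            rng.uniform(-np.pi, np.pi, 1000), rng.exponential(1.0, 1000))
        assert pa.pa.sum() == pytest.approx(1.0, abs=1e-12)


class TestModulationIndex:
    def test_uniform_gives_zero(self):
        assert modulation_index(np.full(18, 1 / 18)) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_gives_one(self):
        pa = np.zeros(18)
        pa[4] = 1.0
        assert modulation_index(pa) == pytest.approx(1.0)

    def test_cosine_pa_frozen_value(self):
        # brute-force evaluation of the MI formula on PA_j ∝ 1 + cos φ_j
        pa = analytic_pa(1.0)
        h = -(pa * np.log(pa)).sum()
        expected = (np.log(18) - h) / np.log(18)
        assert modulation_index(pa) == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(0.1060564667511622, abs=1e-12)

    def test_base_invariance(self, rng):
        p = rng.dirichlet(np.ones(18))
        h10 = -(p * np.log10(p)).sum()
        mi10 = (np.log10(18) - h10) / np.log10(18)
        assert modulation_index(p) == pytest.approx(mi10, abs=1e-12)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds_property(self, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(18))
        assert 0.0 <= modulation_index(p) <= 1.0

    def test_amplitude_rescaling_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.exponential(1.0, 5000)
        a = modulation_index(phase_amp_distribution(phase, amp))
        b = modulation_index(phase_amp_distribution(phase, 7.3 * amp))
        assert a == pytest.approx(b, abs=1e-12)


class TestPacOracle:
    def test_kappa1_within_20pct_of_analytic(self):
        cfg = SimulationConfig(
            sampling_rate=FS, duration=60.0,
            pac=PacParams(phase_freq=5.0, amp_freq=40.0, coupling_strength=1.0,
                          noise_sd=0.0, carrier_bandwidth=0.0,
                          phase_drift=0.0), seed=3)
        rec = gen_pac_series(cfg)
        amp, _ = bandpass_analytic(rec.samples, (25.0, 55.0), FS)
        _, phase = bandpass_analytic(rec.samples, (4.0, 6.0), FS)
        mi = modulation_index(phase_amp_distribution(phase, amp))
        oracle = modulation_index(analytic_pa(1.0))
        assert mi == pytest.approx(oracle, rel=0.20)

    def test_kappa0_near_zero(self):
        cfg = SimulationConfig(
            sampling_rate=FS, duration=60.0,
            pac=PacParams(coupling_strength=0.0, noise_sd=0.0, carrier_bandwidth=0.0,
                          phase_drift=0.0), seed=3)
        rec = gen_pac_series(cfg)
        amp, _ = bandpass_analytic(rec.samples, (25.0, 55.0), FS)
        _, phase = bandpass_analytic(rec.samples, (4.0, 6.0), FS)
        assert modulation_index(phase_amp_distribution(phase, amp)) < 0.01

    def test_monotone_in_kappa(self):
        vals = []
        for kappa in (0.0, 0.5, 1.0):
            cfg = SimulationConfig(
                sampling_rate=FS, duration=60.0,
                pac=PacParams(coupling_strength=kappa, noise_sd=0.0,
                              carrier_bandwidth=0.0, phase_drift=0.0), seed=3)
            rec = gen_pac_series(cfg)
            amp, _ = bandpass_analytic(rec.samples, (25.0, 55.0), FS)
            _, phase = bandpass_analytic(rec.samples, (4.0, 6.0), FS)
            vals.append(modulation_index(phase_amp_distribution(phase, amp)))
        assert vals[0] < vals[1] < vals[2]


class TestComodulogram:
    def _pac_epochs(self, kappa, seed=3, duration=30.0, phase_freq=3.0):
        cfg = SimulationConfig(
            sampling_rate=FS, duration=duration,
            pac=PacParams(phase_freq=phase_freq, amp_freq=40.0,
                          coupling_strength=kappa, slow_amplitude=2.0,
                          fast_amplitude=3.0, noise_sd=1.0,
                          carrier_bandwidth=0.0), seed=seed)
        return segment(gen_pac_series(cfg), 5.0)

    def test_matrix_dimensions(self):
        es = self._pac_epochs(1.0, duration=10.0)
        coms = comodulogram(es)
        assert len(coms) == 2
        assert coms[0].mi.shape == (6, 26)

    def test_argmax_at_coupled_cell(self):
        # 3 Hz phase: AM sidebands stay inside the 4 Hz amplitude bands
        es = self._pac_epochs(1.0)
        mean = np.mean([c.mi for c in comodulogram(es)], axis=0)
        i, j = np.unravel_index(np.argmax(mean), mean.shape)
        g = BandGrid.default()
        assert g.phase_bands[i][0] <= 3.0 <= g.phase_bands[i][1]
        assert g.amp_bands[j][0] <= 40.0 <= g.amp_bands[j][1]

    def test_monotone_in_kappa_at_coupled_cell(self):
        g = BandGrid.default()
        i = next(k for k, b in enumerate(g.phase_bands) if b[0] <= 3.0 <= b[1])
        j = next(k for k, b in enumerate(g.amp_bands) if b[0] <= 40.0 <= b[1])
        vals = []
        for kappa in (0.0, 0.5, 1.0):
            es = self._pac_epochs(kappa)
            vals.append(np.mean([c.mi for c in comodulogram(es)], axis=0)[i, j])
        assert vals[0] <= vals[1] <= vals[2]
        assert vals[2] > vals[0]

    def test_white_noise_all_low(self):
        cfg = SimulationConfig(sampling_rate=FS, duration=150.0,
                               aperiodic=AperiodicParams(b=0.0, m=0.0), seed=9)
        es = segment(gen_aperiodic_series(cfg), 5.0)
        mean = np.mean([c.mi for c in comodulogram(es)], axis=0)
        assert mean.max() < 0.02


class TestNoiseComodulogram:
    def test_pairing_never_identity(self, rng):
        for n in (2, 3, 5, 10):
            pairing = mismatch_pairing(n, rng)
            assert np.all(pairing != np.arange(n))

    def test_single_epoch_errors(self, rng):
        with pytest.raises(InvalidConfigError):
            mismatch_pairing(1, rng)

    def test_noise_mi_destroys_coupling(self):
        cfg = SimulationConfig(
            sampling_rate=FS, duration=30.0,
            pac=PacParams(phase_freq=3.0, amp_freq=40.0, coupling_strength=1.0,
                          slow_amplitude=2.0, fast_amplitude=3.0, noise_sd=1.0,
                          carrier_bandwidth=0.0), seed=3)
        es = segment(gen_pac_series(cfg), 5.0)
        g = BandGrid.default()
        i = next(k for k, b in enumerate(g.phase_bands) if b[0] <= 3.0 <= b[1])
        j = next(k for k, b in enumerate(g.amp_bands) if b[0] <= 40.0 <= b[1])
        true_mi = np.mean([c.mi[i, j] for c in comodulogram(es)])
        noise_mi = np.mean([c.mi[i, j] for c in noise_comodulogram(es, seed=1)])
        assert noise_mi < 0.25 * true_mi

    def test_pairwise_tensor_diagonal_is_true(self):
        cfg = SimulationConfig(
            sampling_rate=FS, duration=15.0,
            pac=PacParams(coupling_strength=1.0, noise_sd=1.0), seed=4)
        es = segment(gen_pac_series(cfg), 5.0)
        tensor = pairwise_noise_mi(es)
        true = comodulogram(es)
        for e in range(3):
            assert np.allclose(tensor[e, e], true[e].mi)
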