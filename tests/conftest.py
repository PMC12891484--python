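import numpy as np
import pytest

from oscphen.io_preprocess import EpochSet, Recording
from oscphen.spectral import PowerSpectrum
from oscphen.synthetic import AperiodicParams, SimulationConfig, gen_aperiodic_series


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_recording():
    """60 s of flat-spectrum noise at 500 Hz."""
    cfg = SimulationConfig(
        sampling_rate=500.0, duration=60.0,
        aperiodic=AperiodicParams(b=-2.0, m=0.0), seed=7,
    )
    return gen_aperiodic_series(cfg)


@pytest.fixture
def pink_recording():
    """150 s of 1/f^2 noise at 1000 Hz (b = 1, m = −2)."""
    cfg = SimulationConfig(
        sampling_rate=1000.0, duration=150.0,
        aperiodic=AperiodicParams(b=1.0, m=-2.0), seed=3,
    )
    return gen_aperiodic_series(cfg)


def line_spectrum(b=3.0, m=-2.0, f_max=100.0, df=0.2):
    """Exact power-law spectrum on a regular grid."""
    freqs = np.arange(df, f_max + df / 2, df)
    return PowerSpectrum(freqs, 10.0 ** (b + m * np.log10(freqs)), bin_width=df)


def lorentzian_spectrum(b=4.0, m=-2.0, knee=25.0, f_max=180.0, df=0.2):
    freqs = np.arange(df, f_max + df / 2, df)
    power = 10.0 ** (b - np.log10(knee + freqs ** (-m)))
    return PowerSpectrum(freqs, power, bin_width=df)


def epochs_of(rec: Recording, seconds: float) -> EpochSet:
    from oscphen.io_preprocess import segment
    return segment(rec, seconds)
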