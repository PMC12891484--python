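"""Synthetic signal and cohort generation with known ground truth.

Every downstream stage gets an oracle: the aperiodic background is built by
frequency-domain amplitude shaping (target log10 PSD
``y(f) = b − log10(k + f^(−m))``) with uniformly random phases; periodic
peaks are injected as time-domain bursts so burst statistics are
ground-truthed too; phase-amplitude coupling follows the analytic
``PA_j ∝ 1 + κ·cos(φ_j)`` model; cohorts add group effects and
subject-level Gaussian perturbations on the log-scale parameters.

All generators are deterministic given (config, seed); ground truth (burst
intervals, bout intervals, per-subject parameters) is emitted next to the
signal so tests never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .io_preprocess import InvalidConfigError, Recording


@dataclass(frozen=True)
class AperiodicParams:
    b: float = 1.0       # intercept, log10 power units
    m: float = -2.0      # slope, m ≤ 0
    knee: float = 0.0    # k ≥ 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.b):
            raise InvalidConfigError("intercept b must be finite")
        if self.knee < 0:
            raise InvalidConfigError("knee must be non-negative")

    def log_psd(self, freqs: np.ndarray) -> np.ndarray:
        """Target log10 PSD at f > 0."""
        return self.b - np.log10(self.knee + np.asarray(freqs, float) ** (-self.m))


@dataclass(frozen=True)
class PeakParams:
    center_freq: float
    bandwidth: float = 2.0
    height: float = 0.5          # log10 power units above the background
    burst_rate: float | None = None      # per second; None → always on
    burst_mean_duration: float = 0.4     # seconds


@dataclass(frozen=True)
class PacParams:
    phase_freq: float = 5.0
    amp_freq: float = 40.0
    coupling_strength: float = 1.0  # κ ∈ [0, 1]
    slow_amplitude: float = 10.0
    fast_amplitude: float = 3.0
    noise_sd: float = 1.0
    carrier_bandwidth: float = 20.0  # Hz; 0 → pure tone at amp_freq
    phase_drift: float = 1.5  # rad/√s Brownian drift of the slow phase

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise InvalidConfigError("coupling strength must lie in [0, 1]")


@dataclass(frozen=True)
class LineNoiseParams:
    freq: float = 60.0
    height: float = 1.0  # log10 power boost at the line bin


@dataclass(frozen=True)
class SimulationConfig:
    sampling_rate: float = 1000.0
    duration: float = 100.0
    aperiodic: AperiodicParams = field(default_factory=AperiodicParams)
    peaks: tuple[PeakParams, ...] = ()
    pac: PacParams | None = None
    line_noise: LineNoiseParams | None = None
    highpass_hz: float = 0.5  # acquisition-style rolloff; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise InvalidConfigError("duration and sampling rate must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-6 or round(n) < 2:
            raise InvalidConfigError("duration × sampling_rate must be an integer ≥ 2")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sampling_rate)


@dataclass(frozen=True)
class CohortSpec:
    n_groups: int = 2
    n_subjects: int = 6
    n_epochs: int = 10
    subject_sd: float = 0.0
    group_effects: tuple[dict, ...] = ()  # per-group {param path: additive offset}
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.n_subjects, self.n_epochs) < 1:
            raise InvalidConfigError("all cohort counts must be ≥ 1")
        if self.subject_sd < 0:
            raise InvalidConfigError("subject_sd must be non-negative")


# ---------------------------------------------------------------------------
# Aperiodic background
# ---------------------------------------------------------------------------

def gen_aperiodic_series(config: SimulationConfig, seed: int | None = None) -> Recording:
    """Colored noise whose expected log10 PSD matches the target Lorentzian.

    Deterministic one-sided spectral amplitudes with uniformly random
    phases, inverse-transformed to the time domain.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    fs = config.sampling_rate
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    target = np.zeros_like(freqs)
    target[1:] = 10.0 ** config.aperiodic.log_psd(freqs[1:])
    if config.highpass_hz > 0:
        # steep acquisition-style high-pass keeps the (otherwise divergent)
        # sub-band power from leaking through the last tapers downstream
        target[1:] /= 1.0 + (config.highpass_hz / freqs[1:]) ** 8
    if config.line_noise is not None:
        i = int(np.argmin(np.abs(freqs - config.line_noise.freq)))
        target[i] *= 10.0 ** config.line_noise.height

    # |X_k|² = S(f_k)·n·fs/2 makes the one-sided periodogram equal S exactly
    amps = np.sqrt(target * n * fs / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    spec = amps * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amps[-1]  # Nyquist bin must be real
    samples = np.fft.irfft(spec, n=n)
    return Recording(samples, fs, channel_label="synthetic")


# ---------------------------------------------------------------------------
# Bursty oscillatory peaks
# ---------------------------------------------------------------------------

def _poisson_intervals(
    rng: np.random.Generator, duration: float, rate: float, mean_dur: float
) -> list[tuple[float, float]]:
    """Poisson-process event onsets with exponential durations, clipped."""
    out = []
    t = float(rng.exponential(1.0 / rate))
    while t < duration:
        d = float(rng.exponential(mean_dur))
        out.append((t, min(t + d, duration)))
        t += d + float(rng.exponential(1.0 / rate))
    return out


def add_bursty_oscillation(
    rec: Recording,
    peak: PeakParams,
    seed: int,
    background_log_psd: float | None = None,
    analysis_bandwidth: float = 2.0,
) -> tuple[Recording, list[tuple[float, float]]]:
    """Add a band-limited sinusoidal carrier gated by Poisson bursts.

    The carrier amplitude is calibrated so the measured log10 PSD at the
    peak center sits ``peak.height`` above the background:
    ``A² = 2·S_bg·(10^h − 1)·B_eff / ⟨env²⟩`` where B_eff is the effective
    spectral width (the larger of the peak bandwidth and the analysis
    resolution) and ⟨env²⟩ the realized envelope duty.  Ground-truth burst
    intervals (seconds) are returned alongside the new recording.

    ``background_log_psd``: log10 PSD of the background at the peak center;
    estimated from the recording when not given.
    """
    fs = rec.sampling_rate
    nyq = fs / 2.0
    if not 0 < peak.center_freq - peak.bandwidth / 2 < peak.center_freq + peak.bandwidth / 2 < nyq:
        raise InvalidConfigError("peak band must lie inside (0, Nyquist)")

    rng = np.random.default_rng(seed)
    n = len(rec.samples)
    duration = n / fs
    t = np.arange(n) / fs

    if peak.burst_rate is None:
        intervals = [(0.0, duration)]
    elif peak.burst_rate == 0:
        return rec.copy_with(samples=rec.samples.copy()), []
    else:
        intervals = _poisson_intervals(
            rng, duration, peak.burst_rate, peak.burst_mean_duration
        )
        if not intervals:
            return rec.copy_with(samples=rec.samples.copy()), []

    envelope = np.zeros(n)
    carrier = np.zeros(n)
    for (t0, t1) in intervals:
        i0, i1 = int(t0 * fs), int(t1 * fs)
        if i1 <= i0:
            continue
        seg = slice(i0, i1)
        ramp = min(int(0.05 * fs), (i1 - i0) // 4)
        env = np.ones(i1 - i0)
        if ramp > 0:
            up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[:ramp] = up
            env[-ramp:] = up[::-1]
        envelope[seg] = np.maximum(envelope[seg], env)
        phase0 = rng.uniform(0, 2 * np.pi)
        carrier[seg] = np.cos(2 * np.pi * peak.center_freq * t[seg] + phase0)

    duty = float((envelope ** 2).mean())
    if duty == 0:
        return rec.copy_with(samples=rec.samples.copy()), []

    if background_log_psd is None:
        background_log_psd = _estimate_background(rec, peak.center_freq)
    s_bg = 10.0 ** background_log_psd
    b_eff = max(peak.bandwidth, analysis_bandwidth)
    amp = np.sqrt(2.0 * s_bg * (10.0 ** peak.height - 1.0) * b_eff / duty)

    new = rec.samples + amp * envelope * carrier
    return rec.copy_with(samples=new), intervals


def _estimate_background(rec: Recording, freq: float, half_width: float = 2.0) -> float:
    """Median log10 periodogram power in a band around ``freq``."""
    n = len(rec.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.sampling_rate)
    psd = 2.0 * np.abs(np.fft.rfft(rec.samples)) ** 2 / (rec.sampling_rate * n)
    m = (freqs >= freq - half_width) & (freqs <= freq + half_width)
    return float(np.median(np.log10(np.maximum(psd[m], 1e-300))))


# ---------------------------------------------------------------------------
# Phase-amplitude coupling
# ---------------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n: int, fs: float,
                center: float, bandwidth: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a Gaussian spectral profile
    (σ = bandwidth/4) centered on ``center``, truncated at ± bandwidth."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = bandwidth / 4.0
    profile = np.exp(-((freqs - center) ** 2) / (2 * sigma ** 2))
    profile[np.abs(freqs - center) > bandwidth] = 0.0
    spec = profile * (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def gen_pac_series(config: SimulationConfig, seed: int | None = None) -> Recording:
    """Slow carrier plus a fast carrier amplitude-modulated by the slow phase.

    Fast instantaneous amplitude ∝ (1 + κ·cos φ_slow), so the implied
    18-bin phase-amplitude distribution is PA_j ∝ 1 + κ·cos(φ_j) — an
    analytic oracle for the modulation index.  The fast carrier is
    band-limited noise (``carrier_bandwidth`` wide) by default so the
    modulation survives the narrow per-band filters of the comodulogram;
    a zero bandwidth gives a pure tone at ``amp_freq``.
    """
    if config.pac is None:
        raise InvalidConfigError("config.pac must be present")
    p = config.pac
    if p.phase_freq >= p.amp_freq / 2:
        raise InvalidConfigError("phase_freq must be below amp_freq / 2")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    fs = config.sampling_rate
    t = np.arange(n) / fs
    phi_slow = 2 * np.pi * p.phase_freq * t
    if p.phase_drift > 0:
        # Brownian phase drift decorrelates the slow phase across epochs so
        # trial-shuffled (noise) comodulograms lose the coupling
        phi_slow = phi_slow + p.phase_drift * np.cumsum(rng.standard_normal(n)) / np.sqrt(fs)
    slow = p.slow_amplitude * np.cos(phi_slow)
    if p.carrier_bandwidth > 0:
        carrier = _band_noise(rng, n, config.sampling_rate, p.amp_freq,
                              p.carrier_bandwidth)
    else:
        carrier = np.cos(2 * np.pi * p.amp_freq * t)
    fast = p.fast_amplitude * (1 + p.coupling_strength * np.cos(phi_slow)) * carrier
    noise = rng.normal(0, p.noise_sd, size=n) if p.noise_sd > 0 else 0.0
    return Recording(slow + fast + noise, config.sampling_rate, channel_label="pac")


def analytic_pa(kappa: float, n_bins: int = 18) -> np.ndarray:
    """Closed-form PA vector PA_j ∝ 1 + κ·cos(φ_j) at bin centers."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    pa = 1 + kappa * np.cos(centers)
    return pa / pa.sum()


# ---------------------------------------------------------------------------
# Composite recordings, cohorts, piezo
# ---------------------------------------------------------------------------

def gen_recording(config: SimulationConfig, seed: int | None = None) -> tuple[Recording, dict]:
    """Aperiodic background plus every configured peak (and PAC term).

    Returns the recording and a ground-truth dict with the generative
    parameters and per-peak burst intervals.
    """
    base_seed = config.seed if seed is None else seed
    if isinstance(base_seed, np.random.SeedSequence):
        ss = base_seed
    else:
        ss = np.random.SeedSequence(base_seed)
    child = ss.spawn(len(config.peaks) + 2)
    rec = gen_aperiodic_series(config, seed=child[0])
    truth: dict = {
        "aperiodic": {"b": config.aperiodic.b, "m": config.aperiodic.m,
                      "knee": config.aperiodic.knee},
        "peaks": [],
    }
    for i, peak in enumerate(config.peaks):
        bg = config.aperiodic.log_psd(np.array([peak.center_freq]))[0]
        rec, intervals = add_bursty_oscillation(
            rec, peak, seed=child[i + 1], background_log_psd=bg
        )
        truth["peaks"].append({
            "center_freq": peak.center_freq, "height": peak.height,
            "burst_intervals": [list(iv) for iv in intervals],
        })
    if config.pac is not None:
        pac_rec = gen_pac_series(config, seed=child[-1])
        rec = rec.copy_with(samples=rec.samples + pac_rec.samples)
        truth["pac"] = {
            "phase_freq": config.pac.phase_freq, "amp_freq": config.pac.amp_freq,
            "kappa": config.pac.coupling_strength,
        }
    return rec, truth


def _apply_offsets(config: SimulationConfig, offsets: dict) -> SimulationConfig:
    """Additive offsets addressed by dotted paths, e.g. ``aperiodic.b`` or
    ``peaks.0.height``."""
    ap = dict(b=config.aperiodic.b, m=config.aperiodic.m, knee=config.aperiodic.knee)
    peaks = [dict(center_freq=p.center_freq, bandwidth=p.bandwidth, height=p.height,
                  burst_rate=p.burst_rate, burst_mean_duration=p.burst_mean_duration)
             for p in config.peaks]
    for path, off in offsets.items():
        parts = path.split(".")
        if parts[0] == "aperiodic":
            ap[parts[1]] += off
        elif parts[0] == "peaks":
            peaks[int(parts[1])][parts[2]] += off
        else:
            raise InvalidConfigError(f"unknown parameter path {path!r}")
    return replace(
        config,
        aperiodic=AperiodicParams(**ap),
        peaks=tuple(PeakParams(**p) for p in peaks),
    )


@dataclass
class SimulatedCohort:
    """group → subject → list of per-epoch Recordings, plus ground truth."""

    signals: dict[str, dict[str, list[Recording]]]
    truth: dict

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2)


def gen_cohort(spec: CohortSpec, base: SimulationConfig) -> SimulatedCohort:
    """Group → subject → epoch hierarchy with subject-level random effects.

    Per subject: parameters = base + group effect + N(0, subject_sd) on the
    log-scale parameters (intercept, slope, peak heights), then ``n_epochs``
    independent epochs.  Bit-identical for a fixed (spec, base)."""
    ss = np.random.SeedSequence(spec.seed)
    group_seeds = ss.spawn(spec.n_groups)
    signals: dict[str, dict[str, list[Recording]]] = {}
    truth: dict = {"groups": {}}
    for g in range(spec.n_groups):
        gname = f"group{g}"
        effects = spec.group_effects[g] if g < len(spec.group_effects) else {}
        gconfig = _apply_offsets(base, effects)
        subj_seeds = group_seeds[g].spawn(spec.n_subjects)
        signals[gname] = {}
        truth["groups"][gname] = {"effects": effects, "subjects": {}}
        for s in range(spec.n_subjects):
            sname = f"subj{g}_{s}"
            rng = np.random.default_rng(subj_seeds[s])
            perturb: dict[str, float] = {}
            if spec.subject_sd > 0:
                perturb["aperiodic.b"] = float(rng.normal(0, spec.subject_sd))
                perturb["aperiodic.m"] = float(rng.normal(0, spec.subject_sd))
                for i in range(len(gconfig.peaks)):
                    perturb[f"peaks.{i}.height"] = float(rng.normal(0, spec.subject_sd))
            sconfig = _apply_offsets(gconfig, perturb)
            epoch_seeds = subj_seeds[s].spawn(spec.n_epochs)
            epochs, epoch_truth = [], []
            for e in range(spec.n_epochs):
                rec, tr = gen_recording(sconfig, seed=epoch_seeds[e])
                epochs.append(rec)
                epoch_truth.append(tr)
            signals[gname][sname] = epochs
            truth["groups"][gname]["subjects"][sname] = {
                "params": epoch_truth[0]["aperiodic"],
                "peak_heights": [p["height"] for p in epoch_truth[0]["peaks"]],
                "perturbation": perturb,
            }
    return SimulatedCohort(signals=signals, truth=truth)


def gen_piezo(
    duration: float,
    bout_rate: float,
    bout_duration: float,
    amplitude_mV: float,
    seed: int,
    sampling_rate: float = 1000.0,
    baseline_sd: float = 0.05,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Rectified-style piezo trace with Poisson movement bouts.

    Bouts sit at ``amplitude_mV`` (with small ripple) over a near-zero
    rectified-noise baseline; ground-truth bout intervals are returned.
    """
    rng = np.random.default_rng(seed)
    n = round(duration * sampling_rate)
    trace = np.abs(rng.normal(0, baseline_sd, size=n))
    if bout_rate <= 0:
        return trace, []
    intervals = _poisson_intervals(rng, duration, bout_rate, bout_duration)
    for (t0, t1) in intervals:
        i0, i1 = int(t0 * sampling_rate), int(t1 * sampling_rate)
        if i1 > i0:
            ripple = 0.1 * amplitude_mV * rng.standard_normal(i1 - i0)
            trace[i0:i1] = np.abs(amplitude_mV + ripple)
    return trace, intervals
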