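"""Oscillation burst dynamics and movement-bout alignment.

Bursts are maximal supra-threshold runs of the band-limited analytic-signal
amplitude (or its log-squared power), with the threshold at a percentile of
the metric over a fixed-length continuous segment and a minimum-duration
rule.  Movement bouts come from a rectified piezo trace with a voltage
threshold and a gap-bridging buffer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import windows

from .io_preprocess import InvalidConfigError, Recording
from .pac import bandpass_analytic

AMPLITUDE = "amplitude"
LOG_SQUARED = "log_squared_amplitude"


@dataclass(frozen=True)
class BurstConfig:
    """Burst detection settings.

    Band defaults by context: mouse head-fixed [2, 10] Hz, freely-moving
    [3, 8] Hz, human FXS [5, 10] Hz, TD [7, 12] Hz.  The threshold is the
    90th percentile of the metric over the whole analysis segment; a
    crossing must last more than ``min_duration_ms`` to count.
    """

    band: tuple[float, float] = (2.0, 10.0)
    threshold_percentile: float = 90.0
    min_duration_ms: float = 3.0
    metric: str = AMPLITUDE
    analysis_seconds: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_percentile < 100:
            raise InvalidConfigError("threshold percentile must lie in (0, 100)")
        if self.min_duration_ms <= 0:
            raise InvalidConfigError("min_duration must be positive")
        if self.metric not in (AMPLITUDE, LOG_SQUARED):
            raise InvalidConfigError(f"unknown burst metric {self.metric!r}")


@dataclass(frozen=True)
class MovementConfig:
    volt_threshold: float = 2.0  # mV
    buffer_ms: float = 750.0

    def __post_init__(self) -> None:
        if self.volt_threshold <= 0 or self.buffer_ms <= 0:
            raise InvalidConfigError("movement thresholds must be positive")


@dataclass
class BurstStats:
    count: int
    durations_ms: np.ndarray
    threshold_value: float
    onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    sampling_rate: float = 0.0
    n_samples: int = 0
    fraction_during_movement: float | None = None
    percent_time_moving: float | None = None

    @property
    def mean_duration_ms(self) -> float:
        return float(np.mean(self.durations_ms)) if self.count else 0.0

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "durations_ms": np.asarray(self.durations_ms).tolist(),
            "threshold": self.threshold_value,
            "fraction_during_movement": self.fraction_during_movement,
            "percent_time_moving": self.percent_time_moving,
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as [start, stop) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    stops = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        stops = np.concatenate([stops, [len(mask)]])
    return list(zip(starts, stops))


def extract_analysis_window(
    rec: Recording, seconds: float, start: int | None = None, seed: int | None = None
) -> Recording:
    """A contiguous window of exactly ``seconds``; for longer recordings the
    start index is user-supplied or seeded-random."""
    n = round(seconds * rec.sampling_rate)
    if len(rec.samples) < n:
        raise InvalidConfigError("recording shorter than the analysis length")
    if len(rec.samples) == n:
        start = 0
    elif start is None:
        start = int(np.random.default_rng(seed).integers(0, len(rec.samples) - n + 1))
    piezo = rec.piezo[start:start + n] if rec.piezo is not None else None
    return replace(rec, samples=rec.samples[start:start + n], piezo=piezo)


def burst_detect(rec: Recording, cfg: BurstConfig = BurstConfig()) -> BurstStats:
    """Detect bursts on one continuous segment of the configured length.

    The segment length is part of the percentile-threshold definition, so a
    shorter recording is an error (longer ones should be cut first with
    :func:`extract_analysis_window`).
    """
    n_expected = round(cfg.analysis_seconds * rec.sampling_rate)
    if len(rec.samples) != n_expected:
        raise InvalidConfigError(
            f"burst analysis needs exactly {cfg.analysis_seconds} s of continuous data"
        )
    amp, _ = bandpass_analytic(rec.samples, cfg.band, rec.sampling_rate)
    if cfg.metric == LOG_SQUARED:
        metric = np.log10(np.maximum(amp, 1e-300) ** 2)
    else:
        metric = amp
    threshold = float(np.percentile(metric, cfg.threshold_percentile))
    if np.ptp(metric) == 0:
        warnings.warn("constant burst metric: zero bursts reported", stacklevel=2)
        return BurstStats(0, np.array([]), threshold,
                          sampling_rate=rec.sampling_rate, n_samples=len(metric))

    min_samples = cfg.min_duration_ms / 1000.0 * rec.sampling_rate
    runs = [(a, b) for a, b in _runs(metric > threshold) if (b - a) > min_samples]
    durations = np.array([(b - a) / rec.sampling_rate * 1000.0 for a, b in runs])
    onsets = np.array([a for a, _ in runs], dtype=int)
    return BurstStats(
        count=len(runs), durations_ms=durations, threshold_value=threshold,
        onsets=onsets, sampling_rate=rec.sampling_rate, n_samples=len(metric),
    )


def human_burst_detect(
    channels: list[Recording], cfg: BurstConfig
) -> tuple[BurstStats, list[BurstStats]]:
    """Channel-averaged burst metrics for human occipital data.

    Runs :func:`burst_detect` per channel with the log-squared power metric
    and averages count and mean duration across channels.
    """
    if not channels:
        raise InvalidConfigError("at least one channel required")
    cfg = replace(cfg, metric=LOG_SQUARED)
    per_channel = [burst_detect(ch, cfg) for ch in channels]
    mean_count = float(np.mean([s.count for s in per_channel]))
    mean_dur = float(np.mean([s.mean_duration_ms for s in per_channel]))
    combined = BurstStats(
        count=int(round(mean_count)),
        durations_ms=np.array([mean_dur] if mean_dur else []),
        threshold_value=float(np.mean([s.threshold_value for s in per_channel])),
        sampling_rate=channels[0].sampling_rate,
    )
    combined.mean_count = mean_count  # type: ignore[attr-defined]
    return combined, per_channel


def movement_bouts(
    piezo: np.ndarray, sampling_rate: float, cfg: MovementConfig = MovementConfig()
) -> tuple[np.ndarray, float]:
    """Binary movement state from a rectified piezo trace.

    Samples above the voltage threshold mark movement; sub-threshold gaps
    shorter than the buffer between movement samples are bridged (counted
    as movement).  Returns (state, percent_time_moving).
    """
    piezo = np.asarray(piezo, dtype=float)
    state = piezo > cfg.volt_threshold
    buffer_samples = cfg.buffer_ms / 1000.0 * sampling_rate
    if state.any():
        runs = _runs(~state)
        for a, b in runs:
            if a == 0 or b == len(state):
                continue  # leading/trailing quiescence is not a gap
            if (b - a) < buffer_samples:
                state[a:b] = True
    percent = 100.0 * state.sum() / len(state)
    return state, float(percent)


def align_bursts_movement(bursts: BurstStats, state: np.ndarray,
                          percent_time_moving: float | None = None) -> BurstStats:
    """Classify each burst by the movement state at its onset sample."""
    state = np.asarray(state, dtype=bool)
    if bursts.n_samples and len(state) != bursts.n_samples:
        raise InvalidConfigError("movement state does not match the burst timeline")
    frac = float(state[bursts.onsets].mean()) if bursts.count else 0.0
    return replace(
        bursts,
        fraction_during_movement=frac,
        percent_time_moving=percent_time_moving,
    )


def spectrogram(
    rec: Recording,
    n_tapers: int = 2,
    window_seconds: float = 3.0,
    step_seconds: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multitaper sliding-window spectrogram.

    Defaults: 2 tapers (TW = 1.5), 3 s windows, 750 ms steps, no zero
    padding.  Returns (times at window centers, freqs, power[n_freq, n_frames]).
    """
    fs = rec.sampling_rate
    win = round(window_seconds * fs)
    step = round(step_seconds * fs)
    if len(rec.samples) < win:
        raise InvalidConfigError("recording shorter than the spectrogram window")
    tw = (n_tapers + 1) / 2.0
    tapers = windows.dpss(win, tw, Kmax=n_tapers)
    n_frames = (len(rec.samples) - win) // step + 1
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    out = np.empty((len(freqs), n_frames))
    for k in range(n_frames):
        seg = rec.samples[k * step:k * step + win]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        psd = (np.abs(spec) ** 2).mean(axis=0) / fs
        psd *= 2.0
        psd[0] /= 2.0
        if win % 2 == 0:
            psd[-1] /= 2.0
        out[:, k] = psd
    times = (np.arange(n_frames) * step + win / 2) / fs
    return times, freqs, out


def write_spectrogram_tsv(times: np.ndarray, freqs: np.ndarray, power: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("# time_s\t" + "\t".join(f"{t:g}" for t in times) + "\n")
        fh.write("# rows=frequency_hz\n")
        for f, row in zip(freqs, power):
            fh.write(f"{f:g}\t" + "\t".join(repr(float(v)) for v in row) + "\n")
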