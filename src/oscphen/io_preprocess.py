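"""Recording I/O and signal conditioning.

Loads voltage time series (delimited text or EDF), applies mean detrending,
zero-phase IIR notch filtering and piezo rectification, cuts fixed-length
epochs, and flags artifact epochs by the conjunctive
amplitude + low-frequency-power rule.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal


class InvalidConfigError(ValueError):
    """Raised when a parameter violates an operation's precondition."""


@dataclass
class Recording:
    """A single-channel voltage time series in microvolts.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in µV.
    sampling_rate : float
        Sampling rate in Hz. Must be positive.
    channel_label : str
        Free-text channel identifier.
    piezo : ndarray, optional
        Rectified movement trace in mV, aligned sample-for-sample.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_label: str = ""
    piezo: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise InvalidConfigError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidConfigError("samples must be finite")
        if self.piezo is not None:
            self.piezo = np.asarray(self.piezo, dtype=float)
            if self.piezo.shape != self.samples.shape:
                raise InvalidConfigError("piezo must match samples length")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.sampling_rate

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Equal-length, non-overlapping windows of one recording.

    Epochs are never deleted by exclusion rules; they carry per-epoch
    inclusion flags so counts and provenance survive to reports.
    """

    epochs: np.ndarray  # (n_epochs, n_samples)
    sampling_rate: float
    segment_length: float
    included: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 2:
            raise InvalidConfigError("epochs must be a 2-D array")
        n = round(self.segment_length * self.sampling_rate)
        if self.epochs.shape[1] != n:
            raise InvalidConfigError(
                "segment_length × sampling_rate must equal epoch sample count"
            )
        if self.included is None:
            self.included = np.ones(len(self.epochs), dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
            if len(self.included) != len(self.epochs):
                raise InvalidConfigError("included flags must match epoch count")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def included_epochs(self) -> np.ndarray:
        return self.epochs[self.included]


# ---------------------------------------------------------------------------
# Conditioning operations
# ---------------------------------------------------------------------------

def detrend_mean(rec: Recording) -> Recording:
    """Subtract the signal mean (output mean is zero)."""
    if len(rec.samples) == 0:
        raise InvalidConfigError("cannot detrend an empty recording")
    return rec.copy_with(samples=rec.samples - rec.samples.mean())


def notch_filter(rec: Recording, center_freq: float, bandwidth: float) -> Recording:
    """Zero-phase second-order IIR notch.

    ``bandwidth`` is in normalized frequency (fraction of Nyquist), the
    convention of common second-order IIR notch designs.  Applied
    forward-backward so no phase distortion is introduced ahead of
    phase-amplitude analyses.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < center_freq < nyq:
        raise InvalidConfigError("notch center must lie in (0, Nyquist)")
    if bandwidth <= 0:
        raise InvalidConfigError("notch bandwidth must be positive")
    w0 = center_freq / nyq
    q = w0 / bandwidth
    b, a = signal.iirnotch(center_freq, q, fs=rec.sampling_rate)
    filtered = signal.filtfilt(b, a, rec.samples)
    return rec.copy_with(samples=filtered)


def rectify(trace: np.ndarray) -> np.ndarray:
    """Full-wave rectification (used for raw piezo channels)."""
    return np.abs(np.asarray(trace, dtype=float))


def segment(rec: Recording, segment_length: float) -> EpochSet:
    """Cut ``floor(duration / segment_length)`` non-overlapping epochs.

    The trailing remainder is discarded; temporal order is preserved.
    """
    if segment_length <= 0:
        raise InvalidConfigError("segment_length must be positive")
    n_per = round(segment_length * rec.sampling_rate)
    n_epochs = len(rec.samples) // n_per
    if n_epochs < 1:
        raise InvalidConfigError("segment longer than recording")
    trimmed = rec.samples[: n_epochs * n_per]
    return EpochSet(
        epochs=trimmed.reshape(n_epochs, n_per),
        sampling_rate=rec.sampling_rate,
        segment_length=segment_length,
        source_label=rec.channel_label,
    )


def concatenate_epochs(es: EpochSet, included_only: bool = False) -> np.ndarray:
    """Inverse of :func:`segment` for the retained samples."""
    eps = es.included_epochs if included_only else es.epochs
    return eps.reshape(-1)


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.where(values == med, 0.0, np.inf)
    return (values - med) / scale


def exclude_artifact_epochs(
    es: EpochSet,
    lf_cutoff: float = 1.5,
    amp_z: float = 4.0,
    lf_z: float = 4.0,
) -> tuple[EpochSet, dict]:
    """Flag epochs containing BOTH a large amplitude artifact and a
    low-frequency power spike.

    An epoch is excluded only when its peak absolute amplitude robust
    z-score across epochs exceeds ``amp_z`` AND its summed PSD power below
    ``lf_cutoff`` exceeds ``lf_z`` robust z-units above the across-epoch
    median (conjunctive rule).  Returns a new EpochSet plus a report.
    """
    if amp_z <= 0 or lf_z <= 0:
        raise InvalidConfigError("z thresholds must be positive")
    if es.n_epochs < 3:
        warnings.warn(
            "fewer than 3 epochs: artifact exclusion skipped (z-scores unstable)",
            stacklevel=2,
        )
        return es, {"excluded": [], "skipped": True}

    peak_amp = np.max(np.abs(es.epochs), axis=1)
    freqs, psd = signal.periodogram(es.epochs, fs=es.sampling_rate, axis=1)
    lf_mask = (freqs > 0) & (freqs < lf_cutoff)
    lf_power = psd[:, lf_mask].sum(axis=1)

    amp_flag = _robust_z(peak_amp) > amp_z
    lf_flag = _robust_z(lf_power) > lf_z
    artifact = amp_flag & lf_flag

    new_included = es.included & ~artifact
    report = {
        "excluded": np.nonzero(artifact)[0].tolist(),
        "amp_flagged": np.nonzero(amp_flag)[0].tolist(),
        "lf_flagged": np.nonzero(lf_flag)[0].tolist(),
        "skipped": False,
    }
    return replace(es, included=new_included), report


def amplitude_reject(es: EpochSet, limit: float = 120.0) -> EpochSet:
    """Flag epochs with any sample exceeding ±``limit`` µV."""
    if limit < 0:
        raise InvalidConfigError("limit must be non-negative")
    over = np.max(np.abs(es.epochs), axis=1) > limit
    return replace(es, included=es.included & ~over)


# ---------------------------------------------------------------------------
# Delimited time-series format
# ---------------------------------------------------------------------------
# Header lines: "# sampling_rate_hz=<float>", "# channel=<text>", then one
# sample per line in µV; optional second whitespace-separated column = piezo
# in mV.

def write_delimited(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz={rec.sampling_rate!r}\n")
        fh.write(f"# channel={rec.channel_label}\n")
        if rec.piezo is None:
            for v in rec.samples:
                fh.write(f"{float(v)!r}\n")
        else:
            for v, p in zip(rec.samples, rec.piezo):
                fh.write(f"{float(v)!r}\t{float(p)!r}\n")


def read_delimited(path: str | Path) -> Recording:
    path = Path(path)
    rate = None
    label = ""
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if key.strip() == "sampling_rate_hz":
                    rate = float(value)
                elif key.strip() == "channel":
                    label = value.strip()
            else:
                data_lines.append(line)
    if rate is None:
        raise InvalidConfigError(f"{path}: missing sampling_rate_hz header")
    arr = np.array([[float(v) for v in ln.split()] for ln in data_lines])
    if arr.ndim != 2 or arr.shape[1] not in (1, 2):
        raise InvalidConfigError(f"{path}: expected 1 or 2 data columns")
    piezo = arr[:, 1] if arr.shape[1] == 2 else None
    return Recording(arr[:, 0], rate, channel_label=label, piezo=piezo)


# ---------------------------------------------------------------------------
# Minimal EDF support (16-bit European Data Format, continuous records)
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, channels: list[str] | None = None) -> list[Recording]:
    """Read selected channels of an EDF file as Recordings.

    ``channels``: channel labels to load (all when None).  Digital values
    are mapped to physical units with the per-signal calibration.
    """
    path = Path(path)
    with path.open("rb") as fh:
        hdr = fh.read(256)
        n_records = int(hdr[236:244].decode().strip())
        record_dur = float(hdr[244:252].decode().strip())
        ns = int(hdr[252:256].decode().strip())

        def _fields(width: int) -> list[str]:
            raw = fh.read(width * ns)
            return [raw[i * width:(i + 1) * width].decode().strip() for i in range(ns)]

        labels = _fields(16)
        _fields(80)  # transducer
        _fields(8)   # physical dimension
        phys_min = [float(v) for v in _fields(8)]
        phys_max = [float(v) for v in _fields(8)]
        dig_min = [float(v) for v in _fields(8)]
        dig_max = [float(v) for v in _fields(8)]
        _fields(80)  # prefiltering
        n_samp = [int(v) for v in _fields(8)]
        _fields(32)  # reserved

        per_record = sum(n_samp)
        raw = np.frombuffer(fh.read(per_record * n_records * 2), dtype="<i2")

    raw = raw.reshape(n_records, per_record)
    offsets = np.concatenate([[0], np.cumsum(n_samp)])
    wanted = labels if channels is None else channels
    out = []
    for lab in wanted:
        if lab not in labels:
            raise InvalidConfigError(f"channel {lab!r} not in EDF file")
        i = labels.index(lab)
        dig = raw[:, offsets[i]:offsets[i + 1]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        phys = (dig - dig_min[i]) * gain + phys_min[i]
        out.append(Recording(phys, n_samp[i] / record_dur, channel_label=lab))
    return out


def write_edf(recs: list[Recording], path: str | Path, record_dur: float = 1.0) -> None:
    """Write Recordings as a minimal EDF file (testing / interchange)."""
    path = Path(path)
    ns = len(recs)
    n_samp = [round(r.sampling_rate * record_dur) for r in recs]
    n_records = min(len(r.samples) // k for r, k in zip(recs, n_samp))

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode()

    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80), pad("01.01.20", 8),
        pad("00.00.00", 8), pad(str(256 * (ns + 1)), 8), pad("", 44),
        pad(str(n_records), 8), pad(repr(record_dur), 8), pad(str(ns), 4),
    ])
    phys_min, phys_max = [], []
    for r in recs:
        lo = float(np.floor(r.samples.min())) - 1.0
        hi = float(np.ceil(r.samples.max())) + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
    sig_hdr = b"".join([
        b"".join(pad(r.channel_label or f"ch{i}", 16) for i, r in enumerate(recs)),
        b"".join(pad("", 80) for _ in recs),
        b"".join(pad("uV", 8) for _ in recs),
        b"".join(pad(f"{v:.6g}", 8) for v in phys_min),
        b"".join(pad(f"{v:.6g}", 8) for v in phys_max),
        b"".join(pad("-32768", 8) for _ in recs),
        b"".join(pad("32767", 8) for _ in recs),
        b"".join(pad("", 80) for _ in recs),
        b"".join(pad(str(k), 8) for k in n_samp),
        b"".join(pad("", 32) for _ in recs),
    ])
    with path.open("wb") as fh:
        fh.write(hdr + sig_hdr)
        for rec_i in range(n_records):
            for r, k, lo, hi in zip(recs, n_samp, phys_min, phys_max):
                chunk = r.samples[rec_i * k:(rec_i + 1) * k]
                dig = np.round((chunk - lo) / (hi - lo) * 65535.0 - 32768.0)
                fh.write(struct.pack(f"<{k}h", *dig.astype(int)))
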