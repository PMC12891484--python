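"""Multitaper power spectral density estimation.

Implements the cross-species time-bandwidth calibration
TW = (FR × segment_length) / 2 with K = 2·TW − 1 Slepian tapers,
epoch/channel averaging in linear power, and optional bin interpolation
of log power onto a finer grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import windows

from .io_preprocess import EpochSet, InvalidConfigError

_LOG_FLOOR = 1e-300  # avoids -inf for numerically zero power bins


@dataclass(frozen=True)
class TaperParams:
    """Multitaper configuration tied to a target spectral resolution.

    Invariants: ``TW = (FR × segment_length) / 2`` and
    ``K = floor(2·TW − 1) ≥ 1``.
    """

    FR: float
    segment_length: float
    TW: float
    K: int

    @classmethod
    def from_resolution(cls, FR: float, segment_length: float, K: int | None = None) -> "TaperParams":
        if FR <= 0 or segment_length <= 0:
            raise InvalidConfigError("FR and segment_length must be positive")
        TW = (FR * segment_length) / 2.0
        k = int(math.floor(2 * TW - 1)) if K is None else int(K)
        if k < 1:
            raise InvalidConfigError(
                f"resolution {FR} Hz too fine for {segment_length} s segments (K < 1)"
            )
        return cls(FR=FR, segment_length=segment_length, TW=TW, K=k)

    @classmethod
    def from_tw(cls, TW: float, segment_length: float, K: int | None = None) -> "TaperParams":
        """Inverse use: recover FR from (TW, segment_length)."""
        return cls.from_resolution(2.0 * TW / segment_length, segment_length, K=K)


def taper_params(FR: float, segment_length: float, K: int | None = None) -> TaperParams:
    """Calibrate (TW, K) for a spectral resolution and segment length."""
    return TaperParams.from_resolution(FR, segment_length, K=K)


@dataclass
class PowerSpectrum:
    """Frequency grid plus linear power (µV²/Hz) with a log10 view."""

    freqs: np.ndarray
    power: np.ndarray
    bin_width: float
    n_epochs_averaged: int = 1
    interpolated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise InvalidConfigError("freqs and power must have equal shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidConfigError("freqs must be strictly increasing")

    @property
    def log_power(self) -> np.ndarray:
        return np.log10(np.maximum(self.power, _LOG_FLOOR))

    def band(self, f_lo: float, f_hi: float) -> "PowerSpectrum":
        """Restrict to f_lo ≤ f ≤ f_hi (inclusive, tolerance half a bin)."""
        tol = 1e-9
        m = (self.freqs >= f_lo - tol) & (self.freqs <= f_hi + tol)
        return replace(self, freqs=self.freqs[m], power=self.power[m])


def multitaper_psd(es: EpochSet, tp: TaperParams) -> tuple[list[PowerSpectrum], PowerSpectrum]:
    """Per-epoch multitaper PSDs plus their linear-power average.

    Uses discrete prolate spheroidal (Slepian) tapers with the configured
    time-bandwidth product and taper count, no zero padding; the averaged
    spectrum is the arithmetic mean of the included epochs' linear power.
    Bin width is 1/segment_length.
    """
    eps = es.included_epochs
    if len(eps) < 1:
        raise InvalidConfigError("no included epochs")
    n = eps.shape[1]
    if abs(es.segment_length - tp.segment_length) > 1e-9:
        raise InvalidConfigError("TaperParams segment_length does not match epochs")
    if tp.K > 2 * tp.TW:
        raise InvalidConfigError("taper count exceeds usable tapers (K > 2·TW)")

    tapers = windows.dpss(n, tp.TW, Kmax=tp.K)  # (K, n), unit energy
    fs = es.sampling_rate
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # (n_epochs, K, n_freq)
    spec = np.fft.rfft(eps[:, None, :] * tapers[None, :, :], axis=2)
    psd = (np.abs(spec) ** 2).mean(axis=1) / fs
    psd *= 2.0  # one-sided
    psd[:, 0] /= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0

    bin_width = 1.0 / tp.segment_length
    per_epoch = [
        PowerSpectrum(freqs, p, bin_width=bin_width, n_epochs_averaged=1,
                      meta={"TW": tp.TW, "K": tp.K})
        for p in psd
    ]
    avg = PowerSpectrum(
        freqs, psd.mean(axis=0), bin_width=bin_width,
        n_epochs_averaged=len(eps), meta={"TW": tp.TW, "K": tp.K},
    )
    return per_epoch, avg


def average_spectra(spectra: list[PowerSpectrum], weights: np.ndarray | None = None) -> PowerSpectrum:
    """Element-wise (optionally weighted) mean of linear power.

    All inputs must share one frequency grid; log power is recomputed from
    the averaged linear power.
    """
    if not spectra:
        raise InvalidConfigError("no spectra to average")
    ref = spectra[0]
    for ps in spectra[1:]:
        if ps.freqs.shape != ref.freqs.shape or not np.allclose(ps.freqs, ref.freqs):
            raise InvalidConfigError("mismatched frequency grids")
    stack = np.stack([ps.power for ps in spectra])
    mean = np.average(stack, axis=0, weights=weights)
    return PowerSpectrum(
        ref.freqs.copy(), mean, bin_width=ref.bin_width,
        n_epochs_averaged=sum(ps.n_epochs_averaged for ps in spectra),
        interpolated=ref.interpolated, meta=dict(ref.meta),
    )


def interpolate_psd(ps: PowerSpectrum, target_bin: float = 0.1) -> PowerSpectrum:
    """Linear interpolation of log power onto a finer grid.

    Native-grid values are reproduced exactly at native bins; the
    interpolation flag is set on the result.
    """
    if target_bin >= ps.bin_width:
        raise InvalidConfigError("target bin must be finer than the native bin")
    f0, f1 = ps.freqs[0], ps.freqs[-1]
    n_steps = int(round((f1 - f0) / target_bin))
    fine = f0 + target_bin * np.arange(n_steps + 1)
    logp = np.interp(fine, ps.freqs, ps.log_power)
    return PowerSpectrum(
        fine, 10.0 ** logp, bin_width=target_bin,
        n_epochs_averaged=ps.n_epochs_averaged, interpolated=True,
        meta=dict(ps.meta),
    )


def write_spectrum_tsv(ps: PowerSpectrum, path) -> None:
    """Spectrum TSV: frequency_hz, power, log10_power + metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# bin_width_hz={ps.bin_width!r}\n")
        fh.write(f"# n_epochs={ps.n_epochs_averaged}\n")
        fh.write(f"# interpolated={ps.interpolated}\n")
        for k, v in ps.meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("frequency_hz\tpower\tlog10_power\n")
        for f, p, lp in zip(ps.freqs, ps.power, ps.log_power):
            fh.write(f"{float(f)!r}\t{float(p)!r}\t{float(lp)!r}\n")


def read_spectrum_tsv(path) -> PowerSpectrum:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
            elif not line.startswith("frequency_hz"):
                rows.append([float(x) for x in line.split("\t")[:2]])
    arr = np.array(rows)
    return PowerSpectrum(
        arr[:, 0], arr[:, 1],
        bin_width=float(meta.pop("bin_width_hz")),
        n_epochs_averaged=int(meta.pop("n_epochs", 1)),
        interpolated=meta.pop("interpolated", "False") == "True",
        meta=meta,
    )
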