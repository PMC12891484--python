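"""Phase-amplitude coupling: band grids, analytic signals, 18-bin
phase-amplitude distributions, modulation index, and comodulograms.

MI is the normalized entropy deficit of the phase-amplitude distribution:
``MI = (log N − H) / log N`` with ``H = −Σ PA_j·log PA_j`` and N = 18 bins;
it is 0 for a flat distribution and 1 when all amplitude concentrates in a
single phase bin, and is invariant to the logarithm base and to amplitude
rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import filtfilt, firls, hilbert

from .io_preprocess import EpochSet, InvalidConfigError

N_PHASE_BINS = 18


@dataclass(frozen=True)
class BandGrid:
    """Comodulogram band definitions.

    Default grid: 6 phase bands of width 2 Hz with centers 3–8 Hz stepping
    1 Hz (the only placement of six 2 Hz-wide bands inside 2–9 Hz), and 26
    amplitude bands of width 4 Hz with centers 12–62 Hz stepping 2 Hz
    (lower edges spanning 10–60 Hz).
    """

    phase_bands: tuple[tuple[float, float], ...]
    amp_bands: tuple[tuple[float, float], ...]

    @classmethod
    def default(cls) -> "BandGrid":
        phase = tuple((c - 1.0, c + 1.0) for c in range(3, 9))
        amp = tuple((c - 2.0, c + 2.0) for c in range(12, 63, 2))
        return cls(phase_bands=phase, amp_bands=amp)

    @property
    def phase_centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.phase_bands])

    @property
    def amp_centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.amp_bands])


@dataclass
class PhaseAmpDistribution:
    """18 normalized mean amplitudes over equal phase bins covering (−π, π]."""

    pa: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.pa = np.asarray(self.pa, dtype=float)
        if len(self.pa) != len(self.bin_edges) - 1:
            raise InvalidConfigError("bin edges inconsistent with PA length")
        if abs(self.pa.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("PA must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


@dataclass
class Comodulogram:
    """MI matrix indexed by (phase band, amplitude band)."""

    mi: np.ndarray  # (n_phase, n_amp)
    grid: BandGrid
    is_noise: bool = False
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Filtering and analytic signals
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _design_bandpass(fs: float, low: float, high: float) -> np.ndarray:
    """Two-pass least-squares FIR bandpass (eegfilt-style).

    Order = 3 cycles of the low cutoff (3·fs/low samples, minimum 15),
    15% transition bands; applied forward-backward.
    """
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise InvalidConfigError("band must lie within (0, Nyquist)")
    order = max(int(3 * fs // low), 15)
    numtaps = order + 1 if order % 2 == 0 else order + 2  # firls needs odd
    trans = 0.15
    f_lo_stop = max(low * (1 - trans), 1e-6)
    f_hi_stop = min(high * (1 + trans), nyq * 0.999)
    bands = np.array([0, f_lo_stop, low, high, f_hi_stop, nyq]) / nyq
    desired = [0, 0, 1, 1, 0, 0]
    return firls(numtaps, bands, desired)


def bandpass_analytic(
    samples: np.ndarray, band: tuple[float, float], fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase FIR bandpass followed by the analytic signal.

    Returns (amplitude, phase); phase lies in (−π, π].
    """
    x = np.asarray(samples, dtype=float)
    taps = _design_bandpass(float(fs), float(band[0]), float(band[1]))
    if len(x) <= 3 * (len(taps) - 1):
        raise InvalidConfigError(
            f"epoch of {len(x)} samples too short for filter order {len(taps) - 1}"
        )
    filtered = filtfilt(taps, [1.0], x)
    analytic = hilbert(filtered)
    return np.abs(analytic), np.angle(analytic)


# ---------------------------------------------------------------------------
# Phase-amplitude distribution and modulation index
# ---------------------------------------------------------------------------

def phase_amp_distribution(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_PHASE_BINS
) -> PhaseAmpDistribution:
    """Mean amplitude per phase bin, normalized to sum 1.

    Bins are left-open/right-closed over (−π, π]; empty bins contribute 0
    before normalization; an all-zero amplitude yields the uniform
    distribution with a warning.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise InvalidConfigError("phase and amplitude must have equal length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, phase, side="left") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        warnings.warn("all-zero amplitude: uniform PA returned", stacklevel=2)
        return PhaseAmpDistribution(np.full(n_bins, 1.0 / n_bins), edges)
    return PhaseAmpDistribution(means / total, edges)


def modulation_index(pa: PhaseAmpDistribution | np.ndarray) -> float:
    """Normalized entropy deficit; base-invariant, in [0, 1]."""
    p = pa.pa if isinstance(pa, PhaseAmpDistribution) else np.asarray(pa, dtype=float)
    n = len(p)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())  # 0·log 0 := 0
    return (np.log(n) - h) / np.log(n)


# ---------------------------------------------------------------------------
# Comodulograms
# ---------------------------------------------------------------------------

def _epoch_band_signals(
    es: EpochSet, grid: BandGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Phases for every (epoch, phase band) and amplitudes for every
    (epoch, amplitude band); epochs restricted to the included set."""
    eps = es.included_epochs
    fs = es.sampling_rate
    n_ep, n = eps.shape
    phases = np.empty((n_ep, len(grid.phase_bands), n))
    amps = np.empty((n_ep, len(grid.amp_bands), n))
    for e in range(n_ep):
        for j, band in enumerate(grid.phase_bands):
            _, phases[e, j] = bandpass_analytic(eps[e], band, fs)
        for j, band in enumerate(grid.amp_bands):
            amps[e, j], _ = bandpass_analytic(eps[e], band, fs)
    return phases, amps


def _mi_matrix(phases: np.ndarray, amps: np.ndarray) -> np.ndarray:
    out = np.empty((phases.shape[0], amps.shape[0]))
    for i in range(phases.shape[0]):
        for j in range(amps.shape[0]):
            out[i, j] = modulation_index(phase_amp_distribution(phases[i], amps[j]))
    return out


def comodulogram(es: EpochSet, grid: BandGrid | None = None) -> list[Comodulogram]:
    """Per-epoch MI matrices over the full band grid (6 × 26 by default)."""
    grid = grid or BandGrid.default()
    phases, amps = _epoch_band_signals(es, grid)
    return [
        Comodulogram(_mi_matrix(phases[e], amps[e]), grid)
        for e in range(phases.shape[0])
    ]


def mismatch_pairing(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random pairing j(i) with j(i) ≠ i for every i (n ≥ 2)."""
    if n < 2:
        raise InvalidConfigError("mismatch pairing needs at least 2 epochs")
    pairing = rng.integers(0, n, size=n)
    clash = pairing == np.arange(n)
    while clash.any():
        pairing[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = pairing == np.arange(n)
    return pairing


def noise_comodulogram(
    es: EpochSet,
    grid: BandGrid | None = None,
    pairing: np.ndarray | None = None,
    seed: int | None = None,
) -> list[Comodulogram]:
    """MI with the phase of epoch i paired with the amplitude of epoch
    j ≠ i, destroying within-epoch phase alignment."""
    grid = grid or BandGrid.default()
    phases, amps = _epoch_band_signals(es, grid)
    n_ep = phases.shape[0]
    if pairing is None:
        pairing = mismatch_pairing(n_ep, np.random.default_rng(seed))
    pairing = np.asarray(pairing)
    if np.any(pairing == np.arange(n_ep)):
        raise InvalidConfigError("noise pairing may not map an epoch to itself")
    return [
        Comodulogram(_mi_matrix(phases[i], amps[j]), grid, is_noise=True,
                     meta={"phase_epoch": int(i), "amp_epoch": int(j)})
        for i, j in enumerate(pairing)
    ]


def pairwise_noise_mi(es: EpochSet, grid: BandGrid | None = None) -> np.ndarray:
    """Full mismatched-pair MI tensor of shape (n_ep, n_ep, n_phase, n_amp).

    Cell [i, j] holds the MI matrix with phase from epoch i and amplitude
    from epoch j; the diagonal holds the true (matched) matrices.  Feeds
    the noise-subtracted comodulogram bootstrap, which draws arbitrary
    mismatched pairs per replicate.
    """
    grid = grid or BandGrid.default()
    phases, amps = _epoch_band_signals(es, grid)
    n_ep = phases.shape[0]
    out = np.empty((n_ep, n_ep, len(grid.phase_bands), len(grid.amp_bands)))
    for i in range(n_ep):
        for j in range(n_ep):
            out[i, j] = _mi_matrix(phases[i], amps[j])
    return out


def write_comodulogram_tsv(com: Comodulogram, path) -> None:
    """Rows = phase-band centers, columns = amplitude-band centers."""
    with open(path, "w") as fh:
        fh.write(f"# noise={com.is_noise}\n")
        fh.write("phase_hz\\amp_hz\t" + "\t".join(f"{c:g}" for c in com.grid.amp_centers) + "\n")
        for c, row in zip(com.grid.phase_centers, com.mi):
            fh.write(f"{c:g}\t" + "\t".join(repr(float(v)) for v in row) + "\n")
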