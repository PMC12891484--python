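"""Anchor-based Lorentzian fit of the aperiodic (1/f) spectrum component.

Model (log10 power): ``y(f) = b − log10(knee + f^(−m))``; with knee = 0 this
reduces to the straight line ``b + m·log10(f)``.

Two variants:

* ``fit_linear`` — for surface EEG spectra that are straight in log-log
  space.  A fixed low-frequency anchor is combined with the candidate above
  the search floor that yields the steepest line; the steepest line through
  the fixed anchor lies at or below the spectrum at every candidate, so the
  periodic residual is non-negative there by construction.
* ``fit_knee`` — for depth LFP spectra that bend at low frequency.  A fixed
  high-frequency anchor (global power minimum, optionally skipping a notch
  gap) is combined with the shallowest-slope candidate in a mid-frequency
  window, then knee estimates are back-computed from low-frequency local
  minima lying below the knee-free line.

Anchor and candidate coordinates are neighbor-averaged in BOTH axes
(mean log-power paired with the mean log-frequency of the same bins), so a
spectrum exactly of the model's form is recovered to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import InvalidConfigError
from .spectral import PowerSpectrum


@dataclass
class AperiodicFit:
    """Fitted aperiodic component.

    ``offset`` is the model log10 power at the lower fit edge.  ``anchors``
    holds the (frequency, log-power) pairs the line was drawn through.
    """

    variant: str  # "linear" | "knee"
    b: float
    m: float
    knee: float
    offset: float
    fit_range: tuple[float, float]
    anchors: list[tuple[float, float]]
    notch_gap: tuple[float, float] | None = None
    warnings_: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "b": self.b,
            "m": self.m,
            "knee": self.knee,
            "offset": self.offset,
            "fit_range": list(self.fit_range),
            "anchors": [list(a) for a in self.anchors],
            "notch_gap": list(self.notch_gap) if self.notch_gap else None,
            "warnings": list(self.warnings_),
        }


@dataclass
class PeriodicSpectrum:
    """Log10-power residual after subtracting the aperiodic fit."""

    freqs: np.ndarray
    residual: np.ndarray
    fit: AperiodicFit

    def band(self, f_lo: float, f_hi: float) -> "PeriodicSpectrum":
        tol = 1e-9
        m = (self.freqs >= f_lo - tol) & (self.freqs <= f_hi + tol)
        return PeriodicSpectrum(self.freqs[m], self.residual[m], self.fit)


def evaluate(fit: AperiodicFit, freqs: np.ndarray) -> np.ndarray:
    """Model curve ``b − log10(knee + f^(−m))`` at the given frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise InvalidConfigError("model is defined for f > 0 only")
    if fit.knee == 0:
        return fit.b + fit.m * np.log10(freqs)
    return fit.b - np.log10(fit.knee + freqs ** (-fit.m))


def _neighbor_point(logf: np.ndarray, logp: np.ndarray, i: int) -> tuple[float, float]:
    """Mean (log-frequency, log-power) over bin i and its available neighbors."""
    lo, hi = max(i - 1, 0), min(i + 1, len(logp) - 1)
    sl = slice(lo, hi + 1)
    return float(logf[sl].mean()), float(logp[sl].mean())


def _low_anchor(freqs: np.ndarray, logf: np.ndarray, logp: np.ndarray,
                f_lo: float, span: float = 0.6) -> tuple[float, float]:
    """Mean point over the lowest ``span`` Hz of the fitting range."""
    m = freqs < f_lo + span - 1e-9
    if not m.any():
        m = np.zeros(len(freqs), dtype=bool)
        m[0] = True
    return float(logf[m].mean()), float(logp[m].mean())


def fit_linear(
    ps: PowerSpectrum,
    f_lo: float,
    f_hi: float,
    search_min: float = 8.0,
) -> AperiodicFit:
    """Knee-free fit: fixed low anchor + steepest-slope candidate above
    ``search_min``.

    The anchor is the averaged point over the lowest 0.6 Hz of the fitting
    range; every bin in (search_min, f_hi] is a candidate with a
    three-bin-averaged coordinate; the candidate maximizing the slope
    magnitude of the line through the anchor wins (ties broken toward the
    lowest frequency).
    """
    band = ps.band(f_lo, f_hi)
    if len(band.freqs) < 3:
        raise InvalidConfigError("grid does not cover the fitting range")
    logp = band.log_power
    if not np.all(np.isfinite(logp)):
        raise InvalidConfigError("non-finite log power in fitting range")
    logf = np.log10(band.freqs)

    ax, ay = _low_anchor(band.freqs, logf, logp, f_lo)

    cand_idx = np.nonzero(band.freqs > search_min)[0]
    if len(cand_idx) == 0:
        raise InvalidConfigError("no slope candidates above search_min")
    pts = np.array([_neighbor_point(logf, logp, i) for i in cand_idx])
    slopes = (pts[:, 1] - ay) / (pts[:, 0] - ax)
    best = int(np.argmax(np.abs(slopes)))  # first index wins ties → lowest f

    m = float(slopes[best])
    b = ay - m * ax
    warns = []
    if m >= 0:
        warns.append("non-negative fitted slope (pathological input)")
    fit = AperiodicFit(
        variant="linear", b=b, m=m, knee=0.0,
        offset=b + m * np.log10(f_lo),
        fit_range=(f_lo, f_hi),
        anchors=[(10 ** ax, ay), (float(band.freqs[cand_idx[best]]), float(pts[best, 1]))],
        warnings_=warns,
    )
    return fit


def _local_minima(values: np.ndarray) -> list[int]:
    """Indices of strict interior local minima; leftmost bin of plateaus."""
    out = []
    n = len(values)
    i = 1
    while i < n - 1:
        if values[i] < values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[j]:
                j += 1
            if j < n - 1 and values[j + 1] > values[j]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def fit_knee(
    ps: PowerSpectrum,
    f_lo: float = 1.5,
    hi_search_max: float = 175.0,
    notch_gap: tuple[float, float] | None = (45.0, 75.0),
    mid_search: tuple[float, float] = (9.0, 25.0),
    knee_search: tuple[float, float] = (1.5, 2.24),
) -> AperiodicFit:
    """Lorentzian fit with a knee, anchored at the high-frequency power
    minimum.

    Steps: (1) the high anchor is the frequency with the lowest linear power
    up to ``hi_search_max`` (skipping ``notch_gap`` when set), averaged with
    its two neighbors; (2) the candidate in ``mid_search`` minimizing the
    slope magnitude of the line through the anchor yields (m, b); (3) local
    minima of log power inside ``knee_search`` lying below that line each
    give a knee estimate ``10^(b − y) − x^(−m)`` and the knee is their mean
    (falling back to all below-line bins when the noiseless spectrum is
    monotone and has no interior minimum, and to 0 when nothing lies below
    the line); (4) the offset is the model value at ``f_lo``.
    """
    band = ps.band(f_lo, max(hi_search_max, mid_search[1]))
    if len(band.freqs) < 5 or band.freqs[-1] < mid_search[1]:
        raise InvalidConfigError("grid does not cover the fitting range")
    freqs = band.freqs
    logp = band.log_power
    logf = np.log10(freqs)
    warns: list[str] = []

    # (1) high anchor: global linear-power minimum, notch gap excluded
    search = freqs <= hi_search_max + 1e-9
    if notch_gap is not None:
        search &= ~((freqs >= notch_gap[0]) & (freqs <= notch_gap[1]))
    idx_candidates = np.nonzero(search)[0]
    i1 = idx_candidates[int(np.argmin(band.power[idx_candidates]))]
    x1, y1 = _neighbor_point(logf, logp, int(i1))

    # (2) shallowest line through the high anchor from mid-window candidates
    mid_idx = np.nonzero((freqs >= mid_search[0]) & (freqs <= mid_search[1]))[0]
    if len(mid_idx) == 0:
        raise InvalidConfigError("no candidates in mid-frequency search window")
    pts = np.array([_neighbor_point(logf, logp, int(i)) for i in mid_idx])
    slopes = (y1 - pts[:, 1]) / (x1 - pts[:, 0])
    best = int(np.argmin(np.abs(slopes)))
    m = float(slopes[best])
    b = y1 - m * x1
    if m >= 0:
        warns.append("non-negative fitted slope (pathological input)")

    # (3) knee from low-frequency points below the knee-free line
    km = (freqs >= knee_search[0] - 1e-9) & (freqs <= knee_search[1] + 1e-9)
    kidx = np.nonzero(km)[0]
    line_at = b + m * logf
    minima = [i for i in _local_minima(logp) if km[i]]
    below = [i for i in minima if logp[i] < line_at[i] - 1e-12]
    if not minima:
        # noiseless monotone spectrum: no interior minima exist; use every
        # below-line bin in the window instead
        below = [int(i) for i in kidx if logp[i] < line_at[i] - 1e-12]
    knee = 0.0
    if below:
        ks = [10.0 ** (b - logp[i]) - freqs[i] ** (-m) for i in below]
        knee = float(np.mean(ks))
        if knee < 0:
            warns.append("negative mean knee estimate clamped to 0")
            knee = 0.0
    else:
        warns.append("no valid knee candidates; knee set to 0")

    fit = AperiodicFit(
        variant="knee", b=b, m=m, knee=knee,
        offset=b - np.log10(knee + f_lo ** (-m)),
        fit_range=(f_lo, float(min(freqs[-1], hi_search_max))),
        anchors=[(float(freqs[i1]), y1),
                 (float(freqs[mid_idx[best]]), float(pts[best, 1]))],
        notch_gap=notch_gap,
        warnings_=warns,
    )
    return fit


def subtract(ps: PowerSpectrum, fit: AperiodicFit) -> PeriodicSpectrum:
    """Periodic spectrum: log power minus the fitted aperiodic curve."""
    f_lo, f_hi = fit.fit_range
    band = ps.band(f_lo, f_hi)
    if len(band.freqs) == 0:
        raise InvalidConfigError("spectrum grid lies outside the fit range")
    residual = band.log_power - evaluate(fit, band.freqs)
    return PeriodicSpectrum(band.freqs, residual, fit)
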