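"""Periodic peak extraction from the aperiodic-subtracted spectrum.

Human spectra yield Pk1/Pk2 around a 15 Hz split; mouse surface spectra a
single smoothed peak below 10 Hz; mouse depth spectra two subpeaks
(Pk1a/Pk1b) of the 2–10 Hz structure split at the deepest smoothed local
minimum (fallback split at 6 Hz when no interior minimum exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from statsmodels.nonparametric.smoothers_lowess import lowess

from .aperiodic import PeriodicSpectrum
from .io_preprocess import InvalidConfigError

AUTOMATIC = "automatic"
FALLBACK_SPLIT = "fallback_split"


@dataclass
class Peak:
    label: str  # Pk1 | Pk2 | Pk1a | Pk1b
    center_frequency: float
    max_power: float
    detection_mode: str = AUTOMATIC
    weak: bool = False  # residual non-positive over the search window
    raw_max_power: float | None = None

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "center_frequency_hz": self.center_frequency,
            "max_power_log10": self.max_power,
            "detection_mode": self.detection_mode,
            "weak": self.weak,
        }
        if self.raw_max_power is not None:
            d["raw_max_power_log10"] = self.raw_max_power
        return d


def _argmax_peak(freqs: np.ndarray, residual: np.ndarray, label: str) -> Peak:
    i = int(np.argmax(residual))
    return Peak(
        label=label,
        center_frequency=float(freqs[i]),
        max_power=float(residual[i]),
        weak=bool(np.all(residual <= 0)),
    )


def find_peaks_human(per: PeriodicSpectrum, split: float = 15.0) -> dict[str, Peak]:
    """Pk1 = residual argmax below ``split``; Pk2 = argmax above it."""
    below = per.freqs < split
    above = per.freqs > split
    if not below.any() or not above.any():
        raise InvalidConfigError("residual must cover both sides of the split")
    return {
        "Pk1": _argmax_peak(per.freqs[below], per.residual[below], "Pk1"),
        "Pk2": _argmax_peak(per.freqs[above], per.residual[above], "Pk2"),
    }


def _smooth(freqs: np.ndarray, residual: np.ndarray, span: float) -> np.ndarray:
    """Locally weighted linear regression (lowess) of the residual."""
    n_bins = max(int(round(span * len(freqs))), 1) if span <= 1 else int(span)
    if n_bins < 3:
        raise InvalidConfigError("smoother span below 3 bins")
    frac = min(n_bins / len(freqs), 1.0)
    return lowess(residual, freqs, frac=frac, it=0, return_sorted=False)


def find_peak_mouse_surface(
    per: PeriodicSpectrum, upper: float = 10.0, smooth_span: float = 0.25
) -> Peak:
    """Single smoothed-residual peak below ``upper`` Hz.

    ``smooth_span``: lowess span as a fraction of the window's bins (≤ 1)
    or an absolute bin count (> 1).  The peak power is read from the
    smoothed curve; the raw residual value is recorded alongside.
    """
    m = (per.freqs > per.fit.fit_range[0]) & (per.freqs <= upper)
    if not m.any():
        raise InvalidConfigError("residual does not cover the search window")
    freqs, residual = per.freqs[m], per.residual[m]
    sm = _smooth(freqs, residual, smooth_span)
    i = int(np.argmax(sm))  # argmax returns the first (lowest-f) maximum
    return Peak(
        label="Pk1",
        center_frequency=float(freqs[i]),
        max_power=float(sm[i]),
        weak=bool(np.all(sm <= 0)),
        raw_max_power=float(residual[i]),
    )


def find_subpeaks(
    per: PeriodicSpectrum,
    smooth_span: float = 0.25,
    fallback_split: float = 6.0,
    window: tuple[float, float] = (2.0, 10.0),
    interior: tuple[float, float] = (3.0, 9.0),
    split_mode: str = "prominence",
) -> dict[str, Peak]:
    """Split the 2–10 Hz periodic structure into Pk1a / Pk1b.

    The split is the smoothed residual's interior local minimum within
    ``interior``; "largest" is implemented as greatest prominence
    (``split_mode="value"`` selects the literal largest-valued minimum
    instead).  With no interior minimum, the split falls back to
    ``fallback_split`` and both peaks carry the fallback detection mode.
    Subpeak maxima are read from the raw residual.
    """
    m = (per.freqs >= window[0]) & (per.freqs <= window[1])
    if not m.any():
        raise InvalidConfigError(f"residual does not cover {window}")
    freqs, residual = per.freqs[m], per.residual[m]
    sm = _smooth(freqs, residual, smooth_span)

    troughs, props = find_peaks(-sm, prominence=0)
    keep = [
        (i, p) for i, p in zip(troughs, props["prominences"])
        if interior[0] <= freqs[i] <= interior[1]
    ]
    mode = AUTOMATIC
    if keep:
        if split_mode == "value":
            split_i = max(keep, key=lambda t: sm[t[0]])[0]
        else:
            split_i = max(keep, key=lambda t: t[1])[0]
        split = float(freqs[split_i])
    else:
        split = fallback_split
        mode = FALLBACK_SPLIT

    lo = freqs < split
    hi = freqs > split
    pk1a = _argmax_peak(freqs[lo], residual[lo], "Pk1a")
    pk1b = _argmax_peak(freqs[hi], residual[hi], "Pk1b")
    pk1a.detection_mode = pk1b.detection_mode = mode
    return {"Pk1a": pk1a, "Pk1b": pk1b, "split": split}
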