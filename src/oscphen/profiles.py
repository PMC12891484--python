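"""Named analysis presets bundling all stage parameters."""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_preprocess import InvalidConfigError


@dataclass(frozen=True)
class AnalysisProfile:
    name: str
    variant: str                 # "linear" | "knee"
    f_lo: float                  # lower fit edge, Hz
    f_hi: float                  # upper fit edge, Hz
    segment_length: float        # seconds
    FR: float                    # spectral resolution, Hz
    interp_bin: float | None = None   # interpolate PSD bins to this width
    peak_mode: str = "human"     # "human" | "mouse_surface" | "mouse_lfp"
    peak_split: float = 15.0     # human Pk1/Pk2 split, Hz
    peak_upper: float = 10.0     # mouse single-peak search ceiling, Hz
    subpeak_FR: float | None = None   # second spectral pass for subpeaks
    burst_band: tuple[float, float] = (2.0, 10.0)
    burst_metric: str = "amplitude"
    burst_seconds: float = 100.0
    ci_level: int = 99
    bootstrap_levels: int = 2
    notch_gap: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)


PROFILES: dict[str, AnalysisProfile] = {
    "human_child": AnalysisProfile(
        name="human_child", variant="linear", f_lo=3.0, f_hi=55.0,
        segment_length=2.0, FR=2.0, interp_bin=0.1, peak_mode="human",
        peak_split=15.0, burst_band=(5.0, 10.0),
        burst_metric="log_squared_amplitude", burst_seconds=90.0,
        ci_level=95, bootstrap_levels=1,
    ),
    "human_adult": AnalysisProfile(
        name="human_adult", variant="linear", f_lo=3.0, f_hi=55.0,
        segment_length=2.0, FR=2.0, interp_bin=None, peak_mode="human",
        peak_split=15.0, burst_band=(7.0, 12.0),
        burst_metric="log_squared_amplitude", burst_seconds=90.0,
        ci_level=95, bootstrap_levels=2,
    ),
    "mouse_surface": AnalysisProfile(
        name="mouse_surface", variant="linear", f_lo=2.0, f_hi=55.0,
        segment_length=5.0, FR=2.0, peak_mode="mouse_surface",
        peak_upper=10.0, burst_band=(3.0, 8.0), burst_seconds=100.0,
        ci_level=99, bootstrap_levels=2,
    ),
    "mouse_lfp": AnalysisProfile(
        name="mouse_lfp", variant="knee", f_lo=1.5, f_hi=175.0,
        segment_length=5.0, FR=2.0, subpeak_FR=1.0, peak_mode="mouse_lfp",
        burst_band=(2.0, 10.0), burst_seconds=100.0,
        ci_level=99, bootstrap_levels=2,
    ),
}


def get_profile(name: str) -> AnalysisProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise InvalidConfigError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None
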