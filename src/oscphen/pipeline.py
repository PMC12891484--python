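"""End-to-end orchestration: conditioning → spectra → aperiodic fit →
peaks (→ PAC, bursts) per subject, then group-level bootstrap statistics.

A single global seed is fanned out to per-stage child seeds by stable
hashing of stage names, so reruns with the same config and seed are
byte-identical (modulo timestamps, which are not written).
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aperiodic import fit_knee, fit_linear, subtract
from .bursts import BurstConfig, burst_detect, extract_analysis_window
from .group_stats import BootstrapConfig, hier_bootstrap_diff
from .io_preprocess import (
    EpochSet,
    InvalidConfigError,
    Recording,
    detrend_mean,
    exclude_artifact_epochs,
    notch_filter,
    read_delimited,
    segment,
)
from .pac import BandGrid, comodulogram
from .periodic_peaks import find_peak_mouse_surface, find_peaks_human, find_subpeaks
from .profiles import AnalysisProfile, get_profile
from .spectral import (
    PowerSpectrum,
    interpolate_psd,
    multitaper_psd,
    taper_params,
    write_spectrum_tsv,
)
from .synthetic import (
    AperiodicParams,
    CohortSpec,
    PacParams,
    PeakParams,
    SimulationConfig,
    gen_cohort,
)

log = logging.getLogger("oscphen")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed."""
    return int(np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())]).generate_state(1)[0])


def epochs_from_recordings(recs: list[Recording], segment_length: float) -> EpochSet:
    """Stack epochs cut from one or more recordings of a single subject."""
    chunks = []
    fs = recs[0].sampling_rate
    for rec in recs:
        if rec.sampling_rate != fs:
            raise InvalidConfigError("mixed sampling rates within one subject")
        chunks.append(segment(rec, segment_length).epochs)
    all_epochs = np.concatenate(chunks, axis=0)
    return EpochSet(all_epochs, fs, segment_length, source_label=recs[0].channel_label)


def analyze_subject(
    recs: list[Recording],
    profile: AnalysisProfile,
    seed: int = 0,
    do_pac: bool = False,
    do_bursts: bool = False,
    notch: tuple[float, float] | None = None,
) -> dict:
    """Full per-subject analysis; returns a serializable ResultRecord."""
    recs = [detrend_mean(r) for r in recs]
    if notch is not None:
        recs = [notch_filter(r, notch[0], notch[1]) for r in recs]

    es = epochs_from_recordings(recs, profile.segment_length)
    es, exclusion = exclude_artifact_epochs(es)

    tp = taper_params(profile.FR, profile.segment_length)
    per_epoch, avg = multitaper_psd(es, tp)
    if profile.interp_bin is not None:
        avg_for_fit = interpolate_psd(avg.band(profile.f_lo, profile.f_hi), profile.interp_bin)
    else:
        avg_for_fit = avg

    if profile.variant == "knee":
        fit = fit_knee(avg_for_fit, f_lo=profile.f_lo, hi_search_max=profile.f_hi,
                       notch_gap=profile.notch_gap)
    else:
        fit = fit_linear(avg_for_fit, f_lo=profile.f_lo, f_hi=profile.f_hi)
    per = subtract(avg_for_fit, fit)

    peaks: dict = {}
    if profile.peak_mode == "human":
        peaks = {k: v.to_dict() for k, v in find_peaks_human(per, profile.peak_split).items()}
    elif profile.peak_mode == "mouse_surface":
        peaks = {"Pk1": find_peak_mouse_surface(per, upper=profile.peak_upper).to_dict()}
    elif profile.peak_mode == "mouse_lfp":
        sub_tp = taper_params(profile.subpeak_FR or 1.0, profile.segment_length)
        _, sub_avg = multitaper_psd(es, sub_tp)
        sub_per = subtract(sub_avg.band(2.0, 10.0), fit)
        found = find_subpeaks(sub_per)
        peaks = {k: (v.to_dict() if hasattr(v, "to_dict") else v) for k, v in found.items()}

    record = {
        "profile": profile.name,
        "software_version": __version__,
        "seed": seed,
        "n_epochs": int(es.n_epochs),
        "n_epochs_included": int(es.included.sum()),
        "exclusion": exclusion,
        "aperiodic_fit": fit.to_dict(),
        "peaks": peaks,
    }

    if do_pac:
        coms = comodulogram(es, BandGrid.default())
        mean_mi = np.mean([c.mi for c in coms], axis=0)
        record["pac"] = {
            "mean_mi": mean_mi.tolist(),
            "max_mi": float(mean_mi.max()),
            "n_epochs": len(coms),
        }

    if do_bursts:
        full = recs[0]
        if full.duration >= profile.burst_seconds:
            window = extract_analysis_window(
                full, profile.burst_seconds, seed=stage_seed(seed, "burst_window")
            )
            bcfg = BurstConfig(
                band=profile.burst_band, metric=profile.burst_metric,
                analysis_seconds=profile.burst_seconds,
            )
            stats = burst_detect(window, bcfg)
            record["bursts"] = stats.to_dict()
        else:
            record["bursts"] = {"skipped": "recording shorter than burst analysis length"}

    return record, avg


def _simulation_config(d: dict) -> SimulationConfig:
    ap = d.get("aperiodic", {})
    peaks = tuple(
        PeakParams(
            center_freq=p["center_freq"],
            bandwidth=p.get("bandwidth", 2.0),
            height=p.get("height", 0.5),
            burst_rate=p.get("burst_rate"),
            burst_mean_duration=p.get("burst_mean_duration", 0.4),
        )
        for p in d.get("peaks", [])
    )
    pac = PacParams(**d["pac"]) if d.get("pac") else None
    return SimulationConfig(
        sampling_rate=d.get("sampling_rate", 1000.0),
        duration=d.get("duration", 5.0),
        aperiodic=AperiodicParams(
            b=ap.get("b", 1.0), m=ap.get("m", -2.0), knee=ap.get("knee", 0.0)
        ),
        peaks=peaks,
        pac=pac,
        seed=d.get("seed", 0),
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every stage from a config mapping; returns the results index.

    The config either names input files (``inputs: {group: {subject:
    [paths]}}``) or a synthetic cohort (``simulate: {...}``); stage toggles
    live under ``stages`` and bootstrap settings under ``bootstrap``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = get_profile(config.get("profile", "mouse_surface"))
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    stages = config.get("stages", {})

    subjects: dict[str, dict[str, list[Recording]]] = {}
    if "simulate" in config:
        sim = config["simulate"]
        base = _simulation_config(sim.get("base", {}))
        spec = CohortSpec(
            n_groups=sim.get("n_groups", 2),
            n_subjects=sim.get("n_subjects", 4),
            n_epochs=sim.get("n_epochs", 8),
            subject_sd=sim.get("subject_sd", 0.0),
            group_effects=tuple(sim.get("group_effects", [])),
            seed=stage_seed(seed, "simulate"),
        )
        cohort = gen_cohort(spec, base)
        subjects = cohort.signals
        (out / "ground_truth.json").write_text(cohort.truth_json())
    elif "inputs" in config:
        for gname, subj_map in config["inputs"].items():
            subjects[gname] = {
                sname: [read_delimited(p) for p in paths]
                for sname, paths in subj_map.items()
            }
    else:
        raise InvalidConfigError("config needs either 'simulate' or 'inputs'")

    notch = None
    if "notch" in config:
        notch = (config["notch"]["center"], config["notch"]["bandwidth"])

    records: dict[str, dict] = {}
    group_spectra: dict[str, dict[str, np.ndarray]] = {}
    freqs = None
    for gname, subj_map in subjects.items():
        group_spectra[gname] = {}
        for sname, recs in subj_map.items():
            record, avg = analyze_subject(
                recs, profile, seed=stage_seed(seed, f"subject:{sname}"),
                do_pac=stages.get("pac", False),
                do_bursts=stages.get("bursts", False),
                notch=notch,
            )
            record["subject"] = sname
            record["group"] = gname
            records[sname] = record
            (out / f"{sname}.json").write_text(json.dumps(record, indent=2))
            write_spectrum_tsv(avg, out / f"{sname}_psd.tsv")
            group_spectra[gname][sname] = avg.log_power[None, :]
            freqs = avg.freqs
            log.info("analyzed %s/%s: %d epochs", gname, sname, record["n_epochs"])

    index: dict = {"profile": profile.name, "seed": seed,
                   "subjects": sorted(records), "groups": sorted(subjects)}

    gnames = sorted(group_spectra)
    if len(gnames) >= 2:
        bcfg_d = config.get("bootstrap", {})
        bcfg = BootstrapConfig(
            n_boot=bcfg_d.get("n_boot", 1000),
            ci_level=bcfg_d.get("ci_level", profile.ci_level),
            levels=1,  # one epoch-averaged spectrum per subject at this stage
            matched=bcfg_d.get("matched", False),
            seed=stage_seed(seed, "bootstrap"),
        )
        res = hier_bootstrap_diff(group_spectra[gnames[0]], group_spectra[gnames[1]], bcfg)
        boot_path = out / f"bootstrap_{gnames[0]}_minus_{gnames[1]}.tsv"
        with boot_path.open("w") as fh:
            fh.write("frequency_hz\tmedian\tlower\tupper\tsignificant\n")
            for f, md, lo, hi, sig in zip(freqs, res.median, res.lower, res.upper, res.significant):
                fh.write(f"{f!r}\t{float(md)!r}\t{float(lo)!r}\t{float(hi)!r}\t{int(sig)}\n")
        index["bootstrap"] = boot_path.name

    (out / "index.json").write_text(json.dumps(index, indent=2))
    return {"records": records, "index": index}
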