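# oscphen

Resting-state EEG/LFP oscillation phenotyping in Python: multitaper spectral
estimation with cross-species time-bandwidth calibration, an anchor-based
Lorentzian decomposition of spectra into aperiodic (1/f, linear or knee) and
periodic components, peak/subpeak quantification, phase-amplitude coupling
(18-bin modulation index, comodulograms, trial-shuffled noise correction),
analytic-envelope burst dynamics with piezo movement alignment, and
non-parametric hierarchical bootstrap group statistics.

A first-class synthetic-data module generates signals and cohorts with known
aperiodic shape, injected bursty peaks, controlled phase-amplitude coupling,
and a group → subject → epoch hierarchy, so every analysis stage can be
validated against ground truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance-level checks (taper
calibration, segmentation counts, band-grid shape, MI identities, aperiodic
parameter recovery, residual non-negativity guarantees, subpeak recovery,
burst definitions, bootstrap calibration).

## Command line

The console script `oscphen` exposes each stage plus an end-to-end runner:

```sh
# full pipeline on a synthetic two-group cohort
oscphen run-all --config examples/demo_config.yaml --seed 1 --out-dir out/

# individual stages
oscphen simulate   --config sim.yaml --seed 3 --out rec.tsv
oscphen preprocess rec.tsv --out clean.tsv --notch-center 60
oscphen psd        clean.tsv --profile mouse_surface --out psd.tsv
oscphen aperiodic  psd.tsv --profile mouse_surface --out fit.json
oscphen peaks      psd.tsv --profile mouse_surface --out peaks.json
oscphen pac        clean.tsv --profile mouse_lfp --out comod.tsv
oscphen bursts     clean.tsv --profile mouse_lfp --seed 1 --out bursts.json
```

Profiles (`human_child`, `human_adult`, `mouse_surface`, `mouse_lfp`) bundle
the per-context constants: fitting edges (3 / 2 / 1.5 Hz), segment lengths
(2 s / 5 s), taper calibration (TW = FR·len/2, K = 2·TW − 1), interpolation,
peak search rules, burst bands, and bootstrap settings.

Recordings are plain text: header lines `# sampling_rate_hz=...`,
`# channel=...`, then one sample per line in µV (optional second column =
piezo trace in mV). A minimal EDF reader (`read_edf`) covers multichannel
input with channel selection by label.

## Package layout

| module | contents |
| --- | --- |
| `oscphen.synthetic` | ground-truth generators (aperiodic series, bursty peaks, PAC, cohorts, piezo) |
| `oscphen.io_preprocess` | Recording/EpochSet types, delimited + EDF I/O, detrend, notch, segmentation, artifact exclusion |
| `oscphen.spectral` | taper calibration, multitaper PSD, spectrum averaging/interpolation |
| `oscphen.aperiodic` | linear and knee Lorentzian fits, evaluation, subtraction |
| `oscphen.periodic_peaks` | Pk1/Pk2, smoothed mouse surface peak, Pk1a/Pk1b subpeaks |
| `oscphen.pac` | band grids, filtered analytic signals, PA distributions, MI, comodulograms |
| `oscphen.bursts` | burst detection, movement bouts, alignment, spectrograms |
| `oscphen.group_stats` | hierarchical bootstrap (1/2-level, matched), noise-subtracted comodulogram bootstrap, Cliff's delta, BH-FDR, r² |
| `oscphen.pipeline` / `oscphen.cli` | orchestration, profiles, config handling, CLI |
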