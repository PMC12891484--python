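# Two-group synthetic cohort analyzed with the mouse surface-EEG profile.
# Group 1 gets a +0.3 log10-power boost of the 6 Hz periodic peak.
profile: mouse_surface
seed: 1
simulate:
  n_groups: 2
  n_subjects: 4
  n_epochs: 8
  subject_sd: 0.02
  group_effects:
    - {}
    - {"peaks.0.height": 0.3}
  base:
    sampling_rate: 250.0
    duration: 5.0
    aperiodic: {b: 1.0, m: -2.0, knee: 0.0}
    peaks:
      - {center_freq: 6.0, height: 0.4, burst_rate: null}
bootstrap:
  n_boot: 1000
  ci_level: 99
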