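# Study-default configuration: 260x280 px at 60 fps cycling four
# wavelengths, 10 s trials (1.5 s baseline / 1.5 s stimulus / 7 s post).
acquisition:
  frame_rate_hz: 60.0
  wavelengths_nm: [470.0, 530.0, 588.0, 627.0]
  frame_shape: [260, 280]
  baseline_s: 1.5
  stimulus_s: 1.5
  post_s: 7.0
  n_trials: 1
  pixel_pitch_um: 20.0
  illumination_counts: [800.0, 1000.0, 900.0, 700.0]
disturbance:
  breathing_hz: 1.2
  breathing_amp: 0.02
  heartbeat_hz: 6.0
  heartbeat_amp: 0.01
  n_harmonics: 2
  harmonic_decay: 0.5
  phase_noise_sd: 0.6
  electrical_noise_sd: 20.0
  drift_rate: 0.0005
  trial_gain_jitter_sd: 0.1
response:
  center_xy: null
  spatial_sigma: 32.5
  delta_hbo_peak: 6.0e-7
  delta_hbr_peak: -2.0e-7
  onset_s: 1.5
  time_to_peak_s: 2.0
  decay_tau_s: 1.2
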