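# Example simulator configuration for `eegssa simulate --config`.
# Values are the package defaults: four Markov-amplitude rhythms,
# EOG pulses, baseline drift and white measurement noise.
fs_hz: 200
duration_s: 8
rhythms:
  - {name: delta, f_hz: 2.50, gamma: 0.99, sigma_xi_uV: 2.26, theta_rad: 0.0}
  - {name: theta, f_hz: 6.00, gamma: 0.97, sigma_xi_uV: 2.78, theta_rad: 0.0}
  - {name: alpha, f_hz: 10.50, gamma: 0.99, sigma_xi_uV: 2.35, theta_rad: 0.0}
  - {name: beta, f_hz: 21.50, gamma: 0.99, sigma_xi_uV: 0.36, theta_rad: 0.0}
artifacts:
  v_eog_uV: 50 # EOG pulse peak
  t_eog_s: 3 # EOG pulse period
  w_eog_s: 0.3 # EOG pulse base width
  v_bd_uV: 10 # baseline-drift amplitude
  f_bd_hz: 0.5 # baseline-drift frequency
noise_power_dbw: 1 # white-noise power, 10*log10(variance / uV^2)
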