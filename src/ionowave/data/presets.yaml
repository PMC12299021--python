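# Experiment presets: scenario geometry/dosimetry, acquisition chain, record layout.
# Units: metres, seconds, hertz, pascal, volts, gray, decibels.
preclinical_20MeV:
  scenario:
    name: preclinical_20MeV
    proton_energy_mev: 20.0
    dose_per_pulse_gy: 0.8
    bp_depth_m: 0.00406
    bp_fwhm_m: 0.00032
    sensor_distance_m: 0.0256
    sound_speed_m_s: 1492.0
    pressure_at_bp_pa: 80.0
    pressure_at_sensor_pa: 5.0
    single_pulse_snr_db: 13.0
    alt_single_pulse_snr_db: 11.0
  chain:
    sensitivity_v_per_pa: 1.0e-05
    gain_db: 80.0
    hp_corner_hz: 10000.0
    lp_corner_hz: 4500000.0
    lp_quality: 0.707
    sampling_rate_hz: 80000000.0
    adc_bits: 10
    adc_vpp: 1.25
    noise_floor_v_rms: 6.24e-06
  acquisition:
    duration_samples: 32768
    trigger_index: 2048

clinical_200MeV:
  scenario:
    name: clinical_200MeV
    proton_energy_mev: 200.0
    dose_per_pulse_gy: 0.035
    bp_depth_m: 0.259
    bp_fwhm_m: 0.0201
    sensor_distance_m: 0.05
    sound_speed_m_s: 1492.0
    # absolute pressures are not printed for this setup; the 20 MeV pair is
    # scaled by the dose ratio 35 mGy / 0.8 Gy (results are scale-invariant)
    pressure_at_bp_pa: 3.5
    pressure_at_sensor_pa: 0.21875
    single_pulse_snr_db: -2.0
  chain:
    sensitivity_v_per_pa: 1.0e-05
    gain_db: 80.0
    hp_corner_hz: 10000.0
    lp_corner_hz: 4500000.0
    lp_quality: 0.707
    sampling_rate_hz: 80000000.0
    adc_bits: 10
    adc_vpp: 1.25
    noise_floor_v_rms: 6.24e-06
  acquisition:
    duration_samples: 16384
    trigger_index: 2048
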