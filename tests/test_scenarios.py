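"""Synthetic-trace generator: physics of the presets, noise calibration,
coherent averaging."""

import math

import numpy as np
import pytest

import ionowave as iw
from ionowave.errors import (
    ConfigurationError,
    InvalidRequestError,
    InvalidScenarioError,
)
from ionowave.metrology import predict_averaged_snr
from ionowave.scenarios import Scenario, tof_samples


class TestCharacteristicFrequency:
    def test_20mev_preset_matches_printed_value(self, preclinical):
        scenario, _, _ = preclinical
        f = iw.characteristic_frequency(scenario)
        assert f == pytest.approx(1492.0 / (2 * 0.32e-3))
        assert round(f / 1e6, 1) == 2.3

    def test_200mev_preset(self, clinical):
        scenario, _, _ = clinical
        assert iw.characteristic_frequency(scenario) == pytest.approx(37.1e3, rel=1e-3)

    def test_wide_bragg_peak_limit(self, preclinical):
        scenario, _, _ = preclinical
        from dataclasses import replace

        wide = replace(scenario, bp_fwhm_m=10.0)
        assert iw.characteristic_frequency(wide) < 100.0

    def test_invalid_fwhm_rejected(self, preclinical):
        scenario, _, _ = preclinical
        with pytest.raises(InvalidScenarioError):
            Scenario(
                name="bad",
                proton_energy_mev=20,
                dose_per_pulse_gy=0.8,
                bp_depth_m=4e-3,
                bp_fwhm_m=-1.0,
                sensor_distance_m=0.02,
            )


class TestCleanTrace:
    def test_peak_amplitude_is_pressure_times_chain_gain(self, preclinical, clean_trace):
        _, chain, _ = preclinical
        # 5 Pa x 10 uV/Pa x 10^(80/20) = 0.5 V at the digitizer
        assert np.max(clean_trace.samples) == pytest.approx(0.5)

    def test_peak_sits_at_time_of_flight_sample(self, preclinical, clean_trace):
        scenario, chain, _ = preclinical
        expected = clean_trace.trigger_index + tof_samples(scenario, chain)
        assert int(np.argmax(np.abs(clean_trace.samples))) == expected
        # 25.6 mm / 1492 m/s = 17.16 us after the trigger
        tof = (expected - clean_trace.trigger_index) / chain.sampling_rate_hz
        assert tof == pytest.approx(17.16e-6, rel=1e-3)

    def test_pre_trigger_samples_exactly_zero(self, clean_trace):
        assert np.all(clean_trace.samples[: clean_trace.trigger_index] == 0.0)

    def test_zero_source_pressure_gives_zero_trace(self, preclinical):
        scenario, chain, acq = preclinical
        from dataclasses import replace

        silent = replace(scenario, pressure_at_sensor_pa=0.0)
        tr = iw.generate_clean_trace(silent, chain, **acq)
        assert np.all(tr.samples == 0.0)

    def test_too_short_record_rejected(self, preclinical):
        scenario, chain, _ = preclinical
        with pytest.raises(ConfigurationError):
            iw.generate_clean_trace(scenario, chain, duration_samples=2048)

    def test_tof_scales_linearly_with_distance(self, preclinical):
        scenario, chain, acq = preclinical
        from dataclasses import replace

        far = replace(scenario, sensor_distance_m=2 * scenario.sensor_distance_m)
        # continuous-time ToF doubles exactly; sample indices round within 1
        assert far.sensor_distance_m / far.sound_speed_m_s == pytest.approx(
            2 * scenario.sensor_distance_m / scenario.sound_speed_m_s, rel=1e-12
        )
        near_peak = tof_samples(scenario, chain)
        far_peak = tof_samples(far, chain)
        assert abs(far_peak - 2 * near_peak) <= 1
        tr = iw.generate_clean_trace(far, chain, **acq)
        assert int(np.argmax(np.abs(tr.samples))) == tr.trigger_index + far_peak


class TestAddNoise:
    def test_same_seed_bit_identical(self, preclinical, clean_trace):
        _, chain, _ = preclinical
        a = iw.add_noise(clean_trace, 13.0, chain, seed=5)
        b = iw.add_noise(clean_trace, 13.0, chain, seed=5)
        assert np.array_equal(a.samples, b.samples)
        c = iw.add_noise(clean_trace, 13.0, chain, seed=6)
        assert not np.array_equal(a.samples, c.samples)

    def test_infinite_snr_is_identity(self, preclinical, clean_trace):
        _, chain, _ = preclinical
        out = iw.add_noise(clean_trace, math.inf, chain, seed=1)
        assert np.array_equal(out.samples, clean_trace.samples)

    def test_zero_amplitude_signal_rejected(self, preclinical, clean_trace):
        _, chain, _ = preclinical
        silent = clean_trace.with_samples(np.zeros(len(clean_trace)))
        with pytest.raises(InvalidRequestError):
            iw.add_noise(silent, 13.0, chain, seed=1)

    def test_mean_measured_snr_near_target(self, preclinical, clean_trace):
        """Measured SNR recovers the 13 dB target in expectation.

        The amplitude term of the SNR definition is a post-trigger maximum, so
        the noise maximum over the record biases the measurement upward by
        ~0.6 dB at this SNR and record length; the noise scaling itself is the
        exact definitional one (sigma = A_0pk / 10^(SNR/20)).
        """
        _, chain, _ = preclinical
        vals = [
            iw.measure_snr(iw.add_noise(clean_trace, 13.0, chain, seed=s)).snr_db
            for s in range(200)
        ]
        assert abs(np.mean(vals) - 13.0) < 0.75

    def test_absolute_noise_mode_uses_chain_floor(self, preclinical, clean_trace):
        _, chain, _ = preclinical
        out = iw.add_noise(clean_trace, None, chain, seed=2)
        sigma = np.std(out.samples[:1024])
        expected = chain.noise_floor_v_rms * chain.gain_linear
        assert sigma == pytest.approx(expected, rel=0.15)


class TestCoherentAverage:
    def test_average_of_identical_clean_traces_is_identity(self, clean_trace):
        out = iw.coherent_average([clean_trace] * 5)
        assert np.allclose(out.samples, clean_trace.samples)

    def test_empty_and_mismatched_inputs_rejected(self, preclinical, clean_trace):
        scenario, chain, _ = preclinical
        with pytest.raises(InvalidRequestError):
            iw.coherent_average([])
        other = iw.generate_clean_trace(
            scenario, chain, duration_samples=2**14, trigger_index=2048
        )
        with pytest.raises(InvalidRequestError):
            iw.coherent_average([clean_trace, other])

    @pytest.mark.parametrize("n_pulses", [4, 16, 64])
    def test_averaged_snr_follows_10log10_law(self, preclinical, clean_trace, n_pulses):
        """Measured SNR of an N-fold average matches SNR_1p + 10 log10 N."""
        _, chain, _ = preclinical
        reps = 200 // n_pulses + 10
        vals = []
        for rep in range(reps):
            traces = [
                iw.add_noise(clean_trace, 13.0, chain, seed=900_000 + rep * n_pulses + k)
                for k in range(n_pulses)
            ]
            vals.append(iw.measure_snr(iw.coherent_average(traces)).snr_db)
        assert abs(np.mean(vals) - predict_averaged_snr(13.0, n_pulses)) < 0.5

    def test_80_fold_average_at_11db_reaches_30db(self, preclinical, clean_trace):
        _, chain, _ = preclinical
        vals = []
        for rep in range(6):
            traces = [
                iw.add_noise(clean_trace, 11.0, chain, seed=500_000 + rep * 80 + k)
                for k in range(80)
            ]
            vals.append(iw.measure_snr(iw.coherent_average(traces)).snr_db)
        assert np.mean(vals) == pytest.approx(30.0, abs=1.0)


class TestPresets:
    def test_preset_names(self):
        assert set(iw.preset_names()) == {"preclinical_20MeV", "clinical_200MeV"}

    def test_preclinical_values(self, preclinical):
        scenario, chain, acq = preclinical
        assert scenario.bp_fwhm_m == 0.32e-3
        assert scenario.bp_depth_m == 4.06e-3
        assert scenario.sensor_distance_m == 25.6e-3
        assert scenario.sound_speed_m_s == 1492.0
        assert scenario.pressure_at_bp_pa == 80.0
        assert scenario.pressure_at_sensor_pa == 5.0
        assert scenario.dose_per_pulse_gy == 0.8
        assert (scenario.single_pulse_snr_db, scenario.alt_single_pulse_snr_db) == (13.0, 11.0)
        assert chain.sampling_rate_hz == 80e6
        assert chain.adc_bits == 10
        assert acq["trigger_index"] >= 1024

    def test_clinical_values(self, clinical):
        scenario, _, _ = clinical
        assert scenario.bp_depth_m == 0.259
        assert scenario.bp_fwhm_m == 20.1e-3
        assert scenario.sensor_distance_m == 0.05
        assert scenario.dose_per_pulse_gy == 0.035
        assert scenario.single_pulse_snr_db == -2.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidRequestError):
            iw.load_preset("nope")
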