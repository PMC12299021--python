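# ionowave

Ionoacoustic (protoacoustic) range verification for proton therapy, as a
testable Python pipeline: synthetic Bragg-peak acoustic pulses with a
realistic sensor/electronics chain, single-trace wavelet denoising, and the
metrology that turns traces into numbers — SNR, time-of-flight Bragg-peak
localization, Monte-Carlo range precision, and the dose cost of coherent
averaging.

A pulsed proton beam deposits its dose in a sharp Bragg peak (BP); the rapid
heating emits an ultrasound pulse whose time of flight (ToF) to a sensor
localizes the BP: `distance = ToF × c`. The signal-to-noise ratio of a single
pulse is poor (13 dB in a 20 MeV water-phantom setup, −2 dB for a 200 MeV
clinical beam), and the classical fix — averaging N beam pulses, with
`SNR_avg = SNR_1p + 10·log10(N)` — multiplies the patient dose by N. The
package implements the alternative: a Mallat fast wavelet transform (sym6,
14 levels), a level-dependent MAD noise estimate, and empirical-Bayes
shrinkage under a sparse quasi-Cauchy prior, where each detail coefficient
`x ~ N(theta, sigma²)`, `theta ~ w·gamma + (1−w)·delta_0`, is replaced by the
posterior median of `theta | x` — a thresholding rule with bounded shrinkage,
with per-level weights `w` fitted by marginal maximum likelihood.

Intended users: physicists and engineers studying denoising/ToF algorithms
for ionoacoustic detectors who need a controlled, reproducible synthetic
test bench; the I/O module also ingests externally recorded traces.

## Worked example

```python
import ionowave as iw

scenario, chain, acq = iw.preclinical_20mev()
clean = iw.generate_clean_trace(scenario, chain, **acq)
tof = iw.measure_tof(clean, scenario.sound_speed_m_s)
noisy = iw.add_noise(clean, scenario.single_pulse_snr_db, chain, seed=1)
denoised = iw.denoise(noisy)
print(iw.characteristic_frequency(scenario) / 1e6)   # MHz
print(tof.tof_s * 1e6, tof.bp_position_m * 1e3)      # us, mm
print(iw.measure_snr(noisy).snr_db, iw.measure_snr(denoised).snr_db)
```

Running `python examples/01_simulate_and_denoise.py` (the same computation)
prints:

```
characteristic frequency: 2.33 MHz
time of flight: 17.16 us -> BP-sensor distance 25.61 mm (preset: 25.6 mm)
SNR in:    13.2 dB  (single pulse, 0.8 Gy)
SNR out:  130.5 dB  (after wavelet denoising, no extra dose)
```

Meaning: the 0.32 mm Bragg peak in water implies a 2.33 MHz acoustic pulse;
its peak arrives 17.16 µs after the beam trigger, recovering the 25.6 mm
sensor distance to one sample (18.7 µm); the denoiser lifts a 13 dB
single-pulse trace far above the 30 dB that 80-fold averaging (64 Gy instead
of 0.8 Gy) would buy. On ideal synthetic noise the post-denoising noise floor
in the pre-trigger window nearly vanishes, so the measured output SNR is much
higher — and more seed-variable — than on real acquisitions; see
`docs/methods.md` for what the synthetic conditions do and do not show.

The other examples characterize the denoiser's SNR transfer curve
(`02_snr_transfer_curve.py`), range precision vs SNR for averaging vs
denoising (`03_precision_vs_snr.py`), and the clinical 200 MeV dose/precision
trade-off (`04_clinical_dose_study.py`).

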