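# Methods

## The problem

A pulsed proton beam stopping in water (or tissue) deposits most of its dose
in the Bragg peak (BP). The fast local heating launches a thermoacoustic
pressure pulse; a piezoelectric sensor records it, and the time of flight
(ToF) from the beam trigger to the acoustic peak times the speed of sound
gives the BP–sensor distance. The per-pulse dose is small, so the raw trace is
noisy; the classical remedy — coherently averaging N beam pulses, which gains
`10·log10(N)` dB of SNR — costs an N-fold dose to the patient. This package
quantifies how much of that dose a single-trace wavelet denoiser can save, on
fully synthetic but physically parameterized data.

## Synthetic signal model

`Scenario` + `AcquisitionChain` define the study conditions; two presets ship:

| quantity | pre-clinical 20 MeV | clinical 200 MeV |
|---|---|---|
| BP depth | 4.06 mm | 25.9 cm |
| BP FWHM | 0.32 mm | 20.1 mm |
| dose/pulse at BP | 0.8 Gy | 35 mGy |
| sensor distance | 25.6 mm | 5 cm |
| pressure at BP / sensor | 80 / 5 Pa | 3.5 / 0.219 Pa |
| single-pulse SNR | 13 dB (11 dB alt.) | −2 dB |

Both use the same front end: 10 µV/Pa sensitivity, 80 dB gain, first-order
high-pass at 10 kHz × second-order low-pass at 4.5 MHz (Q = 0.707), 10-bit
ADC at 80 MS/s. Clinical absolute pressures are not published; they are the
20 MeV values scaled by the dose ratio, and every reported result (SNR,
precision) is invariant to that absolute scale.

The acoustic pulse is a Gaussian-enveloped cosine burst: carrier at the
characteristic frequency `f_c = c/(2·FWHM)` (2.33 MHz pre-clinical, 37.1 kHz
clinical), envelope `sigma_t = FWHM/(2.355·c)` (the BP's own Gaussian sigma in
time units). This reproduces the printed 2.3 MHz for the 20 MeV setup and
places the pulse's unique global maximum exactly at the ToF sample, so peak
detection on a clean trace recovers the sensor distance to one sample
(18.7 µm at 80 MS/s). An antisymmetric derivative-of-Gaussian pulse was
considered and rejected: its two extrema tie in magnitude at ±sigma from
center, which makes sample-level peak ToF ill-defined on clean data. Samples
before the trigger are exactly zero (the electromagnetic interference burst at
t = 0 reported for real accelerators is deliberately not simulated; it does
not overlap the acoustic arrival).

Noise is zero-mean Gaussian, spectrally shaped by the chain's band-pass
(applied circularly in the frequency domain, so it is stationary with no
filter warm-up), and scaled definitionally: `sigma_n = A_0pk / 10^(SNR/20)`
with `A_0pk` the clean trace's 0-to-peak amplitude. The definitional scale is
what keeps the averaging law exact (measured SNR of an N-fold average matches
`SNR_1p + 10·log10 N` within 0.2 dB in the tests). A consequence worth
knowing: the *measured* SNR of one noisy trace uses the post-trigger maximum,
and the noise maximum over a 2^15 record biases it upward by ≈ +0.6 dB at
13 dB, saturating near 12 dB as the target SNR drops (a long-record
max-statistic effect, not a calibration error). ADC quantization is off by
default (at 10 bits the analog noise floor dominates); a flag enables it.
Record geometry: 2^15 samples pre-clinical, 2^14 clinical, trigger at sample
2048 so the 1024-sample pre-trigger noise window has margin.

## The denoiser

Mallat fast wavelet transform, sym6 family, 14 levels, periodic boundary
(orthonormal: perfect reconstruction and Parseval hold to 1e−10 relative;
symmetric extension is available but not orthonormal). Level n covers the
dyadic band `[f_N/2^n, f_N/2^(n−1)]`, `f_N` = 40 MHz. Per detail level:

1. noise scale `sigma_n = median(|c|)/0.6745` (MAD, level-dependent);
2. mixing weight `w` of the sparse prior `w·gamma + (1−w)·delta_0`
   (`gamma` = quasi-Cauchy, marginal `g(x) = (2pi)^{-1/2} x^{-2}(1−e^{−x²/2})`)
   fitted by marginal maximum likelihood, bounded on `[1e−4, 1−1e−4]`
   (end points excluded so no level degenerates to all-pass/all-zero),
   scalar search tolerance 1e−6;
3. every coefficient replaced by the posterior median of the true coefficient
   — a genuine threshold (exactly zero below a w-dependent cut) with bounded
   shrinkage for large inputs. The closed-form root equation is bisected
   vectorized (60 halvings); above 25 sigma the asymptote `x − 2·sigma²/x` is
   used. The tests pin the rule against an independent quadrature+bisection
   oracle of the posterior CDF (agreement ≈ 1e−11 sigma).

Approximation coefficients are never shrunk. Levels with fewer than 8
coefficients (or zero MAD) reuse the nearest finer valid level's scale and
weight. An optional hard-threshold mode zeroes below the same w-dependent
threshold and keeps survivors untouched; it is provided for comparison, not
claimed to match any published variant. A note on the weight: with strong
planted signals the marginal-ML weight saturates towards 1 rather than
tracking the signal fraction — that is the correct likelihood behavior, and
per-level weights on realistic traces stay small because signal coefficients
are sparse.

## Measurement definitions

* SNR (dB) = `20·log10(max |x[t ≥ trigger]| / std(x over the 1024 samples
  before the trigger))`; zero noise reports +inf.
* ToF = first index of maximum absolute post-trigger value (no sub-sample
  interpolation; ties break to the first index), minus the trigger, over the
  sampling rate; position = ToF × c.
* Precision = standard deviation of the measured position over a Monte-Carlo
  of fresh-noise repetitions (per-repetition seeds are `seed + r·n_avg + k`,
  so runs are bit-reproducible and two pipelines with one seed share noise).
  The noise-free limit returns exactly zero.
* The precision Monte-Carlo gates the peak search to the nominal arrival
  ± 3 envelope sigmas. Without a gate, a 13 dB trace has an O(1%) per-trace
  chance that some noise excursion in the ~30 000-sample post-trigger region
  beats the true peak, which would make the position SD arbitrarily large —
  no practical ToF analysis searches the whole record. `measure_tof` itself
  keeps the ungated default.

## What the study conditions do and do not show

The suite reproduces exactly: the averaging-law and dose arithmetic (80 pulses
from 11 dB → 30 dB and 64 Gy; 200 pulses from −2 dB → 21 dB and 7 Gy;
1770 → 61.95 Gy), the 2.33 MHz characteristic frequency, and the 17.16 µs ToF
(25.6 mm at 1492 m/s).

Stochastic observables land in the right regime but not inside the published
error-free bands, and they are reported as measured:

* Denoised single-pulse SNR at 13 dB input: median ≈ 41–46 dB (gain ≈ 28–32
  dB) versus the published 30 dB (17 dB gain). On an ideal Gaussian-noise
  synthetic trace the shrinkage empties the pre-trigger window almost
  completely, so the measured output SNR is bounded only by the few noise
  coefficients that leak past the threshold; real acquisitions carry
  correlated residuals and acquisition artifacts that floor the output near
  30 dB. For the same reason the synthetic transfer curve does not show the
  published net SNR *loss* below 10 dB input: a lone clean pulse is still
  sparse enough to survive.
* Single-pulse range precision: ≈ 33 µm at 13 dB and ≈ 22 µm at 15 dB versus
  the published 21 / 11 µm — same order, factor ≈ 1.6–2 worse, with the
  published monotone shape (12.6 µm at 20 dB, 8.6 µm at 24 dB). The excess
  comes from multi-sample argmax excursions under broadband noise; the real
  sensor's 2.45–4.95 MHz passband reshapes (sharpens) the physical pulse in a
  way the parametric far-field model does not emulate.
* Clinical 500-pulse point: averaging-only ≈ 0.8 mm versus the published
  180 µm, and a 3.5–5-fold precision gain from the denoiser versus the
  published 6-fold. As predicted before any clinical run: a 37 kHz pulse
  observed against 4 MHz-wide front-end noise has a peak plateau much wider
  than the noise correlation time, so its argmax wanders over the plateau.
  The published pipeline's effective noise bandwidth (k-Wave plus a Matlab
  noise model) is not published; the preset deliberately keeps the documented
  80 MS/s chain rather than inventing a band-matched one. Both branches
  inflate together, which is why the precision *ratio* lands near the
  published value while both absolute precisions are ≈ 5× larger. The
  clinical extrapolation of dose-to-target for pure averaging is reported
  from a power-law fit of precision vs N and is shallow (N^−0.2 in the
  plateau regime) — read it as a diagnostic, not a clinical claim.

## Numerical/edge choices

All-zero traces denoise to all-zero (zero MAD ⇒ pass-through). Exact SNR
targets of +inf bypass noise generation. `pulses_for_target_snr` subtracts
1e−9 before the ceiling so exact decibel round-trips invert to the original
count. Degenerate weight/scale arguments raise typed errors
(`InvalidRequestError`, `DecompositionError`, ...). Monte-Carlo problem sizes
default to 100 seeds (SNR transfer), 1000 repetitions (pre-clinical
precision) and 300 (clinical, 500-fold averaging), chosen as desk-scale
sizes with Monte-Carlo standard errors well inside the tolerances quoted
above; all counts are parameters.

## Known limitations

No particle transport or full wave propagation (the 3-D dose map and k-space
simulation behind the clinical scenario are replaced by the parametric pulse);
no tissue heterogeneity, sensor directivity, or sensor-passband filtering of
the signal; no translation-invariant (cycle-spinning) transform; no wavelet
family/threshold optimization study. The synthetic noise is Gaussian and
stationary — conclusions about absolute denoiser output SNR on real hardware
should rest on recorded traces, which the I/O module ingests.
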