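"""Physical scenarios, acquisition chains, and synthetic ionoacoustic traces.

A :class:`Scenario` describes the beam/absorber/sensor geometry and dosimetry of
one ionoacoustic experiment (e.g. a 20 MeV pre-clinical water-phantom setup or a
200 MeV clinical one).  An :class:`AcquisitionChain` describes the piezoelectric
sensor plus analog front-end (LNA gain, band-pass, ADC) that turns pressure at
the sensor into a digitized voltage trace.  The generator functions below turn a
(scenario, chain) pair into clean and noisy :class:`SignalTrace` objects with a
controlled signal-to-noise ratio, which the rest of the package denoises and
measures.

The acoustic pulse is modeled as a Gaussian-enveloped cosine burst in the far
field: the Bragg peak acts as a thermoacoustic source whose axial extent
(BP FWHM) sets both the envelope duration, ``sigma = FWHM / (2.355 c)``, and the
characteristic frequency ``f_c = c / (2 FWHM)``.  For the 20 MeV preset this
reproduces the 2.3 MHz dominant frequency implied by a 0.32 mm Bragg peak in
water.  The pulse's unique global maximum lies exactly at the time-of-flight
sample ``trigger + round(distance / c * fs)``, so a peak detector on the clean
trace recovers the Bragg-peak--sensor distance to one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidRequestError, InvalidScenarioError

__all__ = [
    "Scenario",
    "AcquisitionChain",
    "SignalTrace",
    "characteristic_frequency",
    "envelope_sigma",
    "generate_clean_trace",
    "add_noise",
    "coherent_average",
    "preclinical_20mev",
    "clinical_200mev",
    "load_preset",
    "preset_names",
]

#: FWHM of a Gaussian in units of its standard deviation, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class Scenario:
    """Beam/absorber/sensor geometry and dosimetry for one experiment preset.

    Lengths in metres, pressures in pascal, dose in gray.  ``single_pulse_snr_db``
    is the nominal single-pulse SNR the experiment reports for this setup (the
    20 MeV setup quotes both 13 dB and, for one displayed trace, 11 dB; the
    latter is kept in ``alt_single_pulse_snr_db``).
    """

    name: str
    proton_energy_mev: float
    dose_per_pulse_gy: float
    bp_depth_m: float
    bp_fwhm_m: float
    sensor_distance_m: float
    sound_speed_m_s: float = 1492.0
    pressure_at_bp_pa: float = 80.0
    pressure_at_sensor_pa: float = 5.0
    single_pulse_snr_db: float | None = None
    alt_single_pulse_snr_db: float | None = None

    def __post_init__(self) -> None:
        for fname in ("bp_depth_m", "bp_fwhm_m", "sensor_distance_m"):
            if getattr(self, fname) <= 0:
                raise InvalidScenarioError(f"{fname} must be > 0")
        if self.dose_per_pulse_gy <= 0:
            raise InvalidScenarioError("dose_per_pulse_gy must be > 0")
        if self.pressure_at_sensor_pa > self.pressure_at_bp_pa:
            raise InvalidScenarioError(
                "pressure at the sensor cannot exceed pressure at the Bragg peak"
            )
        if not (1400.0 <= self.sound_speed_m_s <= 1600.0):
            raise InvalidScenarioError(
                "sound_speed_m_s outside the water range [1400, 1600]"
            )


@dataclass(frozen=True)
class AcquisitionChain:
    """Sensor + analog front-end + ADC parameters.

    ``noise_floor_v_rms`` is the input-referred (pre-gain) RMS voltage noise of
    sensor plus LNA; it is used when noise is added in absolute mode rather than
    to a target SNR.  The band-pass is a first-order high-pass at ``hp_corner_hz``
    (LNA AC coupling) times a second-order low-pass at ``lp_corner_hz`` with
    quality factor ``lp_quality`` (anti-aliasing filter).
    """

    sensitivity_v_per_pa: float = 10e-6
    gain_db: float = 80.0
    hp_corner_hz: float = 10e3
    lp_corner_hz: float = 4.5e6
    lp_quality: float = 0.707
    sampling_rate_hz: float = 80e6
    adc_bits: int = 10
    adc_vpp: float = 1.25
    noise_floor_v_rms: float = 6.24e-6

    def __post_init__(self) -> None:
        if self.sensitivity_v_per_pa <= 0:
            raise InvalidScenarioError("sensitivity must be > 0")
        if self.adc_bits < 1:
            raise InvalidScenarioError("adc_bits must be >= 1")
        if not (0 < self.hp_corner_hz < self.lp_corner_hz < self.sampling_rate_hz / 2):
            raise InvalidScenarioError(
                "need 0 < hp_corner < lp_corner < sampling_rate/2"
            )

    @property
    def gain_linear(self) -> float:
        return 10.0 ** (self.gain_db / 20.0)


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled voltage trace with a beam-trigger index (t = 0).

    The record length must be a power of two so that deep dyadic wavelet
    decompositions are well-posed.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    trigger_index: int
    units: str = "V"
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        n = samples.size
        if n < 2 or (n & (n - 1)) != 0:
            raise ConfigurationError(f"trace length {n} is not a power of two")
        if not (0 <= self.trigger_index < n):
            raise ConfigurationError("trigger_index outside the record")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times_s(self) -> np.ndarray:
        """Time axis in seconds relative to the beam trigger."""
        n = self.samples.size
        return (np.arange(n) - self.trigger_index) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "SignalTrace":
        return replace(self, samples=samples, label=self.label if label is None else label)


def characteristic_frequency(scenario: Scenario) -> float:
    """Dominant acoustic frequency implied by the Bragg-peak width, in Hz.

    ``f_c = c / (2 * BP_FWHM)``: half an acoustic wavelength spans the emitting
    region.  For the 20 MeV water preset (c = 1492 m/s, FWHM = 0.32 mm) this is
    2.33 MHz.
    """
    if scenario.bp_fwhm_m <= 0:
        raise InvalidScenarioError("bp_fwhm_m must be > 0")
    return scenario.sound_speed_m_s / (2.0 * scenario.bp_fwhm_m)


def envelope_sigma(scenario: Scenario) -> float:
    """Temporal standard deviation of the pulse envelope, in seconds.

    The Bragg peak's Gaussian axial profile (FWHM = 2.355 sigma) swept past the
    sensor at the speed of sound gives ``sigma_t = FWHM / (2.355 c)``.
    """
    return scenario.bp_fwhm_m / (FWHM_PER_SIGMA * scenario.sound_speed_m_s)


def tof_samples(scenario: Scenario, chain: AcquisitionChain) -> int:
    """Nominal time of flight in (rounded) samples."""
    return int(
        round(
            scenario.sensor_distance_m
            / scenario.sound_speed_m_s
            * chain.sampling_rate_hz
        )
    )


def generate_clean_trace(
    scenario: Scenario,
    chain: AcquisitionChain,
    duration_samples: int = 2**15,
    trigger_index: int = 2048,
) -> SignalTrace:
    """Noise-free digitized trace of a single ionoacoustic pulse.

    The sensor-referred pressure pulse (0-to-peak amplitude
    ``scenario.pressure_at_sensor_pa``) is converted to volts at the digitizer
    through the chain's sensitivity and gain.  Samples before the trigger are
    exactly zero.
    """
    n = int(duration_samples)
    if n < 2 or (n & (n - 1)) != 0:
        raise ConfigurationError("duration_samples must be a power of two")
    fs = chain.sampling_rate_hz
    peak_index = trigger_index + tof_samples(scenario, chain)
    sigma_t = envelope_sigma(scenario)
    tail = int(math.ceil(4.0 * sigma_t * fs))
    if peak_index + tail >= n:
        raise ConfigurationError(
            f"record of {n} samples does not cover trigger + ToF + pulse support "
            f"({peak_index + tail} samples needed)"
        )
    t = (np.arange(n) - peak_index) / fs
    f_c = characteristic_frequency(scenario)
    pressure = (
        scenario.pressure_at_sensor_pa
        * np.cos(2.0 * math.pi * f_c * t)
        * np.exp(-0.5 * (t / sigma_t) ** 2)
    )
    volts = pressure * chain.sensitivity_v_per_pa * chain.gain_linear
    volts[:trigger_index] = 0.0
    return SignalTrace(
        samples=volts,
        sampling_rate_hz=fs,
        trigger_index=trigger_index,
        label=f"{scenario.name} clean",
    )


@lru_cache(maxsize=32)
def _band_shape(chain: AcquisitionChain, n: int, fs: float):
    """One-sided |H(f)| of the analog band-pass on the rFFT grid, plus the RMS
    gain applied to unit-variance white noise (used for deterministic scaling)."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    x_hp = f / chain.hp_corner_hz
    h_hp = x_hp / np.sqrt(1.0 + x_hp**2)
    x_lp = f / chain.lp_corner_hz
    h_lp = 1.0 / np.sqrt((1.0 - x_lp**2) ** 2 + (x_lp / chain.lp_quality) ** 2)
    h = h_hp * h_lp
    # variance of irfft(rfft(white) * h): two-sided mean of |H|^2
    h2 = h**2
    if n % 2 == 0:
        total = h2[0] + h2[-1] + 2.0 * h2[1:-1].sum()
    else:
        total = h2[0] + 2.0 * h2[1:].sum()
    sigma_unit = math.sqrt(total / n)
    return h, sigma_unit


def band_limited_noise(
    chain: AcquisitionChain, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise shaped by the chain's band-pass (stationary,
    circularly filtered so there is no filter warm-up transient)."""
    h, sigma_unit = _band_shape(chain, n, chain.sampling_rate_hz)
    white = rng.standard_normal(n)
    shaped = np.fft.irfft(np.fft.rfft(white) * h, n)
    return shaped / sigma_unit


def quantize(samples: np.ndarray, chain: AcquisitionChain) -> np.ndarray:
    """Mid-tread ADC quantization to ``adc_bits`` levels over ``adc_vpp``."""
    lsb = chain.adc_vpp / 2**chain.adc_bits
    half = chain.adc_vpp / 2.0
    return np.clip(np.round(samples / lsb) * lsb, -half, half - lsb)


def add_noise(
    trace: SignalTrace,
    target_snr_db: float | None,
    chain: AcquisitionChain,
    seed: int,
    apply_adc: bool = False,
) -> SignalTrace:
    """Add band-limited Gaussian sensor/electronics noise to a trace.

    With a finite ``target_snr_db`` the noise RMS is set so that the SNR
    definition used throughout (0-to-peak post-trigger amplitude over the RMS of
    the pre-trigger noise window) recovers the target in expectation:
    ``sigma_n = A_0pk / 10^(SNR/20)``.  With ``target_snr_db=None`` the chain's
    input-referred noise floor times the gain is used instead (absolute mode).
    ``target_snr_db=inf`` returns the input unchanged.  Reproducible: the same
    seed yields a bit-identical result.
    """
    x = trace.samples
    if target_snr_db is not None and math.isinf(target_snr_db) and target_snr_db > 0:
        out = x.copy()
        if apply_adc:
            out = quantize(out, chain)
        return trace.with_samples(out)
    if target_snr_db is None:
        sigma_n = chain.noise_floor_v_rms * chain.gain_linear
    else:
        amplitude = float(np.max(np.abs(x[trace.trigger_index:])))
        if amplitude == 0.0:
            raise InvalidRequestError(
                "cannot target a finite SNR on a zero-amplitude signal"
            )
        sigma_n = amplitude / 10.0 ** (target_snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noise = band_limited_noise(chain, x.size, rng) * sigma_n
    out = x + noise
    if apply_adc:
        out = quantize(out, chain)
    return trace.with_samples(out, label=f"{trace.label} + noise".strip())


def coherent_average(traces: Sequence[SignalTrace]) -> SignalTrace:
    """Sample-wise mean of trigger-aligned acquisitions.

    Averaging ``N`` independent-noise realizations improves the SNR by
    ``10 log10 N`` dB (at the cost of an N-fold dose in a real experiment).
    """
    if len(traces) == 0:
        raise InvalidRequestError("cannot average an empty list of traces")
    first = traces[0]
    for t in traces[1:]:
        if (
            len(t) != len(first)
            or t.sampling_rate_hz != first.sampling_rate_hz
            or t.trigger_index != first.trigger_index
        ):
            raise InvalidRequestError("traces disagree in length, rate, or trigger")
    mean = np.mean(np.vstack([t.samples for t in traces]), axis=0)
    return first.with_samples(mean, label=f"{len(traces)}-fold average")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _load_preset_file() -> dict:
    import yaml
    from importlib import resources

    text = resources.files("ionowave").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=1)
def _presets() -> dict:
    return _load_preset_file()


def preset_names() -> list[str]:
    return sorted(_presets().keys())


def load_preset(name: str) -> tuple[Scenario, AcquisitionChain, dict]:
    """Load a named preset -> (scenario, chain, acquisition dict).

    The acquisition dict carries the default record geometry
    (``duration_samples``, ``trigger_index``).
    """
    presets = _presets()
    if name not in presets:
        raise InvalidRequestError(
            f"unknown preset {name!r}; available: {preset_names()}"
        )
    entry = presets[name]
    scenario = Scenario(**entry["scenario"])
    chain = AcquisitionChain(**entry["chain"])
    return scenario, chain, dict(entry["acquisition"])


def preclinical_20mev() -> tuple[Scenario, AcquisitionChain, dict]:
    """The 20 MeV water-phantom preset (Bragg peak at 4.06 mm, sensor 25.6 mm)."""
    return load_preset("preclinical_20MeV")


def clinical_200mev() -> tuple[Scenario, AcquisitionChain, dict]:
    """The 200 MeV clinical preset (range 25.9 cm, sensor 5 cm from the BP)."""
    return load_preset("clinical_200MeV")
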