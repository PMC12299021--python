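"""Wavelet-transform denoising: sym6 multilevel decomposition + empirical-Bayes
per-level shrinkage.

The chain is the classical Mallat fast wavelet transform (orthonormal with
periodic boundary handling), a level-dependent MAD noise estimate, a
marginal-ML mixing weight per level, and quasi-Cauchy posterior-median
shrinkage of the detail coefficients (:mod:`ionowave.ebayes`).  Approximation
coefficients are never shrunk.  Level ``n`` of the decomposition covers the
dyadic band ``[f_N / 2^n, f_N / 2^(n-1)]`` where ``f_N`` is the Nyquist
frequency (40 MHz at the 80 MS/s chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from . import ebayes
from .errors import DecompositionError, InvalidRequestError
from .scenarios import SignalTrace

__all__ = [
    "WaveletSpec",
    "WaveletDecomposition",
    "fwt",
    "ifwt",
    "estimate_level_noise",
    "estimate_level_weight",
    "cauchy_posterior_median",
    "denoise",
]

#: levels with fewer coefficients than this reuse the nearest valid level's
#: noise scale and weight (MAD and marginal ML are meaningless on a handful
#: of points)
MIN_LEVEL_SIZE = 8


@dataclass(frozen=True)
class WaveletSpec:
    """Configuration of the denoising transform."""

    family: str = "sym6"
    n_levels: int = 14
    threshold_rule: str = "ebayes_cauchy_median"  # or "hard"
    noise_estimate: str = "level_dependent_mad"
    boundary: str = "periodization"  # or "symmetric"

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise DecompositionError("n_levels must be >= 1")
        if self.threshold_rule not in ("ebayes_cauchy_median", "hard"):
            raise InvalidRequestError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.noise_estimate != "level_dependent_mad":
            raise InvalidRequestError(f"unknown noise estimate {self.noise_estimate!r}")
        try:
            wav = pywt.Wavelet(self.family)
        except ValueError as exc:
            raise DecompositionError(f"unknown wavelet family {self.family!r}") from exc
        if not wav.orthogonal:
            raise DecompositionError(f"{self.family!r} is not an orthonormal family")

    @property
    def wavelet(self) -> "pywt.Wavelet":
        return pywt.Wavelet(self.family)


@dataclass
class WaveletDecomposition:
    """Multilevel decomposition of a trace.

    ``details[n-1]`` holds level ``n`` (level 1 = finest, band near
    ``[f_N/2, f_N]``).  ``sigma_per_level`` / ``weight_per_level`` are filled by
    :func:`denoise` (noise scale and mixing weight actually applied per level).
    """

    approximation: np.ndarray
    details: list  # finest first
    sampling_rate_hz: float
    length: int
    spec: WaveletSpec
    sigma_per_level: np.ndarray | None = None
    weight_per_level: np.ndarray | None = None

    @property
    def nyquist_hz(self) -> float:
        return self.sampling_rate_hz / 2.0

    def band_edges(self, level: int) -> tuple[float, float]:
        """(low, high) frequency edges of the given detail level in Hz."""
        f_n = self.nyquist_hz
        return f_n / 2.0**level, f_n / 2.0 ** (level - 1)

    def coefficient_count(self) -> int:
        return self.approximation.size + sum(d.size for d in self.details)

    def to_table(self) -> pd.DataFrame:
        """Per-level diagnostic table (band edges, sizes, sigma, weight)."""
        rows = []
        for i, d in enumerate(self.details):
            lo, hi = self.band_edges(i + 1)
            rows.append(
                {
                    "level": i + 1,
                    "band_low_hz": lo,
                    "band_high_hz": hi,
                    "n_coeffs": d.size,
                    "sigma": None
                    if self.sigma_per_level is None
                    else float(self.sigma_per_level[i]),
                    "weight": None
                    if self.weight_per_level is None
                    else float(self.weight_per_level[i]),
                }
            )
        return pd.DataFrame(rows)


def fwt(trace: SignalTrace, spec: WaveletSpec = WaveletSpec()) -> WaveletDecomposition:
    """Fast wavelet transform of a trace into ``spec.n_levels`` detail levels.

    With periodic boundary handling the transform is orthonormal: coefficient
    counts add up to the input length, energy is conserved (Parseval), and
    :func:`ifwt` inverts it to machine precision.
    """
    x = trace.samples
    if 2**spec.n_levels > x.size:
        raise DecompositionError(
            f"{spec.n_levels} levels need at least 2^{spec.n_levels} samples, "
            f"got {x.size}"
        )
    with warnings.catch_warnings():
        # deep decompositions are intentional here; periodization handles them
        warnings.filterwarnings("ignore", message="Level value .* is too high")
        coeffs = pywt.wavedec(x, spec.wavelet, mode=spec.boundary, level=spec.n_levels)
    approximation, details_deep_first = coeffs[0], coeffs[1:]
    return WaveletDecomposition(
        approximation=approximation,
        details=list(reversed(details_deep_first)),
        sampling_rate_hz=trace.sampling_rate_hz,
        length=x.size,
        spec=spec,
    )


def ifwt(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse fast wavelet transform back to sample space."""
    coeffs = [dec.approximation] + list(reversed(dec.details))
    x = pywt.waverec(coeffs, dec.spec.wavelet, mode=dec.spec.boundary)
    return x[: dec.length]


def estimate_level_noise(detail_coeffs: np.ndarray) -> float:
    """Level-dependent noise scale: ``median(|c|) / 0.6745``."""
    return ebayes.mad_sigma(detail_coeffs)


def estimate_level_weight(detail_coeffs: np.ndarray, sigma: float) -> float:
    """Marginal-ML mixing weight of the sparse quasi-Cauchy prior for a level."""
    return ebayes.weight_from_coeffs(detail_coeffs, sigma)


def cauchy_posterior_median(x, sigma: float, w: float):
    """Posterior-median shrinkage of coefficient(s) ``x`` (see ebayes module)."""
    return ebayes.posterior_median(x, sigma, w)


def denoise(
    trace: SignalTrace,
    spec: WaveletSpec = WaveletSpec(),
    return_decomposition: bool = False,
):
    """Denoise a trace: fwt -> per-level EB shrinkage of details -> ifwt.

    Per detail level (finest to coarsest): estimate the noise scale by MAD, fit
    the mixing weight by marginal ML, and shrink every coefficient to its
    posterior median (or hard-threshold when ``spec.threshold_rule == 'hard'``).
    Levels too small for estimation (or with zero MAD) reuse the nearest
    finer valid level's scale and weight; if none exists the level passes
    through unshrunk.  Approximation coefficients always pass through.
    """
    dec = fwt(trace, spec)
    n_lev = len(dec.details)
    sigmas = np.full(n_lev, np.nan)
    weights = np.full(n_lev, np.nan)
    last_valid: tuple[float, float] | None = None
    shrunk = []
    for i, d in enumerate(dec.details):
        sigma_w: tuple[float, float] | None
        if d.size >= MIN_LEVEL_SIZE:
            sigma = estimate_level_noise(d)
            if sigma > 0.0:
                w = estimate_level_weight(d, sigma)
                sigma_w = (sigma, w)
                last_valid = sigma_w
            else:
                sigma_w = last_valid
        else:
            sigma_w = last_valid
        if sigma_w is None:
            shrunk.append(d.copy())  # nothing estimable anywhere yet: pass through
            continue
        sigma, w = sigma_w
        sigmas[i], weights[i] = sigma, w
        if spec.threshold_rule == "hard":
            t = ebayes.threshold_from_weight(w, sigma)
            shrunk.append(np.where(np.abs(d) < t, 0.0, d))
        else:
            shrunk.append(ebayes.posterior_median(d, sigma, w))
    out_dec = WaveletDecomposition(
        approximation=dec.approximation,
        details=shrunk,
        sampling_rate_hz=dec.sampling_rate_hz,
        length=dec.length,
        spec=spec,
        sigma_per_level=sigmas,
        weight_per_level=weights,
    )
    out = trace.with_samples(ifwt(out_dec), label=f"{trace.label} denoised".strip())
    if return_decomposition:
        return out, out_dec
    return out
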