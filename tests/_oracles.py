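"""Independent numeric oracles used by the tests.

The posterior-median oracle integrates the quasi-Cauchy posterior density by
quadrature and bisects its CDF; it shares no code with the closed-form root
equation in :mod:`ionowave.ebayes`.
"""

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

_PHI0 = 1.0 / np.sqrt(2.0 * np.pi)


def quasi_cauchy_prior(theta: float) -> float:
    t = abs(theta)
    if t >= 30.0:
        return _PHI0 / t**2  # asymptotic tail, avoids 0/0 in the Mills ratio
    return _PHI0 * (1.0 - t * norm.sf(t) / norm.pdf(t))


def quasi_cauchy_marginal(z: float) -> float:
    if z == 0.0:
        return 0.5 * _PHI0
    return _PHI0 * (1.0 - np.exp(-0.5 * z * z)) / z**2


def oracle_posterior_median(x: float, w: float, sigma: float = 1.0) -> float:
    """Median of the posterior of theta given x under w*gamma + (1-w)*delta_0."""
    s = np.sign(x)
    z = abs(x) / sigma
    if z == 0.0 or w == 0.0:
        return 0.0
    m = w * quasi_cauchy_marginal(z) + (1.0 - w) * norm.pdf(z)

    def tail_mass(mu: float) -> float:
        val = integrate.quad(
            lambda th: quasi_cauchy_prior(th) * norm.pdf(z - th),
            mu,
            z + 40.0,
            points=[z] if mu < z else None,
            limit=200,
        )[0]
        return w * val

    target = 0.5 * m
    if tail_mass(0.0) <= target:
        return 0.0
    mu = optimize.brentq(lambda mu: tail_mass(mu) - target, 0.0, z + 10.0, xtol=1e-10)
    return float(s * mu * sigma)
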