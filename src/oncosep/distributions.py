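"""Moment-matched nonnegative sampling for lab values.

Published lab summaries give only a mean and SD per group.  Clinical
concentrations cannot be negative, and naively truncating N(mean, sd) at zero
inflates the mean (for the A/G ratio by ~0.18).  We therefore draw from a
zero-truncated normal whose *underlying* (mu0, sigma0) are solved so that the
truncated distribution reproduces the target mean and SD exactly.

A zero-truncated normal cannot attain a coefficient of variation >= 1
(its cv approaches 1 only in the exponential-tail limit); for lab tests whose
printed cv is that large (cholesterol, APTT, PT) a moment-matched gamma is
used instead — also nonnegative and also matching both moments.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

#: above this cv the truncated-normal solve becomes ill-conditioned; use gamma
CV_SWITCH = 0.95


def _lambda(alpha: float) -> float:
    """Inverse Mills ratio phi(a)/(1-Phi(a)), stable for large |a|."""
    return float(np.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha)))


def _truncated_cv(alpha: float) -> float:
    """cv of a normal left-truncated at ``alpha`` SDs below/above its mean."""
    lam = _lambda(alpha)
    delta = lam - alpha  # scaled mean of the truncated variable
    var = 1.0 - lam * delta
    if var <= 0.0:  # numerical underflow far in the tail
        var = 0.0
    return math.sqrt(var) / delta


def truncnorm_match(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu0, sigma0) of a zero-truncated normal with given moments.

    Solves cv(alpha) = sd/mean for alpha = -mu0/sigma0, then rescales.
    Requires 0 < sd/mean < 1 (the attainable cv range of the family).
    """
    if mean <= 0:
        raise ValueError("zero-truncated normal requires mean > 0")
    cv = sd / mean
    if not 0.0 < cv < 1.0:
        raise ValueError(f"cv={cv:.3f} unattainable by a zero-truncated normal")
    # cv(alpha) increases from 0 (alpha -> -inf, truncation negligible)
    # towards 1 (alpha -> +inf); bracket generously.
    alpha = optimize.brentq(lambda a: _truncated_cv(a) - cv, -60.0, 60.0, xtol=1e-12)
    delta = _lambda(alpha) - alpha
    sigma0 = mean / delta
    mu0 = -alpha * sigma0
    return mu0, sigma0


def sample_lab_values(
    mean: float,
    sd: float,
    size: int,
    rng: np.random.Generator,
    nonnegative: bool = True,
) -> np.ndarray:
    """Draw ``size`` values with the given mean/SD from a nonnegative family.

    sd == 0 degenerates to a constant; cv < CV_SWITCH uses the moment-matched
    zero-truncated normal; larger cv uses a moment-matched gamma.  With
    ``nonnegative=False`` a plain normal is used.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.full(size, float(mean))
    if not nonnegative:
        return rng.normal(mean, sd, size=size)
    cv = sd / mean
    if cv < CV_SWITCH:
        mu0, sigma0 = truncnorm_match(mean, sd)
        a = (0.0 - mu0) / sigma0
        u = rng.random(size)
        # inverse-CDF sampling of the left-truncated normal
        lo = stats.norm.cdf(a)
        return stats.norm.ppf(lo + u * (1.0 - lo)) * sigma0 + mu0
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=size)
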