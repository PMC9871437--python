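"""Probability kernels for the four count families.

All four laws — Poisson (P), negative binomial (NB), zero-inflated Poisson
(ZIP) and zero-inflated negative binomial (ZINB) — are special cases of the
ZINB distribution.  The NB is parameterized by its mean ``mu`` and dispersion
``theta`` (often written phi), with variance ``mu + mu**2 / theta``; the
zero-inflated laws add a structural-zero probability ``omega``:

    P(Y = 0) = omega + (1 - omega) * g(0)
    P(Y = y) = (1 - omega) * g(y)          for y > 0

where ``g`` is the P or NB probability mass function.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

FAMILIES = ("P", "NB", "ZIP", "ZINB")
UNIMODAL = frozenset({"P", "NB"})
ZERO_INFLATED = frozenset({"ZIP", "ZINB"})

_LOG_EPS = -745.0  # below exp() underflow


def nb_logpmf(k, mu, theta):
    """log NB(k; mu, theta) with variance mu + mu^2/theta; mu may be 0.

    theta = inf is the Poisson limit (boundary MLE on equidispersed data).
    """
    k = np.asarray(k)
    mu = np.asarray(mu, dtype=float)
    if np.isinf(theta):
        return stats.poisson.logpmf(k, mu)
    p = theta / (theta + mu)
    return stats.nbinom.logpmf(k, theta, p)


def zi_logpmf(k, base_logpmf, omega):
    """Mix a point mass at zero into base log-pmf values."""
    k = np.asarray(k)
    out = np.asarray(base_logpmf, dtype=float) + np.log1p(-omega)
    if omega > 0:
        zero = k == 0
        if np.any(zero):
            out = np.where(
                zero, np.logaddexp(np.log(omega), out), out
            )
    return out


def family_logpmf(k, family, mu, phi=None, omega=0.0):
    """Log pmf of one of the four families at counts ``k``.

    ``mu`` is the count-component mean (scalar or per-observation vector),
    ``phi`` the NB dispersion (ignored for P/ZIP) and ``omega`` the
    structural-zero probability (ignored for P/NB).
    """
    if family in ("P", "ZIP"):
        base = stats.poisson.logpmf(k, mu)
    elif family in ("NB", "ZINB"):
        base = nb_logpmf(k, mu, phi)
    else:
        raise ValueError(f"unknown family {family!r}")
    if family in ZERO_INFLATED:
        return zi_logpmf(k, base, float(omega))
    return base


def zinb_cdf(k, pi, mu, theta):
    """CDF of ZINB(pi, mu, theta) at integer points k."""
    p = theta / (theta + mu)
    return pi + (1.0 - pi) * stats.nbinom.cdf(k, theta, p)


def zinb_rvs(rng, pi, mu, theta, size):
    """Draw from ZINB(pi, mu, theta); ``mu`` scalar or length-``size``."""
    p = theta / (theta + np.broadcast_to(mu, (size,)).astype(float))
    y = rng.negative_binomial(theta, p)
    if pi > 0:
        y = np.where(rng.random(size) < pi, 0, y)
    return y


def family_rvs(rng, family, mu, phi=None, omega=0.0, size=None):
    """Sample counts from one of the four families.

    ``mu`` may be a per-cell vector (library-size-scaled means); ``size``
    defaults to its length.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if size is None:
        size = mu.shape[0]
    mu = np.broadcast_to(mu, (size,))
    if family in ("P", "ZIP"):
        y = rng.poisson(mu)
    elif family in ("NB", "ZINB"):
        p = phi / (phi + mu)
        y = rng.negative_binomial(phi, p)
    else:
        raise ValueError(f"unknown family {family!r}")
    if family in ZERO_INFLATED and omega > 0:
        y = np.where(rng.random(size) < omega, 0, y)
    return y


def zero_probability(family, mu, phi=None, omega=0.0):
    """P(Y=0) under the family at mean ``mu`` (elementwise)."""
    return np.exp(family_logpmf(0, family, mu, phi=phi, omega=omega))
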