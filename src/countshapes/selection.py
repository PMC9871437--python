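"""BIC model selection and the two rounds of model-adequacy testing.

The candidate family is the converged fit with the least BIC.  Two adequacy
checks follow:

* zero-inflation LRT (decision-making): if the candidate is ZIP or ZINB, the
  boundary likelihood-ratio test against its unimodal counterpart must
  support omega > 0; its null is the equal mixture 0.5*chi2_0 + 0.5*chi2_1
  because omega sits on the boundary of the parameter space.  A
  non-significant test makes the call fall back to the counterpart.
* deviance goodness of fit (diagnostic): for a final P or NB call the
  deviance against the saturated model is recorded; it is not valid for the
  zero-inflated models (not strictly nested) and triggers no relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distributions import family_logpmf
from .glm import FitResult

FAMILY_ORDER = ("P", "NB", "ZIP", "ZINB")  # simpler first; tie-break order
_ZI_COUNTERPART = {"ZIP": "P", "ZINB": "NB"}
_BIC_TIE_TOL = 1e-9


@dataclass
class AdequacyResult:
    deviance: float | None = None
    deviance_df: int | None = None
    deviance_p: float | None = None
    lrt_stat: float | None = None
    lrt_p: float | None = None
    round1_pass: bool | None = None  # deviance GoF (diagnostic)
    round2_pass: bool | None = None  # zero-inflation LRT


@dataclass
class DistributionCall:
    gene: str
    condition: str
    label: str  # P | NB | ZIP | ZINB | FAILED
    bic_all: dict[str, float] = field(default_factory=dict)
    adequacy: AdequacyResult = field(default_factory=AdequacyResult)
    omega_hat: float | None = None


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion: -2 ln L + k ln n (lower is better)."""
    return -2.0 * loglik + k * np.log(n)


def select_min_bic(fits: dict[str, FitResult | None]) -> str | None:
    """Family with minimal BIC among converged fits; exact ties go to the
    simpler family in the order P < NB < ZIP < ZINB. None if nothing converged."""
    best = None
    best_bic = np.inf
    for family in FAMILY_ORDER:
        fit = fits.get(family)
        if fit is None or not fit.converged:
            continue
        b = bic(fit.loglik, fit.k, fit.n)
        if b < best_bic - _BIC_TIE_TOL:
            best, best_bic = family, b
    return best


def saturated_loglik(y, family: str, phi: float | None = None) -> float:
    """Log-likelihood of the saturated model (per-cell mean mu_j = y_j,
    0*log 0 := 0); for NB the fitted dispersion is held fixed."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(y, 1e-300)  # nbinom/poisson pmf at mu=0, y=0 is 1
    ll = family_logpmf(y.astype(np.int64), family, np.where(y > 0, y, 0.0), phi=phi)
    return float(np.sum(ll))


def deviance_gof(fit: FitResult, y) -> tuple[float, int, float]:
    """Deviance D = 2 (l_saturated - l_fitted), asymptotically chi2 with
    n - k degrees of freedom; valid for P and NB fits only."""
    if fit.family not in ("P", "NB"):
        raise ValueError("deviance GoF applies to P and NB fits only")
    l_sat = saturated_loglik(y, fit.family, phi=fit.phi)
    d = 2.0 * (l_sat - fit.loglik)
    d = max(d, 0.0)
    df = fit.n - fit.k
    if df <= 0:
        return d, df, 1.0
    return d, df, float(stats.chi2.sf(d, df))


def zi_lrt(fit_zi: FitResult, fit_base: FitResult) -> tuple[float, float]:
    """Boundary LRT of omega = 0: rho = -2 (l_base - l_zi), p-value from the
    equal mixture 0.5*chi2_0 + 0.5*chi2_1 (p = 1 at rho = 0, else half the
    chi2_1 upper tail)."""
    if _ZI_COUNTERPART.get(fit_zi.family) != fit_base.family:
        raise ValueError(
            f"invalid LRT pair ({fit_zi.family} vs {fit_base.family}); "
            "expected ZIP vs P or ZINB vs NB"
        )
    rho = max(0.0, -2.0 * (fit_base.loglik - fit_zi.loglik))
    if rho == 0.0:
        return 0.0, 1.0
    return rho, float(0.5 * stats.chi2.sf(rho, 1))


def assign_distribution(
    fits: dict[str, FitResult | None],
    y,
    gene: str = "",
    condition: str = "",
    alpha: float = 0.05,
) -> DistributionCall:
    """Final per-gene call: min-BIC candidate, zero-inflation LRT fallback,
    then deviance diagnostic on unimodal calls."""
    bics = {
        fam: bic(fit.loglik, fit.k, fit.n)
        for fam, fit in fits.items()
        if fit is not None and fit.converged
    }
    adequacy = AdequacyResult()
    candidate = select_min_bic(fits)
    if candidate is None:
        return DistributionCall(gene=gene, condition=condition, label="FAILED",
                                bic_all=bics, adequacy=adequacy)

    label = candidate
    if candidate in _ZI_COUNTERPART:
        base_family = _ZI_COUNTERPART[candidate]
        base_fit = fits.get(base_family)
        if base_fit is not None and base_fit.converged:
            rho, p = zi_lrt(fits[candidate], base_fit)
            adequacy.lrt_stat, adequacy.lrt_p = rho, p
            adequacy.round2_pass = p < alpha
            if p >= alpha:  # zero inflation not supported: fall back
                label = base_family
        else:
            # counterpart never converged; the LRT cannot be run and the
            # zero-inflated call stands untested
            adequacy.round2_pass = True

    omega_hat = None
    if label in _ZI_COUNTERPART:
        omega_hat = fits[label].omega
    else:
        fit = fits.get(label)
        if fit is not None and fit.converged:
            d, df, p = deviance_gof(fit, y)
            adequacy.deviance, adequacy.deviance_df, adequacy.deviance_p = d, df, p
            adequacy.round1_pass = True if df <= 0 else p >= alpha

    return DistributionCall(
        gene=gene, condition=condition, label=label,
        bic_all=bics, adequacy=adequacy, omega_hat=omega_hat,
    )
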