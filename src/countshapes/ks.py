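"""Monte-Carlo Kolmogorov–Smirnov gate into the ZINB family.

Poisson, NB, ZIP and ZINB are all special cases of the ZINB distribution, so
a gene is eligible for four-family GLM fitting only if a ZINB marginal is an
adequate description of its counts.  Because parameters are estimated from
the data, plain KS tables are invalid (and anticonservative for discrete
data); p-values therefore come from a parametric bootstrap in which the
ZINB parameters are re-estimated on every simulated replicate.

The marginal fit here is covariate-free and offset-free: it works on the
pooled counts of one gene in one condition, compressed to (value, weight)
pairs so that each likelihood evaluation costs O(#unique values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .distributions import zinb_cdf, zinb_rvs


class DegenerateDataError(ValueError):
    """Counts carry no distributional information (constant vector)."""


@dataclass
class ZINBParams:
    """Marginal ZINB parameters: structural-zero probability ``pi`` in [0, 1),
    count-component mean ``mu`` > 0 and dispersion ``theta`` > 0
    (count-component variance = mu + mu^2/theta)."""

    pi: float
    mu: float
    theta: float

    def __post_init__(self):
        if not (0 <= self.pi < 1):
            raise ValueError(f"pi={self.pi} outside [0, 1)")
        if self.mu <= 0 or self.theta <= 0:
            raise ValueError("mu and theta must be > 0")


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n_boot: int
    params: ZINBParams | None = None
    retained: bool | None = None


_LOGIT_PI_BOUNDS = (-13.8, 6.9)   # pi in [~1e-6, ~0.999]
_LOG_THETA_BOUNDS = (-4.6, 9.2)   # theta in [0.01, ~1e4]


def _nb_terms(pos_values, mu, theta, lgam_k1):
    """Weighted NB log-pmf pieces and partials at the positive support."""
    k = pos_values
    tm = theta + mu
    logp = (
        special.gammaln(k + theta)
        - special.gammaln(theta)
        - lgam_k1
        + theta * (np.log(theta) - np.log(tm))
        + k * (np.log(mu) - np.log(tm))
    )
    dmu = k / mu - (k + theta) / tm
    dtheta = (
        special.digamma(k + theta)
        - special.digamma(theta)
        + np.log(theta) + 1.0 - np.log(tm)
        - (k + theta) / tm
    )
    return logp, dmu, dtheta


def _weighted_nll_grad(x, pos_values, pos_weights, w_zero, lgam_k1, fit_pi):
    """Negative log-likelihood and analytic gradient in
    (logit pi, log mu, log theta) — the hot loop of the bootstrap."""
    if fit_pi:
        pi = special.expit(x[0])
        mu, theta = np.exp(x[1]), np.exp(x[2])
    else:
        pi = 0.0
        mu, theta = np.exp(x[0]), np.exp(x[1])
    logp, dmu, dtheta = _nb_terms(pos_values, mu, theta, lgam_k1)
    if fit_pi:
        logp = logp + np.log1p(-pi)
    ll = float(np.dot(pos_weights, logp))
    g_mu = float(np.dot(pos_weights, dmu)) * mu
    g_theta = float(np.dot(pos_weights, dtheta)) * theta
    w_pos = pos_weights.sum()

    if w_zero > 0:
        tm = theta + mu
        log_g0 = theta * (np.log(theta) - np.log(tm))
        g0 = np.exp(log_g0)
        l0 = pi + (1.0 - pi) * g0
        ll += w_zero * np.log(l0)
        g_mu += w_zero * (-(1.0 - pi) * g0 * theta * mu / (tm * l0))
        g_theta += w_zero * ((1.0 - pi) * g0 * (np.log(theta) + 1.0 - np.log(tm) - theta / tm) * theta / l0)
        if fit_pi:
            g_pi = w_zero * pi * (1.0 - pi) * (1.0 - g0) / l0 - w_pos * pi
            return -ll, -np.array([g_pi, g_mu, g_theta])
        return -ll, -np.array([g_mu, g_theta])
    if fit_pi:
        return -ll, -np.array([-w_pos * pi, g_mu, g_theta])
    return -ll, -np.array([g_mu, g_theta])


def _moment_init(values, weights):
    n = weights.sum()
    mean = np.dot(weights, values) / n
    var = np.dot(weights, (values - mean) ** 2) / max(n - 1, 1)
    pos = values > 0
    n_pos = weights[pos].sum()
    mu0 = np.dot(weights[pos], values[pos]) / n_pos
    zero_frac = 1.0 - n_pos / n
    if var > mean:
        theta0 = np.clip(mean**2 / (var - mean), 0.05, 100.0)
    else:
        theta0 = 100.0
    nb_zero = (theta0 / (theta0 + mu0)) ** theta0
    pi0 = np.clip((zero_frac - nb_zero) / max(1.0 - nb_zero, 1e-8), 0.02, 0.95)
    return pi0, mu0, theta0


def fit_zinb_marginal(y, init: ZINBParams | None = None) -> ZINBParams:
    """Maximum-likelihood covariate-free ZINB fit of a count vector.

    Counts are compressed to unique values with multiplicities and the
    negative log-likelihood minimized by L-BFGS-B over (logit pi, log mu,
    log theta); when no zeros are observed, pi is fixed at 0 and the fit
    reduces to the plain NB marginal MLE.  Boundary solutions pi -> 0 are
    snapped to exactly 0.

    Raises DegenerateDataError for constant input.
    """
    y = np.asarray(y, dtype=np.int64)
    values, weights = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise DegenerateDataError("counts are constant; no distribution to fit")
    weights = weights.astype(float)
    has_zero = bool(values[0] == 0)
    if has_zero:
        w_zero = float(weights[0])
        pos_values, pos_weights = values[1:].astype(float), weights[1:]
    else:
        w_zero = 0.0
        pos_values, pos_weights = values.astype(float), weights
    lgam_k1 = special.gammaln(pos_values + 1.0)

    if init is not None:
        pi0, mu0, theta0 = max(init.pi, 0.02), init.mu, init.theta
    else:
        pi0, mu0, theta0 = _moment_init(values, weights)
    theta0 = float(np.clip(theta0, 0.02, 5e3))

    if has_zero:
        x0 = np.array([special.logit(pi0), np.log(mu0), np.log(theta0)])
        bounds = [_LOGIT_PI_BOUNDS, (-20.0, 15.0), _LOG_THETA_BOUNDS]
    else:
        x0 = np.array([np.log(mu0), np.log(theta0)])
        bounds = [(-20.0, 15.0), _LOG_THETA_BOUNDS]

    res = optimize.minimize(
        _weighted_nll_grad,
        x0,
        args=(pos_values, pos_weights, w_zero, lgam_k1, has_zero),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-11},
    )
    x = res.x
    if has_zero:
        pi = float(special.expit(x[0]))
        mu, theta = float(np.exp(x[1])), float(np.exp(x[2]))
    else:
        pi = 0.0
        mu, theta = float(np.exp(x[0])), float(np.exp(x[1]))
    if pi < 1e-5:
        pi = 0.0
    return ZINBParams(pi=pi, mu=mu, theta=theta)


def ks_statistic(y, params: ZINBParams) -> float:
    """sup_k |ECDF(k) - ZINB CDF(k)| over the integer support 0..max(y).

    The ECDF is constant between observed values while the model CDF is
    nondecreasing, so the supremum over the full support is attained either
    at an observed value v or at the integer just before the next observed
    value; only those O(#unique) points need evaluating.
    """
    y = np.asarray(y, dtype=np.int64)
    values, counts = np.unique(y, return_counts=True)
    ecdf = np.cumsum(counts) / len(y)
    cdf_at = zinb_cdf(values, params.pi, params.mu, params.theta)
    d = np.max(np.abs(ecdf - cdf_at))
    # just before each observed value (ECDF there is the previous level)
    prev_ecdf = np.concatenate([[0.0], ecdf[:-1]])
    before = values - 1
    ok = before >= 0
    if ok.any():
        cdf_before = zinb_cdf(before[ok], params.pi, params.mu, params.theta)
        d = max(d, np.max(np.abs(prev_ecdf[ok] - cdf_before)))
    return float(d)


def ks_test_mc(y, n_boot: int = 199, seed=None, rng=None) -> KSResult:
    """Parametric-bootstrap KS goodness-of-fit test against the ZINB family.

    Fits ZINB on ``y``, then simulates ``n_boot`` replicates from the fit,
    re-estimating the parameters on each replicate before computing its KS
    distance (the correct null when parameters are estimated).  The add-one
    estimator p = (1 + #{D_b >= D_obs}) / (n_boot + 1) keeps p > 0.
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=np.int64)
    params = fit_zinb_marginal(y)
    d_obs = ks_statistic(y, params)
    n = len(y)
    exceed = 0
    for _ in range(n_boot):
        y_b = zinb_rvs(rng, params.pi, params.mu, params.theta, n)
        try:
            params_b = fit_zinb_marginal(y_b, init=params)
        except DegenerateDataError:
            # replicate collapsed to a constant; its best fit is its own
            # point mass, so treat its distance as exceeding any observed D
            exceed += 1
            continue
        if ks_statistic(y_b, params_b) >= d_obs:
            exceed += 1
    pvalue = (1 + exceed) / (n_boot + 1)
    return KSResult(statistic=d_obs, pvalue=pvalue, n_boot=n_boot, params=params)


def select_zinb_family(pvalues, alpha: float = 0.01, method: str = "fdr_bh"):
    """Benjamini–Hochberg adjust KS p-values; a gene is retained when its
    adjusted p-value is >= alpha (the ZINB-family fit is not rejected).

    ``pvalues`` maps gene -> raw p-value (or is a pandas Series); returns
    (retained gene list, adjusted p-value dict).
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    series = pd.Series(pvalues, dtype=float)
    if series.empty:
        return [], {}
    _, adjusted, _, _ = multipletests(series.to_numpy(), method=method)
    adj = pd.Series(adjusted, index=series.index)
    retained = [g for g in series.index if adj[g] >= alpha]
    return retained, adj.to_dict()
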