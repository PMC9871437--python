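"""Covariate-adjusted count GLMs: P, NB, ZIP and ZINB with a log link.

Sequencing depth is normalized model-side: the log of the per-cell library
size enters the linear predictor as an offset (coefficient fixed at 1), so
the count-component mean for cell j is mu_j = exp(x_j' beta + offset_j).
The zero-inflated families mix a structural-zero point mass omega into the
count component; omega is a single scalar per gene and condition (the
zero model is intercept-only), so it is directly interpretable as the
estimated proportion of structural zeros.

Fitting is maximum likelihood via statsmodels; the zero-inflated fits are
guarded by a restart from an omega ~ 0 initialization whenever the mixture
log-likelihood falls below its nested base fit, which the true MLE can
never do.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special
from statsmodels.discrete.count_model import (
    ZeroInflatedNegativeBinomialP,
    ZeroInflatedPoisson,
)
from statsmodels.discrete.discrete_model import NegativeBinomial

from .datamodel import CellDesign
from .distributions import family_logpmf

log = logging.getLogger(__name__)

MAX_ITER = 200
TOL = 1e-8
_PHI_CAP = 1e8  # NB dispersion cap; beyond this the NB is numerically Poisson


@dataclass
class ModelSpec:
    """Design matrix (intercept + dummy-coded covariates), per-cell offset
    and the column names that survived the rank check."""

    X: np.ndarray
    offset: np.ndarray
    columns: list[str]

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


@dataclass
class FitResult:
    """One fitted GLM for one gene: coefficients, dispersion, zero inflation,
    log-likelihood and the parameter count entering the BIC."""

    family: str
    beta: np.ndarray
    loglik: float
    k: int
    n: int
    converged: bool
    mu_hat: np.ndarray
    phi: float | None = None
    omega: float | None = None
    columns: list[str] = field(default_factory=list)


@dataclass
class ZeroInflationScreen:
    """Observed/predicted-zero ratio under the Poisson fit; a ratio outside
    1 +/- tolerance flags the gene for zero-inflated fitting."""

    observed_zeros: int
    predicted_zeros: float
    ratio: float
    tolerance: float
    needs_zi: bool


def build_design(
    design: CellDesign,
    covariate_names: list[str] | None = None,
    cells: list[str] | None = None,
    offset_base: str = "e",
    standardize_numeric: bool = False,
) -> ModelSpec:
    """Intercept + dummy-coded categoricals (reference = lexicographically
    first level) + numeric covariates; offset = log library size.

    ``offset_base`` selects natural log (default) or base-10 log of the
    library size. Collinear columns are dropped with a warning.
    """
    covariate_names = list(covariate_names or [])
    table = design.table.loc[cells] if cells is not None else design.table
    n = len(table)
    blocks = [pd.Series(1.0, index=table.index, name="intercept")]
    for cov in covariate_names:
        if cov not in table.columns:
            raise KeyError(f"covariate {cov!r} missing from design")
        col = table[cov]
        if pd.api.types.is_numeric_dtype(col):
            vals = col.astype(float)
            if standardize_numeric and vals.std(ddof=0) > 0:
                vals = (vals - vals.mean()) / vals.std(ddof=0)
            blocks.append(vals.rename(cov))
        else:
            levels = sorted(col.astype(str).unique())
            counts = col.value_counts()
            small = counts[counts < 2]
            if len(small):
                log.warning("covariate %r has levels with < 2 cells: %s", cov, list(small.index))
            for level in levels[1:]:  # first level is the reference
                blocks.append((col.astype(str) == level).astype(float).rename(f"{cov}[{level}]"))
    X = pd.concat(blocks, axis=1)

    # greedy rank check: drop any column not increasing the rank
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X.iloc[:, keep + [j]].to_numpy()
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            log.warning("dropping collinear design column %r", X.columns[j])
    X = X.iloc[:, keep]

    sizes = design.library_sizes().loc[table.index].to_numpy(dtype=float)
    if offset_base == "e":
        offset = np.log(sizes)
    elif offset_base in ("10", 10):
        offset = np.log10(sizes)
    else:
        raise ValueError("offset_base must be 'e' or '10'")
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset not finite for every cell (library size <= 0?)")
    return ModelSpec(X=X.to_numpy(), offset=offset, columns=list(X.columns))


def _result(family, params, llf, converged, spec, extra_k, phi=None, omega=None):
    p = spec.n_coef
    if family in ("P", "NB"):
        beta = np.asarray(params[:p])
    else:  # ZI families: [infl intercept, count coefficients, (alpha)]
        beta = np.asarray(params[1 : 1 + p])
    mu_hat = np.exp(spec.X @ beta + spec.offset)
    return FitResult(
        family=family,
        beta=beta,
        loglik=float(llf),
        k=p + extra_k,
        n=spec.n_cells,
        converged=bool(converged),
        mu_hat=mu_hat,
        phi=phi,
        omega=omega,
        columns=list(spec.columns),
    )


def _phi_from_alpha(alpha: float) -> float:
    if alpha <= 1.0 / _PHI_CAP:
        return _PHI_CAP
    return 1.0 / alpha


def _fit_poisson(y, spec):
    model = sm.GLM(y, spec.X, family=sm.families.Poisson(), offset=spec.offset)
    res = model.fit(maxiter=MAX_ITER, tol=TOL)
    return _result("P", res.params, res.llf, res.converged, spec, extra_k=0)


def _nb_boundary(base_fit, spec):
    """phi -> inf boundary solution: the NB coincides with the Poisson fit."""
    return FitResult(
        family="NB", beta=base_fit.beta.copy(), loglik=base_fit.loglik,
        k=spec.n_coef + 1, n=spec.n_cells, converged=base_fit.converged,
        mu_hat=base_fit.mu_hat.copy(), phi=np.inf, columns=list(spec.columns),
    )


def _fit_nb(y, spec, base_fit=None):
    model = NegativeBinomial(y, spec.X, offset=spec.offset, loglike_method="nb2")
    start = None
    if base_fit is not None:
        start = np.append(base_fit.beta, 0.1)
    base_llf = base_fit.loglik if base_fit is not None else -np.inf
    try:
        res = model.fit(disp=0, maxiter=MAX_ITER, start_params=start, method="bfgs", gtol=TOL)
        alpha = float(res.params[-1])
        if not np.isfinite(res.llf) or alpha < 0:
            raise ValueError("NB fit diverged")
        if res.llf < base_llf:
            # equidispersed data: the NB supremum is the Poisson boundary
            fit = _fit_nb_profiled(y, spec, base_fit)
            return fit if fit.loglik >= base_llf else _nb_boundary(base_fit, spec)
        conv = res.mle_retvals.get("converged", True)
        return _result(
            "NB", res.params, res.llf, conv, spec, extra_k=1, phi=_phi_from_alpha(alpha)
        )
    except Exception:
        fit = _fit_nb_profiled(y, spec, base_fit)
        if base_fit is not None and fit.loglik < base_llf:
            return _nb_boundary(base_fit, spec)
        return fit


def _fit_nb_profiled(y, spec, base_fit=None):
    """Profile the NB dispersion: inner IRLS for beta, outer Brent on log(alpha).

    Used when the joint quasi-Newton fit fails (typically equidispersed data
    pushing alpha to its boundary)."""
    from scipy.optimize import minimize_scalar

    def nll(log_alpha):
        fam = sm.families.NegativeBinomial(alpha=np.exp(log_alpha))
        try:
            r = sm.GLM(y, spec.X, family=fam, offset=spec.offset).fit(
                maxiter=MAX_ITER, tol=TOL
            )
        except Exception:
            return np.inf
        mu = r.predict()
        ll = family_logpmf(y, "NB", mu, phi=1.0 / np.exp(log_alpha)).sum()
        return -ll

    opt = minimize_scalar(nll, bounds=(-18.5, 6.0), method="bounded",
                          options={"xatol": 1e-6})
    alpha = float(np.exp(opt.x))
    fam = sm.families.NegativeBinomial(alpha=alpha)
    res = sm.GLM(y, spec.X, family=fam, offset=spec.offset).fit(maxiter=MAX_ITER, tol=TOL)
    phi = _phi_from_alpha(alpha)
    llf = float(family_logpmf(y, "NB", res.predict(), phi=phi).sum())
    params = np.append(res.params, alpha)
    return _result("NB", params, llf, res.converged, spec, extra_k=1, phi=phi)


def _zi_start(y, base_beta, alpha=None):
    zero_frac = float(np.mean(np.asarray(y) == 0))
    pi0 = np.clip(zero_frac / 2, 0.02, 0.9)
    start = [special.logit(pi0), *np.asarray(base_beta)]
    if alpha is not None:
        start.append(max(alpha, 1e-3))
    return np.asarray(start)


def _fit_zi(y, spec, family, base_fit):
    """Fit ZIP (against P) or ZINB (against NB), restarting near omega = 0 if
    the mixture log-likelihood falls below the nested base fit."""
    ones = np.ones((spec.n_cells, 1))
    if family == "ZIP":
        model = ZeroInflatedPoisson(
            y, spec.X, exog_infl=ones, offset=spec.offset, inflation="logit"
        )
        alpha0 = None
    else:
        model = ZeroInflatedNegativeBinomialP(
            y, spec.X, exog_infl=ones, offset=spec.offset, inflation="logit", p=2
        )
        alpha0 = (1.0 / base_fit.phi) if (base_fit and base_fit.phi) else 0.5

    base_beta = base_fit.beta if base_fit is not None else np.zeros(spec.n_coef)
    start = _zi_start(y, base_beta, alpha0)
    best = None

    def _try(method, start_params, maxiter=MAX_ITER):
        nonlocal best
        try:
            res = model.fit(start_params=start_params, disp=0, maxiter=maxiter,
                            method=method)
        except Exception:
            return None
        if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
            best = res
        return res

    base_llf0 = base_fit.loglik if base_fit is not None else -np.inf
    _try("bfgs", start)
    if best is None or best.llf < base_llf0:
        # quasi-Newton can diverge from rough starts; a simplex pass plus
        # quasi-Newton polish recovers the interior optimum.  Only worth it
        # when the zeros exceed what the base fit already predicts — if not,
        # the MLE is the omega = 0 boundary and the simplex would just crawl
        # back to it.
        zero_excess = True
        if base_fit is not None:
            p0 = np.exp(family_logpmf(0, base_fit.family, base_fit.mu_hat,
                                      phi=base_fit.phi))
            pred = float(p0.sum())
            sd = float(np.sqrt(np.sum(p0 * (1 - p0))))
            zero_excess = np.sum(y == 0) > pred + 2 * sd
        if zero_excess:
            nm = _try("nm", start, maxiter=500)
            if nm is not None and np.all(np.isfinite(nm.params)):
                _try("bfgs", nm.params)

    base_llf = base_fit.loglik if base_fit is not None else -np.inf
    if (best is None or best.llf < base_llf) and base_fit is not None:
        # the mixture supremum is on the omega = 0 boundary, where the ZI
        # model coincides with its unimodal special case: report that
        # boundary solution as the MLE
        extra_k = 1 if family == "ZIP" else 2
        return FitResult(
            family=family, beta=base_fit.beta.copy(), loglik=base_fit.loglik,
            k=spec.n_coef + extra_k, n=spec.n_cells, converged=base_fit.converged,
            mu_hat=base_fit.mu_hat.copy(), phi=base_fit.phi, omega=0.0,
            columns=list(spec.columns),
        )
    if best is None:
        return None
    omega = float(special.expit(best.params[0]))
    conv = best.mle_retvals.get("converged", True)
    llf = float(best.llf)
    if family == "ZIP":
        return _result("ZIP", best.params, llf, conv, spec, extra_k=1, omega=omega)
    alpha = float(best.params[-1])
    if alpha < 0:
        return None
    return _result(
        "ZINB", best.params, llf, conv, spec, extra_k=2,
        phi=_phi_from_alpha(alpha), omega=omega,
    )


def fit_glm(y, spec: ModelSpec, family: str, base_fit: FitResult | None = None) -> FitResult | None:
    """Maximum-likelihood fit of one family; returns None on failure.

    For the zero-inflated families a ``base_fit`` of the nested unimodal
    counterpart (P for ZIP, NB for ZINB) supplies starting values.
    """
    y = np.asarray(y, dtype=np.int64)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if spec.n_cells <= spec.n_coef:
        raise ValueError("need more cells than coefficients")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if family == "P":
                return _fit_poisson(y, spec)
            if family == "NB":
                return _fit_nb(y, spec, base_fit=base_fit)
            if family in ("ZIP", "ZINB"):
                return _fit_zi(y, spec, family, base_fit)
        except Exception as exc:  # separation, all-zero genes, etc.
            log.debug("fit of %s failed: %s", family, exc)
            return None
    raise ValueError(f"unknown family {family!r}")


def fit_all_families(
    y, spec: ModelSpec, fast_zero_screen: bool = False, tolerance: float = 0.05
) -> dict[str, FitResult | None]:
    """Fit P, NB and (unless screened out) ZIP and ZINB for one gene.

    With ``fast_zero_screen`` the zero-inflated families are fitted only when
    the Poisson fit under- or over-predicts the observed zeros by more than
    ``tolerance`` (the observed/predicted ratio leaves [1-tol, 1+tol]).
    """
    fits: dict[str, FitResult | None] = {}
    fits["P"] = fit_glm(y, spec, "P")
    fits["NB"] = fit_glm(y, spec, "NB", base_fit=fits["P"])
    fit_zi = True
    if fast_zero_screen and fits["P"] is not None and fits["P"].converged:
        screen = check_zero_inflation(y, fits["P"], tolerance=tolerance)
        fit_zi = screen.needs_zi
    if fit_zi:
        fits["ZIP"] = fit_glm(y, spec, "ZIP", base_fit=fits["P"])
        fits["ZINB"] = fit_glm(y, spec, "ZINB", base_fit=fits["NB"])
    else:
        fits["ZIP"] = None
        fits["ZINB"] = None
    return fits


def loglik_oracle(y, fit: FitResult) -> float:
    """Brute-force log-likelihood: sum of per-cell log pmf values at the
    fitted parameters. Used to validate fitted log-likelihoods."""
    return float(
        family_logpmf(
            np.asarray(y), fit.family, fit.mu_hat, phi=fit.phi, omega=fit.omega or 0.0
        ).sum()
    )


def check_zero_inflation(y, poisson_fit: FitResult, tolerance: float = 0.05) -> ZeroInflationScreen:
    """Ratio of observed to Poisson-predicted zeros; outside 1 +/- tolerance
    the gene needs a zero-inflated fit (ratio > 1: underfitted zeros;
    ratio < 1: overfitted)."""
    y = np.asarray(y)
    observed = int(np.sum(y == 0))
    predicted = float(np.exp(-poisson_fit.mu_hat).sum())
    if predicted <= 0:
        ratio = np.inf if observed > 0 else 1.0
    else:
        ratio = observed / predicted
    needs = not (1 - tolerance <= ratio <= 1 + tolerance)
    return ZeroInflationScreen(
        observed_zeros=observed,
        predicted_zeros=predicted,
        ratio=ratio,
        tolerance=tolerance,
        needs_zi=needs,
    )
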