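import numpy as np
import pandas as pd
import pytest
from scipy import stats

from countshapes import (
    CellDesign,
    FitResult,
    assign_distribution,
    bic,
    build_design,
    deviance_gof,
    fit_all_families,
    fit_glm,
    select_min_bic,
    zi_lrt,
)
from countshapes.distributions import family_rvs
from countshapes.selection import saturated_loglik


def mock_fit(family, loglik, k, n=100, omega=None, phi=None):
    return FitResult(
        family=family, beta=np.zeros(1), loglik=loglik, k=k, n=n,
        converged=True, mu_hat=np.ones(n), omega=omega, phi=phi,
    )


class TestBIC:
    def test_formula(self):
        assert bic(0.0, 0, 10) == 0.0
        assert bic(-100.0, 3, 50) == pytest.approx(200 + 3 * np.log(50), abs=1e-9)
        assert bic(-100.0, 3, 50) == pytest.approx(211.73600, abs=1e-4)

    def test_extra_parameter_costs_log_n(self):
        assert bic(-5.0, 3, 77) - bic(-5.0, 2, 77) == pytest.approx(np.log(77))

    def test_shift_invariance_of_argmin(self):
        fits = {
            "P": mock_fit("P", -60.0, 1),
            "NB": mock_fit("NB", -50.0, 2),
            "ZIP": mock_fit("ZIP", -55.0, 2),
            "ZINB": mock_fit("ZINB", -49.0, 3),
        }
        shifted = {f: mock_fit(f, v.loglik + 123.0, v.k) for f, v in fits.items()}
        assert select_min_bic(fits) == select_min_bic(shifted)


class TestSelectMinBIC:
    def test_argmin(self):
        n = 100
        fits = {}
        for fam, b in [("P", 100.0), ("NB", 95.0), ("ZIP", 98.0), ("ZINB", 97.0)]:
            k = {"P": 1, "NB": 2, "ZIP": 2, "ZINB": 3}[fam]
            fits[fam] = mock_fit(fam, -(b - k * np.log(n)) / 2, k, n)
        assert select_min_bic(fits) == "NB"

    def test_tie_goes_to_simpler(self):
        n = 100
        # equal BIC for P and ZIP by construction
        fits = {
            "P": mock_fit("P", -50.0, 1, n),
            "ZIP": mock_fit("ZIP", -50.0 + np.log(n) / 2, 2, n),
        }
        assert select_min_bic(fits) == "P"

    def test_only_survivor_wins(self):
        assert select_min_bic({"ZINB": mock_fit("ZINB", -10, 3)}) == "ZINB"
        assert select_min_bic({"P": None, "NB": None}) is None


class TestDevianceGoF:
    def _offsetless_spec(self, n):
        table = pd.DataFrame(
            {"condition": ["A"] * n, "library_size": [1.0] * n},
            index=[f"c{i}" for i in range(n)],
        )
        return build_design(CellDesign(table))

    def test_perfect_fit_zero_deviance(self):
        y = np.array([2, 2, 2])
        fit = fit_glm(y, self._offsetless_spec(3), "P")
        d, df, p = deviance_gof(fit, y)
        assert d == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_poisson_deviance(self):
        y = np.array([1, 2, 3])
        fit = fit_glm(y, self._offsetless_spec(3), "P")
        d, df, p = deviance_gof(fit, y)
        expected = 2 * (1 * np.log(0.5) + 1 + 3 * np.log(1.5) - 1)
        assert d == pytest.approx(expected, abs=1e-6)
        assert d == pytest.approx(1.04650, abs=1e-4)
        assert df == 2

    def test_matches_saturated_oracle(self, rng):
        from countshapes import loglik_oracle

        n = 200
        sizes = rng.lognormal(4, 0.3, n)
        table = pd.DataFrame({"condition": ["A"] * n, "library_size": sizes},
                             index=[f"c{i}" for i in range(n)])
        spec = build_design(CellDesign(table))
        for family, phi in [("P", None), ("NB", 1.2)]:
            y = family_rvs(rng, family, 5.0 * sizes / sizes.mean(), phi=phi)
            fit = fit_glm(y, spec, family)
            d, _, _ = deviance_gof(fit, y)
            oracle = 2 * (saturated_loglik(y, family, phi=fit.phi) - loglik_oracle(y, fit))
            assert d == pytest.approx(oracle, abs=1e-6)

    def test_rejected_for_zero_inflated(self):
        with pytest.raises(ValueError):
            deviance_gof(mock_fit("ZIP", -10, 2), np.array([0, 1]))


class TestZeroInflationLRT:
    def test_boundary_gives_p_one(self):
        zi = mock_fit("ZIP", -50.0, 2)
        base = mock_fit("P", -50.0, 1)
        rho, p = zi_lrt(zi, base)
        assert rho == 0.0 and p == 1.0

    def test_mixture_quantile(self):
        rho = 2.705543
        zi = mock_fit("ZINB", -50.0 + rho / 2, 3)
        base = mock_fit("NB", -50.0, 2)
        got_rho, p = zi_lrt(zi, base)
        assert got_rho == pytest.approx(rho, abs=1e-9)
        assert p == pytest.approx(0.05, abs=1e-4)
        assert p == pytest.approx(0.5 * stats.chi2.sf(rho, 1), abs=1e-12)

    def test_mismatched_pair_rejected(self):
        with pytest.raises(ValueError):
            zi_lrt(mock_fit("ZIP", -10, 2), mock_fit("NB", -11, 2))


class TestAssignDistribution:
    def test_zi_call_requires_significant_lrt(self):
        n = 2000
        # ZINB wins BIC and the LRT is decisive
        fits = {
            "NB": mock_fit("NB", -4000.0, 2, n, phi=1.0),
            "ZINB": mock_fit("ZINB", -3950.0, 3, n, omega=0.4, phi=1.0),
        }
        call = assign_distribution(fits, np.zeros(n), gene="g")
        assert call.label == "ZINB"
        assert call.omega_hat == 0.4
        assert call.adequacy.lrt_p < 0.001

    def test_fallback_when_lrt_insignificant(self):
        # a BIC win needs rho > ln n, so the fallback can only fire when the
        # mixture tail at ln n is still above alpha: small n, strict alpha
        n = 12
        fits = {
            "P": mock_fit("P", -20.0, 1, n),
            "ZIP": mock_fit("ZIP", -18.5, 2, n, omega=0.05),
        }
        assert select_min_bic(fits) == "ZIP"
        y = np.concatenate([np.zeros(6), np.ones(6)]).astype(int)
        call = assign_distribution(fits, y, gene="g", alpha=0.01)
        assert call.label == "P"
        assert call.adequacy.lrt_p >= 0.01
        assert call.adequacy.round2_pass is False

    def test_all_failed(self):
        call = assign_distribution({"P": None, "NB": None}, np.array([0, 1]))
        assert call.label == "FAILED"

    def test_never_zi_label_with_insignificant_lrt(self, rng):
        """On data simulated from each family the final label is never
        zero-inflated when its LRT p-value exceeds alpha."""
        sizes = rng.lognormal(6, 0.3, 600)
        table = pd.DataFrame({"condition": ["A"] * 600, "library_size": sizes},
                             index=[f"c{i}" for i in range(600)])
        spec = build_design(CellDesign(table))
        for family, phi, omega in [("P", None, 0), ("NB", 0.8, 0),
                                   ("ZIP", None, 0.4), ("ZINB", 0.8, 0.4)]:
            y = family_rvs(rng, family, 3.0 * sizes / sizes.mean(), phi=phi, omega=omega)
            call = assign_distribution(fit_all_families(y, spec), y)
            if call.label in ("ZIP", "ZINB"):
                assert call.adequacy.lrt_p is None or call.adequacy.lrt_p < 0.05

    def test_nb_recovered_on_nb_data(self, rng):
        sizes = rng.lognormal(6, 0.3, 2000)
        table = pd.DataFrame({"condition": ["A"] * 2000, "library_size": sizes},
                             index=[f"c{i}" for i in range(2000)])
        spec = build_design(CellDesign(table))
        labels = []
        for _ in range(5):
            y = family_rvs(rng, "NB", 6.0 * sizes / sizes.mean(), phi=0.7)
            labels.append(assign_distribution(fit_all_families(y, spec), y).label)
        assert labels.count("NB") >= 4
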