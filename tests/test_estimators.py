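import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.base import clone

from mrkit.estimators import (
    EggerRegressor,
    IVWEstimator,
    WeightedMedianEstimator,
    ivw,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from mrkit.exceptions import (
    EmptyInputError,
    InsufficientInstrumentsError,
    SingularDesignError,
    UndefinedRatioError,
)

from conftest import make_hset


class TestWaldRatio:
    def test_direct_formula(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_effect(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_negative_exposure_beta(self):
        est = wald_ratio(-0.2, 0.01, 0.04, 0.02)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_beta_errors(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_hset([0.1], [0.01], [0.05], [0.01])
        est = ivw(h)
        wald = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(wald.beta, abs=0)
        assert est.se == pytest.approx(wald.se, abs=0)

    def test_homogeneous_rows(self):
        h = make_hset([0.1, 0.2], [0.01, 0.01], [0.03, 0.06], [0.01, 0.01])
        fixed = ivw(h, model="fixed")
        random = ivw(h)
        assert fixed.beta == pytest.approx(0.3)
        # Q = 0 here, so the multiplicative-random SE floors at the fixed SE
        assert random.se == pytest.approx(fixed.se)

    def test_matches_wls_through_origin_oracle(self, rng):
        """100 random 5-SNP instances against statsmodels WLS (no const)."""
        for _ in range(100):
            be = rng.normal(0.05, 0.02, 5)
            be[be == 0] = 0.01
            bo = rng.normal(0.0, 0.05, 5)
            so = rng.uniform(0.01, 0.05, 5)
            h = make_hset(be, rng.uniform(0.005, 0.02, 5), bo, so)
            fit = sm.WLS(bo, be[:, None], weights=1.0 / so**2).fit()
            est = ivw(h, model="fixed")
            assert est.beta == pytest.approx(fit.params[0], rel=1e-9)
            # fixed-effect SE is the unscaled WLS SE
            unscaled = np.sqrt(np.asarray(fit.cov_params(scale=1.0))[0, 0])
            assert est.se == pytest.approx(unscaled, rel=1e-9)

    def test_weight_scale_invariance(self, rng):
        be = rng.normal(0.05, 0.02, 8)
        bo = rng.normal(0.01, 0.03, 8)
        so = rng.uniform(0.01, 0.05, 8)
        h1 = make_hset(be, so, bo, so)
        h2 = make_hset(be, so, bo, so * 3.0)  # w scaled by 1/9
        assert ivw(h1).beta == pytest.approx(ivw(h2).beta, rel=1e-12)

    def test_empty_set_errors(self):
        h = make_hset([], [], [], [])
        with pytest.raises(EmptyInputError):
            ivw(h)

    def test_random_effects_never_deflates(self, rng):
        for _ in range(20):
            be = rng.normal(0.05, 0.02, 10)
            bo = rng.normal(0.0, 0.05, 10)
            so = rng.uniform(0.01, 0.05, 10)
            h = make_hset(be, so, bo, so)
            assert ivw(h).se >= ivw(h, model="fixed").se - 1e-15


class TestEgger:
    def test_planted_line_recovery(self, rng):
        be = rng.uniform(0.02, 0.15, 40)
        bo = 0.02 + 0.4 * be + rng.normal(0, 1e-5, 40)
        h = make_hset(be, np.full(40, 0.01), bo, np.full(40, 0.01))
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-3)
        assert est.intercept == pytest.approx(0.02, abs=1e-3)

    def test_matches_statsmodels_wls_oracle(self, rng):
        be = rng.uniform(0.02, 0.15, 12)
        bo = rng.normal(0.02 + 0.4 * be, 0.02)
        so = rng.uniform(0.01, 0.03, 12)
        h = make_hset(be, so, bo, so)
        est = mr_egger(h)
        fit = sm.WLS(bo, sm.add_constant(be), weights=1.0 / so**2).fit()
        assert est.beta == pytest.approx(fit.params[1], rel=1e-9)
        assert est.intercept == pytest.approx(fit.params[0], rel=1e-9)
        # statsmodels scales by the residual MSE; mrkit floors that at 1
        if fit.mse_resid >= 1.0:
            assert est.se == pytest.approx(fit.bse[1], rel=1e-9)
        else:
            assert est.se >= fit.bse[1]

    def test_degenerate_design_errors(self):
        h = make_hset([0.1, 0.1, 0.1], [0.01] * 3, [0.02, 0.03, 0.04],
                      [0.01] * 3)
        with pytest.raises(SingularDesignError):
            mr_egger(h)

    def test_too_few_instruments(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.02, 0.03], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)

    def test_row_signflip_invariance(self, rng):
        be = rng.uniform(0.02, 0.15, 6)
        bo = rng.normal(0.4 * be, 0.02)
        so = np.full(6, 0.02)
        h1 = make_hset(be, so, bo, so)
        be2, bo2 = be.copy(), bo.copy()
        be2[0] *= -1
        bo2[0] *= -1
        h2 = make_hset(be2, so, bo2, so)
        e1, e2 = mr_egger(h1), mr_egger(h2)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert e1.intercept == pytest.approx(e2.intercept, rel=1e-12)


class TestWeightedMedian:
    def test_odd_equal_weights_is_middle(self):
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.3, 0.9], [0.1] * 3)
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.3)

    def test_matches_percentile_oracle(self, rng):
        """Unequal weights vs a brute-force interpolated weighted
        percentile computed on a fine grid."""
        for _ in range(25):
            be = rng.uniform(0.02, 0.2, 5)
            bo = rng.normal(0.2 * be, 0.02)
            so = rng.uniform(0.01, 0.05, 5)
            r = bo / be
            w = be**2 / so**2
            # oracle: evaluate the piecewise-linear weighted CDF on a grid
            order = np.argsort(r)
            rs, ws = r[order], w[order]
            s = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
            grid = np.linspace(rs[0], rs[-1], 200001)
            cdf = np.interp(grid, rs, s)
            oracle = grid[np.argmin(np.abs(cdf - 0.5))]
            assert weighted_median_point(r, w) == pytest.approx(oracle, abs=1e-4)

    def test_bootstrap_se_deterministic(self):
        h = make_hset([0.1, 0.12, 0.2, 0.05], [0.01] * 4,
                      [0.02, 0.02, 0.05, 0.01], [0.01] * 4)
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        assert a.se == b.se
        assert a.pval == b.pval

    def test_too_few_instruments(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.02, 0.03], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h)


class TestOddsRatio:
    def test_identity(self):
        assert to_odds_ratio(0.0, 0.1)[0] == pytest.approx(1.0)

    def test_known_log_odds(self):
        # ln(1.232) = 0.209 to 3 dp and back
        assert round(to_odds_ratio(0.209, 0.1)[0], 3) == 1.232

    def test_ci_closed_form(self):
        or_, lo, hi = to_odds_ratio(0.5, 0.1)
        assert lo == pytest.approx(np.exp(0.5 - 0.196), rel=1e-12)
        assert hi == pytest.approx(np.exp(0.5 + 0.196), rel=1e-12)

    def test_estimate_invariants(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.or_point == pytest.approx(np.exp(est.beta))
        assert est.ci_low < est.or_point < est.ci_high


class TestSklearnContract:
    def test_get_set_params_and_clone(self):
        est = IVWEstimator(model="fixed")
        assert est.get_params() == {"model": "fixed"}
        est2 = clone(est).set_params(model="multiplicative_random")
        assert est2.get_params()["model"] == "multiplicative_random"
        wm = clone(WeightedMedianEstimator(n_boot=10, random_state=3))
        assert wm.get_params() == {"n_boot": 10, "random_state": 3}

    def test_fitted_attributes_and_predict(self, rng):
        be = rng.uniform(0.02, 0.15, 10)
        bo = 0.3 * be + rng.normal(0, 0.01, 10)
        so = np.full(10, 0.01)
        est = IVWEstimator().fit(be, bo, y_se=so)
        for attr in ("beta_", "se_", "pvalue_", "n_snp_", "q_"):
            assert hasattr(est, attr)
        np.testing.assert_allclose(est.predict(be), est.beta_ * be)
        egger = EggerRegressor().fit(be, bo, y_se=so)
        np.testing.assert_allclose(egger.predict(be),
                                   egger.intercept_ + egger.beta_ * be)
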