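"""Causal-effect estimators for summary-level Mendelian randomization.

Given J harmonized instruments with exposure effects ``beta_exp`` (gamma_j)
and outcome effects ``beta_out`` (Gamma_j), the per-SNP ratio estimate is
r_j = Gamma_j / gamma_j and the first-order weight w_j = gamma_j^2 /
se_out_j^2.  The estimators:

* Wald ratio — single-SNP r with first-order SE ``se_out/|beta_exp|``.
* IVW — Sum(w r)/Sum(w); algebraically the weighted through-origin
  regression of Gamma on gamma with weights 1/se_out^2.  The default is a
  multiplicative random-effects model whose SE inflates the fixed-effect SE
  by max(1, sqrt(Q/(J-1))) and never deflates it.
* MR-Egger — weighted regression *with* intercept after orienting each row
  to a non-negative exposure effect; the intercept estimates the average
  directional pleiotropic effect under the InSIDE assumption.  SEs use the
  same floored multiplicative overdispersion; p-values use t(J-2).
* Weighted median — interpolated weighted 50th percentile of the ratio
  estimates; consistent when up to 50% of the instrument weight comes from
  invalid instruments.  SE by seeded parametric bootstrap.

The classes follow the scikit-learn estimator contract: configuration in
``__init__``, data in ``fit(X, y, ...)``, fitted attributes with a trailing
underscore, ``get_params``/``set_params`` via ``BaseEstimator``.  ``X`` is
the (J, 1) — or (J, K) for multivariable IVW — array of exposure betas and
``y`` the outcome betas; per-SNP standard errors are passed to ``fit`` as
``y_se`` (and ``X_se`` where the method resamples the exposure side).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    EmptyInputError,
    InsufficientInstrumentsError,
    SingularDesignError,
    UndefinedRatioError,
)
from .instruments import HarmonizedSet

Z95 = 1.96  # fixed normal quantile for 95% intervals, matching field reporting


def to_odds_ratio(beta: float, se: float):
    """(OR, 95% CI) on the odds scale: exp(beta), exp(beta -/+ 1.96 se)."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds (or SD) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_point: float
    ci_low: float
    ci_high: float
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_pval: Optional[float] = None

    @classmethod
    def from_beta_se(cls, method, beta, se, pval, n_snp, **kwargs):
        or_point, ci_low, ci_high = to_odds_ratio(beta, se)
        return cls(method=method, beta=float(beta), se=float(se),
                   pval=float(pval), n_snp=int(n_snp), or_point=or_point,
                   ci_low=ci_low, ci_high=ci_high, **kwargs)


_TINY_P = 5e-324  # smallest positive float: keeps p in (0,1] under underflow


def _floor_p(p):
    return float(max(p, _TINY_P))


def _normal_p(beta, se):
    return _floor_p(2.0 * sps.norm.sf(abs(beta) / se))


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows, y has {y.shape[0]}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    return X, y


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance-weighted MR estimator.

    Parameters
    ----------
    model : {"multiplicative_random", "fixed"}
        Fixed-effect SE is (Sum w)^(-1/2); the multiplicative
        random-effects SE multiplies it by max(1, sqrt(Q/(J-1))) for J >= 2.

    Attributes
    ----------
    beta_, se_, pvalue_ : float
        Causal-effect estimate, its SE, and two-sided normal p-value.
    q_, q_df_ : float, int
        Cochran heterogeneity statistic about the fixed-effect center.
    n_snp_ : int
    """

    def __init__(self, model: str = "multiplicative_random"):
        self.model = model

    def fit(self, X, y, *, y_se):
        if self.model not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown IVW model {self.model!r}")
        X, y = _as_xy(X, y)
        if X.shape[1] != 1:
            raise ValueError("IVWEstimator is univariable; use MultivariableIVW")
        be = X[:, 0]
        so = np.asarray(y_se, dtype=float).ravel()
        J = be.size
        if J == 0:
            raise EmptyInputError("IVW requires at least one instrument")
        if np.any(be == 0):
            raise UndefinedRatioError("zero exposure beta makes a ratio undefined")
        r = y / be
        w = be**2 / so**2
        beta = float(np.sum(w * r) / np.sum(w))
        se_fixed = float(np.sum(w) ** -0.5)
        q = float(np.sum(w * (r - beta) ** 2))
        se = se_fixed
        if self.model == "multiplicative_random" and J >= 2:
            se = se_fixed * max(1.0, np.sqrt(q / (J - 1)))
        self.beta_, self.se_ = beta, float(se)
        self.se_fixed_ = se_fixed
        self.q_, self.q_df_ = q, J - 1
        self.pvalue_ = _normal_p(beta, se)
        self.n_snp_ = J
        return self

    def predict(self, X):
        X, _ = _as_xy(X, np.zeros(np.shape(X)[0]))
        return self.beta_ * X[:, 0]

    def to_estimate(self) -> MREstimate:
        return MREstimate.from_beta_se("ivw", self.beta_, self.se_,
                                       self.pvalue_, self.n_snp_)


class EggerRegressor(RegressorMixin, BaseEstimator):
    """MR-Egger: weighted regression of outcome on exposure betas with an
    intercept, after orienting every row to a non-negative exposure beta.

    Attributes: ``beta_`` / ``se_`` / ``pvalue_`` for the slope (causal
    effect) and ``intercept_`` / ``intercept_se_`` / ``intercept_pvalue_``
    for the average pleiotropic effect; p-values from t(J-2).
    """

    MIN_INSTRUMENTS = 3

    def fit(self, X, y, *, y_se):
        X, y = _as_xy(X, y)
        be, bo = X[:, 0], y
        so = np.asarray(y_se, dtype=float).ravel()
        J = be.size
        if J < self.MIN_INSTRUMENTS:
            raise InsufficientInstrumentsError(self.MIN_INSTRUMENTS, J, "MR-Egger")
        sign = np.where(be < 0, -1.0, 1.0)
        x, yv = be * sign, bo * sign
        if np.ptp(x) == 0:
            raise SingularDesignError("all exposure betas equal after orientation")
        w = 1.0 / so**2
        D = np.column_stack([np.ones(J), x])
        xtwx = D.T @ (w[:, None] * D)
        try:
            cov_unscaled = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as err:
            raise SingularDesignError(str(err)) from err
        coef = cov_unscaled @ (D.T @ (w * yv))
        resid = yv - D @ coef
        dof = J - 2
        sigma2 = float(np.sum(w * resid**2) / dof)
        inflate = max(1.0, np.sqrt(sigma2))
        ses = np.sqrt(np.diag(cov_unscaled)) * inflate
        tvals = coef / ses
        pvals = [_floor_p(p) for p in 2.0 * sps.t.sf(np.abs(tvals), dof)]
        self.intercept_, self.beta_ = map(float, coef)
        self.intercept_se_, self.se_ = map(float, ses)
        self.intercept_pvalue_, self.pvalue_ = map(float, pvals)
        self.sigma2_, self.df_ = sigma2, dof
        self.n_snp_ = J
        return self

    def predict(self, X):
        X, _ = _as_xy(X, np.zeros(np.shape(X)[0]))
        return self.intercept_ + self.beta_ * X[:, 0]

    def to_estimate(self) -> MREstimate:
        return MREstimate.from_beta_se(
            "mr_egger", self.beta_, self.se_, self.pvalue_, self.n_snp_,
            intercept=self.intercept_, intercept_se=self.intercept_se_,
            intercept_pval=self.intercept_pvalue_)


def weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted 50th percentile of ratio estimates.

    Order r ascending; with normalized cumulative weights
    s_j = (Sum_{k<=j} w_k - w_j/2) / Sum(w), the estimate is the linear
    interpolation of r at s = 0.5.
    """
    order = np.argsort(r, kind="mergesort")
    r, w = np.asarray(r, float)[order], np.asarray(w, float)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median MR estimator with parametric-bootstrap SE.

    ``random_state`` seeds the bootstrap; with a fixed seed the SE is
    bit-identical across runs.  ``n_boot=0`` skips the bootstrap (point
    estimate only), which is useful inside large simulation studies.
    """

    MIN_INSTRUMENTS = 3

    def __init__(self, n_boot: int = 1000, random_state: Optional[int] = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, *, X_se, y_se):
        X, y = _as_xy(X, y)
        be, bo = X[:, 0], y
        se_e = np.asarray(X_se, dtype=float).ravel()
        so = np.asarray(y_se, dtype=float).ravel()
        J = be.size
        if J < self.MIN_INSTRUMENTS:
            raise InsufficientInstrumentsError(self.MIN_INSTRUMENTS, J, "weighted median")
        r = bo / be
        w = be**2 / so**2
        self.beta_ = weighted_median_point(r, w)
        self.n_snp_ = J
        if self.n_boot:
            rng = np.random.default_rng(self.random_state)
            be_b = be + rng.standard_normal((self.n_boot, J)) * se_e
            bo_b = bo + rng.standard_normal((self.n_boot, J)) * so
            r_b = bo_b / be_b
            w_b = be_b**2 / so**2
            order = np.argsort(r_b, axis=1, kind="mergesort")
            r_s = np.take_along_axis(r_b, order, axis=1)
            w_s = np.take_along_axis(w_b, order, axis=1)
            cum = np.cumsum(w_s, axis=1)
            s = (cum - 0.5 * w_s) / cum[:, -1:]
            boots = np.array([np.interp(0.5, s[i], r_s[i]) for i in range(self.n_boot)])
            self.se_ = float(np.std(boots, ddof=1))
            self.bootstrap_estimates_ = boots
            self.pvalue_ = _normal_p(self.beta_, self.se_)
        else:
            self.se_ = np.nan
            self.pvalue_ = np.nan
        return self

    def to_estimate(self) -> MREstimate:
        return MREstimate.from_beta_se("weighted_median", self.beta_, self.se_,
                                       self.pvalue_, self.n_snp_)


# ---------------------------------------------------------------------------
# Functional wrappers operating on HarmonizedSet
# ---------------------------------------------------------------------------

def wald_ratio(beta_exp, se_exp, beta_out, se_out) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order SE."""
    if beta_exp == 0:
        raise UndefinedRatioError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate.from_beta_se("wald_ratio", beta, se, _normal_p(beta, se), 1)


def ivw(hset: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    est = IVWEstimator(model=model).fit(hset.beta_exp, hset.beta_out,
                                        y_se=hset.se_out)
    return est.to_estimate()


def mr_egger(hset: HarmonizedSet) -> MREstimate:
    return EggerRegressor().fit(hset.beta_exp, hset.beta_out,
                                y_se=hset.se_out).to_estimate()


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: Optional[int] = None) -> MREstimate:
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed)
    est.fit(hset.beta_exp, hset.beta_out, X_se=hset.se_exp, y_se=hset.se_out)
    return est.to_estimate()
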