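"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

The battery mirrors standard two-sample MR practice: Cochran's Q over the
per-SNP ratio estimates (heterogeneity), the MR-Egger intercept test
(directional pleiotropy), MR-PRESSO (simulation-based residual-sum-of-
squares global test with per-SNP outlier detection and outlier-corrected
re-estimation), and leave-one-out IVW (per-SNP influence).  An adjudication
rule then decides which estimate carries the causal claim: the weighted
median replaces IVW as the evaluation method under heterogeneity, a single
instrument allows only a Wald ratio with no assessable diagnostics, and two
instruments leave pleiotropy not assessable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import EggerRegressor, IVWEstimator, MREstimate, _normal_p
from .exceptions import InsufficientInstrumentsError
from .instruments import HarmonizedSet

ALPHA = 0.05


@dataclass(frozen=True)
class PressoResult:
    global_rss_obs: float
    global_pval: float
    outlier_ids: tuple
    outlier_pvals: pd.Series
    corrected_ivw: Optional[MREstimate]
    distortion_pval: Optional[float]
    n_sim: int
    seed: Optional[int]


@dataclass
class SensitivityReport:
    q_stat: Optional[float]
    q_df: Optional[int]
    q_pval: Optional[float]
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None
    presso: Optional[PressoResult] = None
    loo: Optional[pd.DataFrame] = None
    adjudication: str = "not_assessable"
    heterogeneity_flag: bool = False
    pleiotropy_flag: bool = False


def cochran_q(hset: HarmonizedSet):
    """Q = Sum w_j (r_j - beta_IVW_fixed)^2 with first-order weights;
    chi-square upper tail on J-1 df."""
    if hset.J < 2:
        raise InsufficientInstrumentsError(2, hset.J, "Cochran's Q")
    est = IVWEstimator(model="fixed").fit(hset.beta_exp, hset.beta_out,
                                          y_se=hset.se_out)
    q, df = est.q_, est.q_df_
    return q, df, float(max(sps.chi2.sf(q, df), 5e-324))


def egger_intercept_test(hset: HarmonizedSet):
    """(intercept, SE, p) from the MR-Egger regression; flag at p < 0.05."""
    reg = EggerRegressor().fit(hset.beta_exp, hset.beta_out, y_se=hset.se_out)
    return reg.intercept_, reg.intercept_se_, reg.intercept_pvalue_


def _loo_slopes(be, bo, so):
    """Leave-one-out fixed-effect through-origin slopes, O(J) via sums."""
    w = 1.0 / so**2
    sxy, sxx = np.sum(w * be * bo), np.sum(w * be * be)
    return (sxy - w * be * bo) / (sxx - w * be * be)


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000,
              seed: Optional[int] = None,
              outlier_alpha: float = ALPHA) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    Global: observed RSS = Sum_j ((beta_out_j - beta_IVW(-j) * beta_exp_j)
    / se_out_j)^2 with leave-one-out fixed-effect IVW slopes; the null
    distribution comes from ``n_sim`` parametric draws with
    beta_exp* ~ N(beta_exp_j, se_exp_j) and
    beta_out* ~ N(beta_IVW(-j) * beta_exp_j, se_out_j).
    Outliers: per-SNP p = fraction of simulated squared residuals at j
    exceeding the observed one, declared at p < outlier_alpha / J
    (Bonferroni).  Corrected IVW re-runs on the outlier-free set; the
    distortion p compares the raw-vs-corrected shift against removals of
    random same-size SNP subsets (informational only).
    """
    J = hset.J
    if J < 4:
        raise InsufficientInstrumentsError(4, J, "MR-PRESSO")
    be, se_e = hset.beta_exp, hset.se_exp
    bo, so = hset.beta_out, hset.se_out
    rng = np.random.default_rng(seed)

    slopes = _loo_slopes(be, bo, so)
    resid2_obs = ((bo - slopes * be) / so) ** 2
    rss_obs = float(np.sum(resid2_obs))

    be_s = be + rng.standard_normal((n_sim, J)) * se_e
    bo_s = slopes * be + rng.standard_normal((n_sim, J)) * so
    w = 1.0 / so**2
    sxy = np.sum(w * be_s * bo_s, axis=1, keepdims=True)
    sxx = np.sum(w * be_s * be_s, axis=1, keepdims=True)
    slopes_s = (sxy - w * be_s * bo_s) / (sxx - w * be_s * be_s)
    resid2_s = ((bo_s - slopes_s * be_s) / so) ** 2
    rss_s = np.sum(resid2_s, axis=1)

    global_pval = float(np.mean(rss_s >= rss_obs))
    outlier_pvals = pd.Series(np.mean(resid2_s >= resid2_obs, axis=0),
                              index=hset.variant_ids, name="presso_outlier_p")
    is_out = outlier_pvals < outlier_alpha / J
    outlier_ids = tuple(outlier_pvals.index[is_out])

    corrected = None
    distortion_pval = None
    n_out = len(outlier_ids)
    if 0 < n_out < J:
        kept = hset.drop(outlier_ids)
        corrected = IVWEstimator().fit(kept.beta_exp, kept.beta_out,
                                       y_se=kept.se_out).to_estimate()
        raw = IVWEstimator().fit(be, bo, y_se=so)
        d_obs = corrected.beta - raw.beta_
        # Null: remove random subsets of the same size, fixed-effect slope.
        ranks = rng.random((n_sim, J)).argsort(axis=1)
        drop_mask = ranks < n_out
        wfull = be**2 / so**2
        r = bo / be
        num = np.sum(wfull * r) - np.sum(np.where(drop_mask, wfull * r, 0.0), axis=1)
        den = np.sum(wfull) - np.sum(np.where(drop_mask, wfull, 0.0), axis=1)
        d_null = num / den - raw.beta_
        distortion_pval = float(np.mean(np.abs(d_null) >= abs(d_obs)))

    return PressoResult(global_rss_obs=rss_obs, global_pval=global_pval,
                        outlier_ids=outlier_ids, outlier_pvals=outlier_pvals,
                        corrected_ivw=corrected, distortion_pval=distortion_pval,
                        n_sim=n_sim, seed=seed)


def leave_one_out(hset: HarmonizedSet,
                  model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW estimate excluding each SNP in turn; flags exclusions that flip
    the sign of beta or move p across 0.05."""
    J = hset.J
    if J < 2:
        raise InsufficientInstrumentsError(2, J, "leave-one-out")
    full = IVWEstimator(model=model).fit(hset.beta_exp, hset.beta_out,
                                         y_se=hset.se_out)
    rows = []
    for vid in hset.variant_ids:
        sub = hset.drop([vid])
        est = IVWEstimator(model=model).fit(sub.beta_exp, sub.beta_out,
                                            y_se=sub.se_out)
        rows.append({
            "excluded": vid,
            "beta": est.beta_,
            "se": est.se_,
            "pval": est.pvalue_,
            "delta_beta": est.beta_ - full.beta_,
            "sign_change": np.sign(est.beta_) != np.sign(full.beta_),
            "crosses_0.05": (est.pvalue_ < ALPHA) != (full.pvalue_ < ALPHA),
        })
    return pd.DataFrame(rows)


def adjudicate_robustness(ivw_est: Optional[MREstimate],
                          wm_est: Optional[MREstimate],
                          *,
                          j: int,
                          q: Optional[tuple] = None,
                          egger: Optional[tuple] = None,
                          presso: Optional[PressoResult] = None,
                          loo: Optional[pd.DataFrame] = None) -> SensitivityReport:
    """Decide which estimate carries the causal claim.

    J = 1 -> ``wald_only`` (no diagnostics computable).  J >= 3 with
    heterogeneity (Q p < 0.05) -> ``wm_primary``: the weighted median is
    the evaluation method and the claim stands only if it is significant
    with the same sign as IVW.  Otherwise ``ivw_primary``; at J = 2
    pleiotropy is not assessable but IVW remains primary.
    """
    q_stat = q_df = q_pval = None
    if q is not None:
        q_stat, q_df, q_pval = q
    report = SensitivityReport(q_stat=q_stat, q_df=q_df, q_pval=q_pval,
                               presso=presso, loo=loo)
    if egger is not None:
        (report.egger_intercept, report.egger_intercept_se,
         report.egger_intercept_pval) = egger
        report.pleiotropy_flag = report.egger_intercept_pval < ALPHA
    if q_pval is not None:
        report.heterogeneity_flag = q_pval < ALPHA

    if j <= 1:
        report.adjudication = "wald_only" if j == 1 else "not_assessable"
    elif j >= 3 and report.heterogeneity_flag and wm_est is not None:
        report.adjudication = "wm_primary"
    else:
        report.adjudication = "ivw_primary"
    return report
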