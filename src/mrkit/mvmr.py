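"""Multivariable MR: joint direct effects of K exposures on one outcome.

Instruments are the union of SNPs genome-wide significant for at least one
exposure, jointly LD-clumped using each SNP's minimum p across exposures,
then MAF/palindrome/F filtered and intersected with every exposure table
and the outcome.  The direct effects come from the weighted multiple
regression (no intercept) of outcome betas on the K exposure-beta columns
with weights 1/se_out^2; per-exposure SEs carry the same floored
multiplicative overdispersion as univariable IVW, with J-K residual df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .estimators import MREstimate, _normal_p
from .exceptions import CollinearityError, UnderIdentifiedError
from .instruments import (
    HarmonizedSet,
    _orientation,
    compute_f_statistics,
    filter_maf_and_palindromes,
    ld_clump,
    select_by_pvalue,
)
from .ld import LDInfo
from .summary_io import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class MVHarmonizedSet:
    """Per-SNP exposure-beta matrix and outcome effects, one effect allele.

    ``df`` columns: variant_id, beta_exp_<id>/se_exp_<id> per exposure,
    beta_out, se_out.  ``n_snp_per_exposure`` counts, for each exposure,
    the retained union SNPs that are genome-wide significant for it (the
    per-exposure instrument-count convention used in reporting).
    """

    exposure_ids: List[str]
    outcome_id: str
    df: pd.DataFrame
    n_snp_per_exposure: Dict[str, int]

    @property
    def J(self) -> int:
        return len(self.df)

    @property
    def K(self) -> int:
        return len(self.exposure_ids)

    def beta_matrix(self) -> np.ndarray:
        return self.df[[f"beta_exp_{e}" for e in self.exposure_ids]].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(float)


def build_mvmr_design(exposures: Sequence[SummaryStats], outcome: SummaryStats,
                      ld: Optional[LDInfo] = None, pval_threshold: float = 5e-8,
                      r2_max: float = 0.001, window_kb: float = 10000.0,
                      maf_min: float = 0.01, f_threshold: float = 10.0,
                      exclusion_list=None) -> MVHarmonizedSet:
    """Assemble the joint instrument set and allele-align all tables."""
    if len(exposures) < 2:
        raise ValueError("MVMR needs at least two exposures")
    frames = {e.trait_id: e.df.set_index("variant_id") for e in exposures}
    out_frame = outcome.df.set_index("variant_id")

    sig_sets = {e.trait_id: set(select_by_pvalue(e, pval_threshold).df["variant_id"])
                for e in exposures}
    union_ids = sorted(set().union(*sig_sets.values()))

    # Reference rows: for each union SNP take the exposure where it is most
    # significant; that row supplies alleles, eaf, position, and clumping p.
    ref_rows = []
    for vid in union_ids:
        best = min((e.trait_id for e in exposures if vid in frames[e.trait_id].index),
                   key=lambda t: frames[t].loc[vid, "pval"])
        rec = frames[best].loc[vid].to_dict()
        rec["variant_id"] = vid
        ref_rows.append(rec)
    ref = SummaryStats("mvmr_union", pd.DataFrame(ref_rows).reset_index(drop=True),
                       exposures[0].effect_scale)

    if ld is not None and ref.n_variants > 1:
        ref = ld_clump(ref, ld, r2_max=r2_max, window_kb=window_kb)
    ref = filter_maf_and_palindromes(ref, maf_min=maf_min)
    ref = compute_f_statistics(ref, f_threshold=f_threshold)

    exclusion = set(exclusion_list or ())
    rows = []
    for rec in ref.df.to_dict("records"):
        vid = rec["variant_id"]
        if vid in exclusion:
            continue
        if vid not in out_frame.index or \
                any(vid not in frames[t].index for t in frames):
            continue
        row = {"variant_id": vid}
        ok = True
        for trait, frame in frames.items():
            erec = frame.loc[vid]
            sign = _orientation(rec["effect_allele"], rec["other_allele"],
                                erec["effect_allele"], erec["other_allele"])
            if sign is None:
                ok = False
                break
            row[f"beta_exp_{trait}"] = sign * erec["beta"]
            row[f"se_exp_{trait}"] = erec["se"]
            row[f"pval_exp_{trait}"] = erec["pval"]
        if not ok:
            continue
        orec = out_frame.loc[vid]
        sign = _orientation(rec["effect_allele"], rec["other_allele"],
                            orec["effect_allele"], orec["other_allele"])
        if sign is None:
            continue
        row["beta_out"] = sign * orec["beta"]
        row["se_out"] = orec["se"]
        rows.append(row)

    ids = [e.trait_id for e in exposures]
    df = pd.DataFrame(rows)
    if len(df) <= len(ids):
        raise UnderIdentifiedError(
            f"MVMR design has J={len(df)} SNPs for K={len(ids)} exposures")
    counts = {t: int((df["variant_id"].isin(sig_sets[t])).sum()) for t in ids}
    logger.info("MVMR design: J=%d union SNPs; per-exposure significant counts %s",
                len(df), counts)
    return MVHarmonizedSet(ids, outcome.trait_id, df.reset_index(drop=True), counts)


class MultivariableIVW(BaseEstimator):
    """Weighted multiple regression of outcome betas on exposure betas.

    ``fit(X, y, y_se)`` with X the (J, K) exposure-beta matrix.  Fitted
    attributes are arrays aligned with the columns of X: ``beta_``,
    ``se_``, ``pvalue_``; plus ``q_res_`` (weighted residual SS) and the
    overdispersion ``inflation_``.
    """

    def __init__(self, min_overdispersion: float = 1.0):
        self.min_overdispersion = min_overdispersion

    def fit(self, X, y, *, y_se, exposure_ids: Optional[Sequence[str]] = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        so = np.asarray(y_se, dtype=float).ravel()
        J, K = X.shape
        ids = list(exposure_ids) if exposure_ids is not None else \
            [f"x{k}" for k in range(K)]
        if J <= K:
            raise UnderIdentifiedError(f"J={J} <= K={K}")
        w = 1.0 / so**2
        xtwx = X.T @ (w[:, None] * X)
        if np.linalg.matrix_rank(xtwx) < K:
            offending = [ids[k] for k in range(K) if np.ptp(X[:, k]) == 0]
            for a, b in combinations(range(K), 2):
                c = np.corrcoef(X[:, a], X[:, b])[0, 1]
                if abs(c) > 1 - 1e-12:
                    offending.extend([ids[a], ids[b]])
            raise CollinearityError(sorted(set(offending)) or ids)
        cov_unscaled = np.linalg.inv(xtwx)
        coef = cov_unscaled @ (X.T @ (w * y))
        resid = y - X @ coef
        q_res = float(np.sum(w * resid**2))
        inflation = max(self.min_overdispersion, np.sqrt(q_res / (J - K)))
        ses = np.sqrt(np.diag(cov_unscaled)) * inflation
        self.beta_ = coef
        self.se_ = ses
        self.pvalue_ = np.maximum(2.0 * sps.norm.sf(np.abs(coef) / ses), 5e-324)
        self.q_res_, self.inflation_ = q_res, float(inflation)
        self.n_snp_, self.exposure_ids_ = J, ids
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.beta_


def mvmr_ivw(design: MVHarmonizedSet) -> Dict[str, MREstimate]:
    """Per-exposure direct-effect estimates from the joint regression."""
    est = MultivariableIVW().fit(design.beta_matrix(), design.beta_out,
                                 y_se=design.se_out,
                                 exposure_ids=design.exposure_ids)
    out = {}
    for k, trait in enumerate(design.exposure_ids):
        out[trait] = MREstimate.from_beta_se(
            "mvmr_ivw", est.beta_[k], est.se_[k], est.pvalue_[k],
            design.n_snp_per_exposure.get(trait, design.J))
    return out
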