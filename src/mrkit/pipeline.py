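"""Screen orchestration: exposures x outcomes, classification, mediation.

For each exposure-outcome pair the pipeline selects instruments, harmonizes
the pair, and dispatches estimators by the surviving SNP count J: a single
Wald ratio at J = 1; IVW plus Cochran's Q at J = 2; MR-Egger and the
weighted median join at J >= 3; MR-PRESSO at J >= 4.  The primary p-value
is then classified against a Bonferroni threshold alpha / (n_exposures x
n_outcomes): below it "significant", between it and 0.05 "suggestive",
otherwise "null"; claims withdrawn by the adjudication rule (weighted
median non-significant under heterogeneity, or a single-instrument pair)
are "not_established".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw, mr_egger, wald_ratio, weighted_median
from .exceptions import EmptyInputError, MRKitError
from .instruments import HarmonizedSet, harmonize, select_instruments
from .ld import LDInfo
from .mediation import MediationResult, mediation_effect
from .sensitivity import (
    SensitivityReport,
    adjudicate_robustness,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_presso,
)
from .summary_io import SummaryStats

logger = logging.getLogger(__name__)

ALPHA = 0.05


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def bonferroni_threshold(n_exposures: int, n_outcomes: int,
                         alpha: float = ALPHA) -> float:
    """alpha / (n_exposures * n_outcomes), full precision.

    Printed at 3 significant figures in reports; comparisons always use
    the full-precision value to avoid rounding boundary artifacts.
    """
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_exposures * n_outcomes)


def classify_association(primary_pval: float, threshold: float) -> str:
    if not 0 < primary_pval <= 1:
        raise ValueError(f"p-value {primary_pval} outside (0,1]")
    if not threshold < ALPHA:
        raise ValueError("Bonferroni threshold must be below 0.05")
    if primary_pval < threshold:
        return "significant"
    if primary_pval < ALPHA:
        return "suggestive"
    return "null"


@dataclass
class ScreenConfig:
    seed: int
    pval_threshold: float = 5e-8
    r2_max: float = 0.001
    window_kb: float = 10000.0
    maf_min: float = 0.01
    f_threshold: float = 10.0
    n_boot: int = 1000
    presso_n_sim: int = 1000
    alpha: float = ALPHA
    n_tests: Optional[int] = None  # Bonferroni denominator override
    exclusion_list: Sequence[str] = ()


@dataclass
class ScreenResult:
    exposure_id: str
    outcome_id: str
    estimates: Dict[str, MREstimate]
    sensitivity: Optional[SensitivityReport]
    classification: str
    n_snp_used: int
    attrition: Dict[str, int] = field(default_factory=dict)

    @property
    def primary(self) -> Optional[MREstimate]:
        if "ivw" in self.estimates:
            return self.estimates["ivw"]
        return self.estimates.get("wald_ratio")


def analyse_pair(hset: HarmonizedSet, config: ScreenConfig,
                 seed: Optional[int] = None):
    """Method dispatch by J; returns (estimates dict, SensitivityReport)."""
    J = hset.J
    seed = config.seed if seed is None else seed
    estimates: Dict[str, MREstimate] = {}
    if J == 1:
        row = hset.df.iloc[0]
        estimates["wald_ratio"] = wald_ratio(row["beta_exp"], row["se_exp"],
                                             row["beta_out"], row["se_out"])
        report = adjudicate_robustness(None, None, j=1)
        return estimates, report

    ivw_est = ivw(hset)
    estimates["ivw"] = ivw_est
    q = cochran_q(hset)
    wm_est = egger = presso = None
    if J >= 3:
        estimates["mr_egger"] = mr_egger(hset)
        egger = egger_intercept_test(hset)
        wm_est = weighted_median(hset, n_boot=config.n_boot, seed=seed)
        estimates["weighted_median"] = wm_est
    if J >= 4:
        presso = mr_presso(hset, n_sim=config.presso_n_sim, seed=seed)
    loo = leave_one_out(hset)
    report = adjudicate_robustness(ivw_est, wm_est, j=J, q=q, egger=egger,
                                   presso=presso, loo=loo)
    return estimates, report


def _classify(estimates, report, threshold) -> str:
    if report is None or not estimates:
        return "not_established"
    if report.adjudication in ("wald_only", "not_assessable"):
        # A single instrument leaves the diagnostics unassessable: no claim.
        return "not_established"
    ivw_est = estimates.get("ivw")
    if report.adjudication == "wm_primary":
        wm = estimates.get("weighted_median")
        if wm is None or wm.pval >= ALPHA or \
                np.sign(wm.beta) != np.sign(ivw_est.beta):
            return "not_established"
    if threshold >= ALPHA:
        # Single-test screen: no suggestive band below the ceiling.
        return "significant" if ivw_est.pval < threshold else "null"
    return classify_association(ivw_est.pval, threshold)


def run_screen(exposures: Sequence[SummaryStats],
               outcomes: Sequence[SummaryStats],
               config: ScreenConfig,
               ld: Optional[LDInfo] = None) -> List[ScreenResult]:
    """Screen every exposure-outcome pair; never crashes on an empty pair."""
    if not exposures or not outcomes:
        raise MRKitError("need at least one exposure and one outcome")
    n_tests = config.n_tests or len(exposures) * len(outcomes)
    threshold = bonferroni_threshold(1, n_tests, config.alpha)
    results = []
    for i, exp in enumerate(exposures):
        attrition_base: Dict[str, int] = {}
        inst = select_instruments(
            exp, ld=ld, pval_threshold=config.pval_threshold,
            r2_max=config.r2_max, window_kb=config.window_kb,
            maf_min=config.maf_min, f_threshold=config.f_threshold,
            attrition=attrition_base)
        for k, out in enumerate(outcomes):
            attrition = dict(attrition_base)
            pair_seed = (config.seed + 1009 * i + 31 * k) % (2**31 - 1)
            try:
                hset = harmonize(inst, out, config.exclusion_list)
            except EmptyInputError:
                logger.info("pair %s->%s: no instruments survive; "
                            "not established", exp.trait_id, out.trait_id)
                attrition["n_harmonized"] = 0
                results.append(ScreenResult(exp.trait_id, out.trait_id, {},
                                            None, "not_established", 0,
                                            attrition))
                continue
            attrition["n_harmonized"] = hset.J
            estimates, report = analyse_pair(hset, config, seed=pair_seed)
            classification = _classify(estimates, report, threshold)
            results.append(ScreenResult(exp.trait_id, out.trait_id, estimates,
                                        report, classification, hset.J,
                                        attrition))
    return results


def run_mediation_stage(exposure: SummaryStats,
                        mediators: Sequence[SummaryStats],
                        outcomes: Sequence[SummaryStats],
                        config: ScreenConfig,
                        ld: Optional[LDInfo] = None,
                        profile: str = "full_precision",
                        screen_results: Optional[List[ScreenResult]] = None,
                        ) -> List[MediationResult]:
    """Two-step decomposition for each mediator x outcome.

    beta1 comes from the exposure -> outcome screen (reused if supplied),
    beta2 from exposure -> mediator, beta3 from mediator -> outcome.
    Triplets whose mediator -> outcome link is not established (primary
    p >= 0.05 or withdrawn) are emitted flagged rather than dropped.
    """
    if screen_results is None:
        screen_results = run_screen([exposure], list(outcomes), config, ld=ld)
    beta1 = {r.outcome_id: r for r in screen_results
             if r.exposure_id == exposure.trait_id}
    step2 = {r.outcome_id: r
             for r in run_screen([exposure], list(mediators), config, ld=ld)}
    results = []
    for med in mediators:
        r2 = step2.get(med.trait_id)
        step3 = {r.outcome_id: r
                 for r in run_screen([med], list(outcomes), config, ld=ld)}
        for out in outcomes:
            r1, r3 = beta1.get(out.trait_id), step3.get(out.trait_id)
            if r1 is None or r1.primary is None or r2 is None or \
                    r2.primary is None or r3 is None or r3.primary is None:
                raise MRKitError(
                    f"incomplete triplet {exposure.trait_id}->"
                    f"{med.trait_id}->{out.trait_id}")
            established = (r3.classification in ("significant", "suggestive"))
            res = mediation_effect(
                r1.primary.beta, r2.primary.beta, r3.primary.beta,
                profile=profile, exposure_id=exposure.trait_id,
                mediator_id=med.trait_id, outcome_id=out.trait_id,
                se2=r2.primary.se, se3=r3.primary.se)
            if not established:
                res = MediationResult(
                    res.exposure_id, res.mediator_id, res.outcome_id,
                    res.beta1, res.beta2, res.beta3, res.mediated_effect,
                    res.proportion_pct, res.rounding_profile,
                    flag="not_established", mediated_se=res.mediated_se)
            results.append(res)
    return results


# ---------------------------------------------------------------------------
# Tidy report writers (tabular, mirroring the standard reporting layout)
# ---------------------------------------------------------------------------

def estimates_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """exposure, outcome, method, n_snp, beta, se, pval, OR with CI, plus
    heterogeneity/pleiotropy p columns."""
    rows = []
    for res in results:
        q_p = egger_p = None
        if res.sensitivity is not None:
            q_p = res.sensitivity.q_pval
            egger_p = res.sensitivity.egger_intercept_pval
        if not res.estimates:
            rows.append({"exposure": res.exposure_id, "outcome": res.outcome_id,
                         "method": None, "n_snp": 0, "classification":
                         res.classification})
            continue
        for method, est in res.estimates.items():
            rows.append({
                "exposure": res.exposure_id,
                "outcome": res.outcome_id,
                "method": method,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "OR": round(est.or_point, 3),
                "CI_low": round(est.ci_low, 3),
                "CI_high": round(est.ci_high, 3),
                "cochran_q_p": q_p,
                "egger_intercept_p": egger_p,
                "classification": res.classification,
            })
    return pd.DataFrame(rows)


def format_or_ci(est: MREstimate) -> str:
    return f"{est.or_point:.3f} ({est.ci_low:.3f}-{est.ci_high:.3f})"
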