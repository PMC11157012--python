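"""Instrument selection and exposure–outcome harmonization.

Instruments are chosen from the exposure GWAS by (1) genome-wide
significance (p < 5e-8, strict), (2) greedy LD clumping at r^2 < 0.001
within a 10,000 kb window, (3) exclusion of rare (MAF <= 0.01, inclusive)
and palindromic (A/T, C/G) SNPs, and (4) an instrument-strength filter
F = beta^2/se^2 >= 10.  Harmonization then aligns the outcome table to the
exposure's effect alleles, resolving strand complements and dropping
unresolvable rows and any user-listed confounder-associated SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError
from .ld import LDInfo
from .summary_io import SummaryStats

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Exposure–outcome instrument table with aligned effect alleles.

    ``df`` holds one row per SNP with ``variant_id, beta_exp, se_exp,
    beta_out, se_out`` (plus ``pval_exp, eaf_exp, f_stat, effect_allele,
    other_allele`` when available).  ``beta_out`` is oriented to the same
    effect allele as ``beta_exp`` for every row.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame

    @property
    def J(self) -> int:
        return len(self.df)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(dtype=float)

    @property
    def variant_ids(self) -> list:
        return self.df["variant_id"].tolist()

    def drop(self, variant_ids) -> "HarmonizedSet":
        keep = ~self.df["variant_id"].isin(set(variant_ids))
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.df.loc[keep].reset_index(drop=True))


def select_by_pvalue(stats: SummaryStats, threshold: float = 5e-8) -> SummaryStats:
    """Keep rows with p strictly below ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    keep = stats.df["pval"] < threshold
    return SummaryStats(stats.trait_id, stats.df.loc[keep].reset_index(drop=True),
                        stats.effect_scale, stats.sample_size_default)


def _within_window(row_a, row_b, window_kb: float) -> bool:
    """Distance rule: candidates farther than the window are never clumped."""
    ca, cb = row_a.get("chrom"), row_b.get("chrom")
    pa, pb = row_a.get("pos"), row_b.get("pos")
    if pd.notna(ca) and pd.notna(cb) and str(ca) != str(cb):
        return False
    if pd.notna(pa) and pd.notna(pb):
        return abs(float(pa) - float(pb)) < window_kb * 1000.0
    # No positional information: conservatively treat as within the window
    # so that LD is always consulted rather than assumed absent.
    return True


def ld_clump(stats: SummaryStats, ld: LDInfo, r2_max: float = 0.001,
             window_kb: float = 10000.0) -> SummaryStats:
    """Greedy clumping: keep the lowest-p remaining SNP, discard its
    neighbours with r^2 >= ``r2_max`` within ``window_kb``; repeat.

    Output is ordered by ascending p.  A missing r^2 for a pair inside the
    window is a hard error (independence is never silently assumed).
    """
    rows = stats.df.sort_values("pval", kind="mergesort").to_dict("records")
    kept = []
    while rows:
        index = rows.pop(0)
        kept.append(index)
        survivors = []
        for cand in rows:
            if _within_window(index, cand, window_kb) and \
                    ld.r2(index["variant_id"], cand["variant_id"]) >= r2_max:
                continue
            survivors.append(cand)
        rows = survivors
    out = pd.DataFrame(kept, columns=stats.df.columns)
    logger.info("%s: LD clumping kept %d of %d SNPs", stats.trait_id,
                len(out), stats.n_variants)
    return SummaryStats(stats.trait_id, out.reset_index(drop=True),
                        stats.effect_scale, stats.sample_size_default)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return {effect_allele, other_allele} in _PALINDROMIC


def filter_maf_and_palindromes(stats: SummaryStats, maf_min: float = 0.01) -> SummaryStats:
    """Drop rows with MAF <= ``maf_min`` (inclusive) or palindromic alleles."""
    eaf = stats.df["eaf"]
    maf = np.minimum(eaf, 1.0 - eaf)
    palin = [
        is_palindromic(ea, oa)
        for ea, oa in zip(stats.df["effect_allele"], stats.df["other_allele"])
    ]
    keep = (maf > maf_min) & ~pd.Series(palin, index=stats.df.index)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: MAF/palindrome filter dropped %d SNPs", stats.trait_id, dropped)
    return SummaryStats(stats.trait_id, stats.df.loc[keep].reset_index(drop=True),
                        stats.effect_scale, stats.sample_size_default)


def compute_f_statistics(stats: SummaryStats, f_threshold: float = 10.0) -> SummaryStats:
    """Attach per-SNP F = beta^2/se^2 and drop SNPs with F below threshold."""
    df = stats.df.copy()
    df["f_stat"] = (df["beta"] / df["se"]) ** 2
    keep = df["f_stat"] >= f_threshold
    out = df.loc[keep].reset_index(drop=True)
    if len(out):
        logger.info("%s: F filter kept %d/%d SNPs, mean F = %.1f",
                    stats.trait_id, len(out), len(df), out["f_stat"].mean())
    else:
        logger.info("%s: F filter removed all %d SNPs", stats.trait_id, len(df))
    return SummaryStats(stats.trait_id, out, stats.effect_scale,
                        stats.sample_size_default)


def _orientation(exp_ea, exp_oa, out_ea, out_oa):
    """Classify the outcome allele pair relative to the exposure's.

    Returns +1 (same orientation), -1 (effect/other swapped: flip the
    outcome beta), or None (unresolvable).  Palindromic pairs are
    unresolvable by construction (they match both patterns).
    """
    if is_palindromic(exp_ea, exp_oa) or is_palindromic(out_ea, out_oa):
        return None
    cea, coa = _COMPLEMENT[exp_ea], _COMPLEMENT[exp_oa]
    if (out_ea, out_oa) in ((exp_ea, exp_oa), (cea, coa)):
        return 1
    if (out_ea, out_oa) in ((exp_oa, exp_ea), (coa, cea)):
        return -1
    return None


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              exclusion_list: Optional[Iterable[str]] = None) -> HarmonizedSet:
    """Intersect exposure instruments with the outcome table and align
    outcome effects to the exposure's effect alleles.

    Where the outcome's effect allele equals the exposure's other allele
    (or its strand complement), the outcome beta is negated and its alleles
    swapped.  Unresolvable allele pairs and exclusion-listed SNPs are
    dropped with logged reasons.
    """
    exclusion = set(exclusion_list or ())
    exp = exposure.df
    out = outcome.df.set_index("variant_id")
    rows, dropped = [], {"not_in_outcome": 0, "excluded": 0, "allele_mismatch": 0}
    for rec in exp.to_dict("records"):
        vid = rec["variant_id"]
        if vid not in out.index:
            dropped["not_in_outcome"] += 1
            continue
        if vid in exclusion:
            dropped["excluded"] += 1
            continue
        orec = out.loc[vid]
        sign = _orientation(rec["effect_allele"], rec["other_allele"],
                            orec["effect_allele"], orec["other_allele"])
        if sign is None:
            dropped["allele_mismatch"] += 1
            continue
        rows.append({
            "variant_id": vid,
            "effect_allele": rec["effect_allele"],
            "other_allele": rec["other_allele"],
            "eaf_exp": rec["eaf"],
            "beta_exp": rec["beta"],
            "se_exp": rec["se"],
            "pval_exp": rec["pval"],
            "f_stat": rec.get("f_stat", np.nan),
            "beta_out": sign * orec["beta"],
            "se_out": orec["se"],
        })
    detail = ", ".join(f"{k}={v}" for k, v in dropped.items() if v)
    if detail:
        logger.info("harmonize %s->%s: dropped (%s)", exposure.trait_id,
                    outcome.trait_id, detail)
    if not rows:
        raise EmptyInputError(
            f"no instruments remain for {exposure.trait_id} -> {outcome.trait_id} "
            f"(drop reasons: {dropped})"
        )
    return HarmonizedSet(exposure.trait_id, outcome.trait_id,
                         pd.DataFrame(rows))


def select_instruments(stats: SummaryStats, ld: Optional[LDInfo] = None,
                       pval_threshold: float = 5e-8, r2_max: float = 0.001,
                       window_kb: float = 10000.0, maf_min: float = 0.01,
                       f_threshold: float = 10.0,
                       attrition: Optional[dict] = None) -> SummaryStats:
    """Full selection cascade; optionally records per-filter attrition."""
    log = attrition if attrition is not None else {}
    log["n_total"] = stats.n_variants
    sig = select_by_pvalue(stats, pval_threshold)
    log["n_significant"] = sig.n_variants
    if ld is not None and sig.n_variants > 1:
        sig = ld_clump(sig, ld, r2_max=r2_max, window_kb=window_kb)
    log["n_after_clump"] = sig.n_variants
    sig = filter_maf_and_palindromes(sig, maf_min=maf_min)
    log["n_after_maf_palindrome"] = sig.n_variants
    sig = compute_f_statistics(sig, f_threshold=f_threshold)
    log["n_after_f"] = sig.n_variants
    return sig
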