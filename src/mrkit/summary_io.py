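"""Read, validate, and write per-variant GWAS summary-statistics tables.

The canonical on-disk dialect is tab-delimited with a header row and the
columns ``variant_id, effect_allele, other_allele, eaf, beta, se, pval, n``
(optionally ``chrom, pos``); ``NA`` or ``.`` mark missing values.  This is
the common exchange format used by public summary-statistics repositories.
Only biallelic SNPs are accepted: multi-base or non-ACGT alleles (indels,
multi-allelic records) are rejected at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

#: Canonical column order for the on-disk dialect.
CANONICAL_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]
OPTIONAL_COLUMNS = ["n", "chrom", "pos"]
MANDATORY_COLUMNS = [c for c in CANONICAL_COLUMNS if c not in OPTIONAL_COLUMNS]

_VALID_ALLELES = frozenset("ACGT")


@dataclass
class SummaryStats:
    """Per-variant GWAS association table for one trait.

    Attributes
    ----------
    trait_id : str
        Label for the trait (e.g. ``"GERD"``, ``"AS"``).
    df : pandas.DataFrame
        One row per biallelic SNP with the canonical columns; ``n``,
        ``chrom`` and ``pos`` may be missing (``pd.NA``).
    effect_scale : str
        ``"log_odds"`` for binary traits, ``"sd_units"`` for continuous
        ones.  Declared by the user; never inferred from the data.
    sample_size_default : int or None
        Fallback GWAS sample size when ``n`` is absent per variant.
    """

    trait_id: str
    df: pd.DataFrame
    effect_scale: str = "log_odds"
    sample_size_default: Optional[int] = None

    def __post_init__(self):
        if self.effect_scale not in ("log_odds", "sd_units"):
            raise ConfigurationError(
                f"effect_scale must be 'log_odds' or 'sd_units', got {self.effect_scale!r}"
            )
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise ConfigurationError(
                f"duplicate variant ids in {self.trait_id}: {sorted(set(dups))[:5]}"
            )

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def subset(self, variant_ids) -> "SummaryStats":
        """Return a new table restricted to ``variant_ids`` (original order)."""
        keep = self.df["variant_id"].isin(set(variant_ids))
        return SummaryStats(
            self.trait_id,
            self.df.loc[keep].reset_index(drop=True),
            self.effect_scale,
            self.sample_size_default,
        )


def _validate_rows(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Drop rows violating per-variant invariants; log a per-reason count."""
    reasons = {}

    def _mark(name, bad):
        reasons[name] = int(bad.sum())
        return bad

    numeric = ["eaf", "beta", "se", "pval"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = _mark("non_numeric", df[numeric].isna().any(axis=1))
    bad |= _mark("se_nonpositive", ~bad & ~(df["se"] > 0))
    bad |= _mark("eaf_out_of_range", ~bad & ~((df["eaf"] > 0) & (df["eaf"] < 1)))
    bad |= _mark("pval_out_of_range", ~bad & ~((df["pval"] > 0) & (df["pval"] <= 1)))
    ea, oa = df["effect_allele"], df["other_allele"]
    snp_ok = ea.isin(_VALID_ALLELES) & oa.isin(_VALID_ALLELES)
    bad |= _mark("not_biallelic_snp", ~bad & ~snp_ok)
    bad |= _mark("identical_alleles", ~bad & snp_ok & (ea == oa))
    bad |= _mark("duplicate_id", ~bad & df["variant_id"].duplicated(keep="first"))

    dropped = int(bad.sum())
    if dropped:
        detail = ", ".join(f"{k}={v}" for k, v in reasons.items() if v)
        logger.info("%s: dropped %d invalid rows (%s)", trait_id, dropped, detail)
    return df.loc[~bad].reset_index(drop=True)


def read_summary_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_id: Optional[str] = None,
    effect_scale: str = "log_odds",
    sample_size_default: Optional[int] = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"variant_id": "SNP", "pval": "p"}``; unmapped canonical names are
    assumed to appear verbatim in the header.  Rows violating the
    per-variant invariants are dropped with a logged count; alleles are
    upper-cased before validation.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, na_values=["NA", "."], dtype={0: str})
    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS + ["chrom", "pos"]:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in MANDATORY_COLUMNS:
            raise ConfigurationError(
                f"{path}: mandatory column {canonical!r} (mapped from {source!r}) "
                f"not found in header {list(raw.columns)}"
            )
    df = raw.rename(columns=rename)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[CANONICAL_COLUMNS + ["chrom", "pos"]].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    df["n"] = pd.to_numeric(df["n"], errors="coerce").astype("Int64")
    df["chrom"] = df["chrom"].astype("string")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")

    df = _validate_rows(df, trait_id or path.stem)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: zero valid rows after validation")
    return SummaryStats(
        trait_id=trait_id or path.stem,
        df=df,
        effect_scale=effect_scale,
        sample_size_default=sample_size_default,
    )


def write_summary_table(stats: SummaryStats, path) -> Path:
    """Write the canonical tab-delimited dialect; returns the path written."""
    path = Path(path)
    out = stats.df.copy()
    cols = CANONICAL_COLUMNS + [c for c in ("chrom", "pos") if out[c].notna().any()]
    out[cols].to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
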