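"""Synthetic GWAS summary statistics under a fully specified causal model.

The generator emits exposure / (mediator) / outcome association tables of
the exact dialect ``summary_io`` reads, plus the matching LD source and a
per-SNP truth record, so every pipeline stage is testable without any
download.

Model.  For SNP j with effect-allele frequency u_j ~ Uniform(eaf_range):

* true SNP-exposure effect gamma_j: magnitude |N(0, gamma_sd)| floored at
  ``gamma_floor_z`` exposure-side standard errors (so that the true
  association clears genome-wide significance with high probability at the
  stated exposure sample size), with a random sign representing arbitrary
  effect-allele orientation;
* per-SNP pleiotropic effect alpha_j, applied in the orientation of the
  exposure-increasing allele (Gamma_j gains sign(gamma_j) * alpha_j):
  ``none`` (0), ``balanced`` (mean forced to 0), ``directional``
  (N(mu_alpha, sigma_alpha)), or ``inside_violating`` (alpha correlated
  with instrument strength |gamma_j| through a Gaussian-copula-style
  construction with correlation ``rho``);  ``pleio_frac`` limits the
  affected fraction of SNPs;
* true outcome effect Gamma_j = causal_beta * gamma_j + sign(gamma_j) *
  alpha_j, plus an outlier bump of ``outlier_scale`` outcome-side SEs for
  ``n_outliers`` flagged SNPs;
* observed effects are drawn normal around the truths with the
  standardized-trait SE model se = 1 / sqrt(2 n u (1-u)); binary traits use
  the same normal approximation with the GWAS's effective n.  Emitted
  p-values satisfy p = 2 Phi(-|beta/se|) exactly.

Everything is reproducible from ``seed``; all per-table draws come from
one generator so identical seeds give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, FeasibilityError
from .ld import LDInfo
from .summary_io import SummaryStats

#: |z| threshold for two-sided p < 5e-8.
GENOME_WIDE_Z = float(sps.norm.isf(2.5e-8))

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]


@dataclass(frozen=True)
class MediatorSpec:
    """True two-step structure: exposure -> mediator (beta2), mediator ->
    outcome (beta3), plus a direct exposure -> outcome path."""
    beta2_true: float
    beta3_true: float
    direct_beta: float
    n_snps_mediator: Optional[int] = None  # defaults to n_snps


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_snps: int = 50
    causal_beta: float = 0.0
    mediator_spec: Optional[MediatorSpec] = None
    pleiotropy: str = "none"  # none | balanced | directional | inside_violating
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    rho: float = 0.0
    pleio_frac: float = 1.0
    gamma_sd: float = 0.05
    gamma_floor_z: float = 8.0
    n_exp: int = 500_000
    n_out: int = 500_000
    n_med: int = 500_000
    eaf_range: Tuple[float, float] = (0.05, 0.95)
    n_outliers: int = 0
    outlier_scale: float = 10.0
    ld_blocks: Optional[Tuple[int, float]] = None  # (block_size, within-block r2)

    def validate(self) -> None:
        if self.pleiotropy not in ("none", "balanced", "directional",
                                   "inside_violating"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError(f"rho={self.rho} outside [-1,1]")
        if self.gamma_sd <= 0 or self.sigma_alpha < 0:
            raise ConfigurationError("variance parameters must be positive")
        if not 0.0 <= self.pleio_frac <= 1.0:
            raise ConfigurationError("pleio_frac must lie in [0,1]")
        if min(self.n_exp, self.n_out, self.n_med) <= 0 or self.n_snps <= 0:
            raise ConfigurationError("sample sizes and n_snps must be positive")
        lo, hi = self.eaf_range
        if not 0.0 < lo < hi < 1.0:
            raise ConfigurationError(f"eaf_range {self.eaf_range} invalid")


@dataclass
class TruthRecord:
    """Ground truth aligned one-to-one with the emitted variants."""
    df: pd.DataFrame  # variant_id, gamma, alpha, outlier, [gamma_mediator]
    true_beta1: float
    true_beta2: Optional[float]
    true_beta3: Optional[float]
    true_proportion: Optional[float]
    config: SimulationConfig


@dataclass
class SimulatedPair:
    exposure: SummaryStats
    outcome: SummaryStats
    ld: LDInfo
    truth: TruthRecord


@dataclass
class SimulatedTriplet:
    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    ld: LDInfo
    truth: TruthRecord


def _se(n: int, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _draw_gamma(rng, cfg: SimulationConfig, se_exp: np.ndarray,
                n_label: str = "n_exp"):
    """Signed true SNP-exposure effects with the significance floor."""
    floor = cfg.gamma_floor_z * se_exp
    if np.any(floor > 10.0 * cfg.gamma_sd):
        raise FeasibilityError(
            f"instruments cannot plausibly reach genome-wide significance: "
            f"required magnitude {float(floor.max()):.3g} exceeds 10x gamma_sd "
            f"({cfg.gamma_sd}); increase {n_label} or gamma_sd")
    mag = np.maximum(np.abs(rng.normal(0.0, cfg.gamma_sd, se_exp.size)), floor)
    sign = rng.choice([-1.0, 1.0], size=se_exp.size)
    return mag * sign


def _draw_alpha(rng, cfg: SimulationConfig, gamma_mag: np.ndarray) -> np.ndarray:
    J = gamma_mag.size
    if cfg.pleiotropy == "none":
        return np.zeros(J)
    mu = 0.0 if cfg.pleiotropy == "balanced" else cfg.mu_alpha
    noise = rng.standard_normal(J)
    if cfg.pleiotropy == "inside_violating":
        zg = (gamma_mag - gamma_mag.mean()) / (gamma_mag.std() or 1.0)
        base = cfg.rho * zg + np.sqrt(max(0.0, 1.0 - cfg.rho**2)) * noise
    else:
        base = noise
    alpha = mu + cfg.sigma_alpha * base
    if cfg.pleio_frac < 1.0:
        alpha = np.where(rng.random(J) < cfg.pleio_frac, alpha, 0.0)
    return alpha


def _positions(cfg: SimulationConfig, J: int):
    """Variant coordinates and the matching complete LD source.

    Without LD blocks, SNPs are spaced 20 Mb apart (outside any plausible
    clumping window) so they are mutually independent by the distance rule.
    With ``ld_blocks=(m, r2)``, blocks of m consecutive SNPs sit 10 kb
    apart within a block (inside the window) at constant within-block r2,
    and blocks are 20 Mb apart.
    """
    ids = [f"rs{j + 1:07d}" for j in range(J)]
    if cfg.ld_blocks is None:
        pos = 1 + 20_000_000 * np.arange(J)
        ld = LDInfo(variants=ids, complete=True)
    else:
        m, r2 = cfg.ld_blocks
        if m < 1 or not 0.0 <= r2 <= 1.0:
            raise ConfigurationError(f"invalid ld_blocks {cfg.ld_blocks}")
        block = np.arange(J) // m
        within = np.arange(J) % m
        pos = 1 + 20_000_000 * block + 10_000 * within
        ld = LDInfo(variants=ids, complete=True)
        for b in range(int(block.max()) + 1):
            members = [ids[j] for j in range(J) if block[j] == b]
            for i in range(len(members)):
                for k in range(i + 1, len(members)):
                    ld.add(members[i], members[k], r2)
    return ids, pos.astype(int), ld


def _table(trait_id, ids, pos, eaf, truth_beta, se, n, rng,
           allele_idx, effect_scale="sd_units") -> SummaryStats:
    beta = truth_beta + rng.standard_normal(truth_beta.size) * se
    pval = 2.0 * sps.norm.sf(np.abs(beta) / se)
    ea = [_ALLELE_PAIRS[i][0] for i in allele_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in allele_idx]
    df = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": np.clip(pval, 5e-324, 1.0),
        "n": pd.array([n] * len(ids), dtype="Int64"),
        "chrom": pd.array(["1"] * len(ids), dtype="string"),
        "pos": pd.array(pos, dtype="Int64"),
    })
    return SummaryStats(trait_id, df, effect_scale=effect_scale,
                        sample_size_default=n)


def simulate_gwas_pair(config: SimulationConfig) -> SimulatedPair:
    """One exposure/outcome pair of summary tables plus LD and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    J = config.n_snps
    ids, pos, ld = _positions(config, J)
    eaf = rng.uniform(*config.eaf_range, J)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), J)

    se_exp = _se(config.n_exp, eaf)
    se_out = _se(config.n_out, eaf)
    gamma = _draw_gamma(rng, config, se_exp)
    sign = np.sign(gamma)
    alpha = _draw_alpha(rng, config, np.abs(gamma))
    big_gamma = config.causal_beta * gamma + sign * alpha

    outlier = np.zeros(J, dtype=bool)
    if config.n_outliers:
        idx = rng.choice(J, size=min(config.n_outliers, J), replace=False)
        outlier[idx] = True
        big_gamma = big_gamma + np.where(outlier,
                                         sign * config.outlier_scale * se_out, 0.0)

    exposure = _table("exposure", ids, pos, eaf, gamma, se_exp,
                      config.n_exp, rng, allele_idx)
    outcome = _table("outcome", ids, pos, eaf, big_gamma, se_out,
                     config.n_out, rng, allele_idx)
    truth = TruthRecord(
        df=pd.DataFrame({"variant_id": ids, "gamma": gamma, "alpha": alpha,
                         "outlier": outlier}),
        true_beta1=config.causal_beta, true_beta2=None, true_beta3=None,
        true_proportion=None, config=config)
    return SimulatedPair(exposure, outcome, ld, truth)


def simulate_mediation_triplet(config: SimulationConfig) -> SimulatedTriplet:
    """Exposure, mediator, and outcome tables under a two-step structure.

    Exposure instruments (n_snps) carry gamma_j; an additional
    mediator-specific instrument set (n_snps_mediator, true exposure effect
    zero) makes the mediator -> outcome step estimable by two-sample MR,
    exactly as a real two-step design uses the mediator's own GWAS hits.
    True total effect beta1 = direct_beta + beta2*beta3; true proportion
    mediated = beta2*beta3 / beta1.
    """
    config.validate()
    spec = config.mediator_spec
    if spec is None:
        raise ConfigurationError("mediator_spec is required for a triplet")
    rng = np.random.default_rng(config.seed)
    J1 = config.n_snps
    J2 = spec.n_snps_mediator or config.n_snps
    J = J1 + J2
    ids, pos, ld = _positions(config, J)
    eaf = rng.uniform(*config.eaf_range, J)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), J)

    se_exp = _se(config.n_exp, eaf)
    se_med = _se(config.n_med, eaf)
    se_out = _se(config.n_out, eaf)

    gamma_e = _draw_gamma(rng, config, se_exp[:J1])
    gamma_m = _draw_gamma(rng, config, se_med[J1:], n_label="n_med")
    sign_e = np.sign(gamma_e)
    alpha = _draw_alpha(rng, config, np.abs(gamma_e))

    true_exp = np.concatenate([gamma_e, np.zeros(J2)])
    true_med = np.concatenate([spec.beta2_true * gamma_e, gamma_m])
    true_out = np.concatenate([
        (spec.direct_beta + spec.beta3_true * spec.beta2_true) * gamma_e
        + sign_e * alpha,
        spec.beta3_true * gamma_m,
    ])

    exposure = _table("exposure", ids, pos, eaf, true_exp, se_exp,
                      config.n_exp, rng, allele_idx)
    mediator = _table("mediator", ids, pos, eaf, true_med, se_med,
                      config.n_med, rng, allele_idx)
    outcome = _table("outcome", ids, pos, eaf, true_out, se_out,
                     config.n_out, rng, allele_idx)

    beta1 = spec.direct_beta + spec.beta2_true * spec.beta3_true
    proportion = (spec.beta2_true * spec.beta3_true / beta1) if beta1 else np.nan
    truth = TruthRecord(
        df=pd.DataFrame({
            "variant_id": ids,
            "gamma": true_exp,
            "gamma_mediator": np.concatenate([np.zeros(J1), gamma_m]),
            "alpha": np.concatenate([alpha, np.zeros(J2)]),
            "outlier": np.zeros(J, dtype=bool),
        }),
        true_beta1=beta1, true_beta2=spec.beta2_true,
        true_beta3=spec.beta3_true, true_proportion=float(proportion),
        config=config)
    return SimulatedTriplet(exposure, mediator, outcome, ld, truth)


#: Documented study conditions exercising each pipeline stage.
_PRESETS = {
    # All instruments valid; moderate positive causal effect.
    "valid": dict(n_snps=50, causal_beta=0.2, pleiotropy="none"),
    # Zero-mean pleiotropy: heterogeneity without directional bias.
    "balanced_pleio": dict(n_snps=50, causal_beta=0.2, pleiotropy="balanced",
                           sigma_alpha=0.03),
    # Mean pleiotropic effect 0.05 (InSIDE respected): biases IVW, the
    # Egger intercept should recover 0.05.
    "directional_pleio": dict(n_snps=50, causal_beta=0.2,
                              pleiotropy="directional", mu_alpha=0.05,
                              sigma_alpha=0.02),
    # Pleiotropy correlated with instrument strength (InSIDE violated).
    "inside_violation": dict(n_snps=50, causal_beta=0.2,
                             pleiotropy="inside_violating", mu_alpha=0.05,
                             sigma_alpha=0.03, rho=0.7),
    # Two of 50 SNPs with a 10x-residual-scale outcome bump (MR-PRESSO).
    "with_outliers": dict(n_snps=50, causal_beta=0.2, n_outliers=2,
                          outlier_scale=10.0),
    # No significance floor and a smaller exposure GWAS: roughly a third
    # of SNPs fall under F = 10 and exercise the strength filter.
    "weak_instruments": dict(n_snps=50, causal_beta=0.2, gamma_floor_z=0.0,
                             gamma_sd=0.05, n_exp=100_000),
}


def scenario_presets(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A documented SimulationConfig for a named scenario."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)
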