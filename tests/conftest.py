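import numpy as np
import pandas as pd
import pytest

from mrkit.instruments import HarmonizedSet
from mrkit.simulate import SimulationConfig, simulate_gwas_pair
from mrkit.summary_io import SummaryStats


def make_stats(rows, trait_id="trait", **kwargs):
    """Build a SummaryStats from a list of dicts with canonical defaults."""
    defaults = dict(effect_allele="A", other_allele="G", eaf=0.3,
                    beta=0.1, se=0.01, pval=1e-9, n=pd.NA,
                    chrom=pd.NA, pos=pd.NA)
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("variant_id", f"rs{i + 1}")
        rec.update(row)
        records.append(rec)
    df = pd.DataFrame(records)
    df["n"] = pd.array(df["n"], dtype="Int64")
    df["pos"] = pd.array(df["pos"], dtype="Int64")
    df["chrom"] = df["chrom"].astype("string")
    return SummaryStats(trait_id, df, **kwargs)


def make_hset(beta_exp, se_exp, beta_out, se_out, exposure="X", outcome="Y"):
    beta_exp = np.asarray(beta_exp, float)
    df = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(len(beta_exp))],
        "beta_exp": beta_exp,
        "se_exp": np.asarray(se_exp, float),
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float),
    })
    return HarmonizedSet(exposure, outcome, df)


@pytest.fixture
def valid_pair():
    return simulate_gwas_pair(
        SimulationConfig(seed=42, n_snps=30, causal_beta=0.2))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
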