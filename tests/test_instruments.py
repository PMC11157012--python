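import itertools

import numpy as np
import pandas as pd
import pytest

from mrkit.exceptions import EmptyInputError, MissingLDError
from mrkit.instruments import (
    compute_f_statistics,
    filter_maf_and_palindromes,
    harmonize,
    ld_clump,
    select_by_pvalue,
    select_instruments,
)
from mrkit.ld import LDInfo
from mrkit.estimators import ivw, mr_egger, weighted_median

from conftest import make_stats


class TestSelectByPvalue:
    def test_strict_threshold(self):
        stats = make_stats([{"pval": 4e-8}, {"pval": 6e-8}, {"pval": 5e-8}])
        kept = select_by_pvalue(stats, 5e-8)
        assert list(kept.df["pval"]) == [4e-8]

    def test_all_null_gives_empty(self):
        stats = make_stats([{"pval": 0.5}] * 3)
        assert select_by_pvalue(stats).n_variants == 0

    def test_matches_brute_force_count(self, rng):
        pvals = rng.uniform(size=100)
        stats = make_stats([{"variant_id": f"v{i}", "pval": p}
                            for i, p in enumerate(pvals)])
        kept = select_by_pvalue(stats, 0.3)
        assert kept.n_variants == int(np.sum(pvals < 0.3))


class TestLDClump:
    def test_pairwise_dominance(self):
        stats = make_stats([
            {"variant_id": "a", "pval": 1e-9, "chrom": "1", "pos": 1000},
            {"variant_id": "b", "pval": 1e-10, "chrom": "1", "pos": 2000},
        ])
        ld = LDInfo(pairs=[("a", "b", 0.5)])
        kept = ld_clump(stats, ld)
        assert list(kept.df["variant_id"]) == ["b"]

    def test_different_chromosomes_never_clumped(self):
        stats = make_stats([
            {"variant_id": "a", "pval": 1e-9, "chrom": "1", "pos": 1000},
            {"variant_id": "b", "pval": 1e-10, "chrom": "2", "pos": 1000},
        ])
        # no LD entry needed at all: the window rule short-circuits
        kept = ld_clump(stats, LDInfo())
        assert kept.n_variants == 2

    def test_outside_window_kept(self):
        stats = make_stats([
            {"variant_id": "a", "pval": 1e-9, "chrom": "1", "pos": 1},
            {"variant_id": "b", "pval": 1e-8, "chrom": "1", "pos": 20_000_000},
        ])
        kept = ld_clump(stats, LDInfo(), window_kb=10000)
        assert kept.n_variants == 2

    def test_missing_ld_entry_is_hard_error(self):
        stats = make_stats([
            {"variant_id": "a", "pval": 1e-9, "chrom": "1", "pos": 1000},
            {"variant_id": "b", "pval": 1e-8, "chrom": "1", "pos": 2000},
        ])
        with pytest.raises(MissingLDError):
            ld_clump(stats, LDInfo())

    def test_matches_brute_force_greedy(self, rng):
        """Block-LD instance vs an independent greedy reimplementation."""
        n = 12
        pvals = rng.uniform(1e-12, 1e-6, n)
        block = np.arange(n) // 4
        stats = make_stats([
            {"variant_id": f"v{i}", "pval": pvals[i], "chrom": "1",
             "pos": 1000 * (i + 1)} for i in range(n)])
        ld = LDInfo(variants=[f"v{i}" for i in range(n)], complete=True)
        for i, j in itertools.combinations(range(n), 2):
            if block[i] == block[j]:
                ld.add(f"v{i}", f"v{j}", 0.8)

        # oracle: independent greedy selection
        order = np.argsort(pvals)
        kept, removed = [], set()
        for i in order:
            if i in removed:
                continue
            kept.append(f"v{i}")
            for j in range(n):
                if j != i and block[j] == block[i]:
                    removed.add(j)
        result = ld_clump(stats, ld)
        assert list(result.df["variant_id"]) == kept


class TestMafPalindromeF:
    def test_maf_boundary_inclusive(self):
        # eaf = 0.01 sits exactly on the boundary and is excluded (<=);
        # rare on the other strand (eaf near 1) is excluded symmetrically
        stats = make_stats([{"eaf": 0.01}, {"eaf": 0.005}, {"eaf": 0.999},
                            {"eaf": 0.011}, {"eaf": 0.5}])
        kept = filter_maf_and_palindromes(stats, maf_min=0.01)
        assert list(kept.df["eaf"]) == [0.011, 0.5]

    def test_palindromic_dropped_and_normal_kept(self):
        stats = make_stats([
            {"variant_id": "p1", "effect_allele": "A", "other_allele": "T",
             "eaf": 0.3},
            {"variant_id": "p2", "effect_allele": "G", "other_allele": "C",
             "eaf": 0.3},
            {"variant_id": "ok", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.5},
        ])
        kept = filter_maf_and_palindromes(stats)
        assert list(kept.df["variant_id"]) == ["ok"]

    @pytest.mark.parametrize("beta,se,expect_kept,expect_f", [
        (0.1, 0.02, True, 25.0),
        (0.03, 0.01, False, 9.0),
        (-0.1, 0.02, True, 25.0),  # sign-invariant
    ])
    def test_f_statistic_formula_and_threshold(self, beta, se, expect_kept,
                                               expect_f):
        stats = make_stats([{"beta": beta, "se": se}])
        out = compute_f_statistics(stats, f_threshold=10)
        if expect_kept:
            assert out.df.loc[0, "f_stat"] == pytest.approx(expect_f, rel=1e-9)
        else:
            assert out.n_variants == 0

    def test_row_local_filters_commute(self, rng):
        rows = [{"variant_id": f"v{i}",
                 "effect_allele": "AT"[i % 2], "other_allele": "TG"[i % 2],
                 "eaf": float(rng.uniform(0.001, 0.999)),
                 "beta": float(rng.normal(0, 0.1)),
                 "se": float(rng.uniform(0.005, 0.05))}
                for i in range(40)]
        stats = make_stats(rows)
        a = compute_f_statistics(filter_maf_and_palindromes(stats))
        b = filter_maf_and_palindromes(compute_f_statistics(stats))
        assert list(a.df["variant_id"]) == list(b.df["variant_id"])


COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class TestHarmonize:
    def _one(self, exp_alleles, out_alleles, beta_out=0.2):
        exp = make_stats([{"variant_id": "rs1",
                           "effect_allele": exp_alleles[0],
                           "other_allele": exp_alleles[1], "beta": 0.1}], "X")
        out = make_stats([{"variant_id": "rs1",
                           "effect_allele": out_alleles[0],
                           "other_allele": out_alleles[1],
                           "beta": beta_out}], "Y")
        try:
            h = harmonize(exp, out)
        except EmptyInputError:
            return None
        return float(h.df.loc[0, "beta_out"])

    def test_same_alleles_kept_unchanged(self):
        assert self._one(("A", "G"), ("A", "G")) == 0.2

    def test_swapped_alleles_flip_sign(self):
        assert self._one(("A", "G"), ("G", "A")) == -0.2

    def test_strand_complement_same_orientation_keeps_sign(self):
        assert self._one(("A", "G"), ("T", "C")) == 0.2

    def test_all_allele_configurations_against_truth_table(self):
        """Enumerate every outcome allele pair for a non-palindromic
        exposure SNP against a hand-built orientation truth table."""
        exp = ("A", "G")
        truth = {
            ("A", "G"): 0.2,            # identical
            ("G", "A"): -0.2,           # swapped
            ("T", "C"): 0.2,            # complement, same orientation
            ("C", "T"): -0.2,           # complement, swapped
        }
        for out_pair in itertools.permutations("ACGT", 2):
            expected = truth.get(out_pair)  # None -> unresolvable, dropped
            assert self._one(exp, out_pair) == expected, out_pair

    def test_exclusion_list_applied(self):
        exp = make_stats([{"variant_id": "rs1"}, {"variant_id": "rs2"}], "X")
        out = make_stats([{"variant_id": "rs1"}, {"variant_id": "rs2"}], "Y")
        h = harmonize(exp, out, exclusion_list=["rs1"])
        assert h.variant_ids == ["rs2"]

    def test_empty_intersection_raises_with_diagnostics(self):
        exp = make_stats([{"variant_id": "rs1"}], "X")
        out = make_stats([{"variant_id": "rs9"}], "Y")
        with pytest.raises(EmptyInputError, match="not_in_outcome"):
            harmonize(exp, out)

    def test_harmonization_is_involutive(self, valid_pair):
        h1 = harmonize(valid_pair.exposure, valid_pair.outcome)
        # rebuild an outcome table from the harmonized rows and re-harmonize
        out2 = valid_pair.outcome.subset(h1.variant_ids)
        df = out2.df.copy()
        merged = df.merge(h1.df[["variant_id", "beta_out"]], on="variant_id")
        np.testing.assert_array_equal(merged["beta"], merged["beta_out"])
        h2 = harmonize(valid_pair.exposure, out2)
        pd.testing.assert_frame_equal(h1.df, h2.df)


def test_global_sign_symmetry(valid_pair):
    """Negating every exposure and outcome beta leaves causal-estimate
    magnitudes unchanged."""
    h = harmonize(valid_pair.exposure, valid_pair.outcome)
    flipped = h.df.copy()
    flipped["beta_exp"] *= -1
    flipped["beta_out"] *= -1
    from mrkit.instruments import HarmonizedSet
    hf = HarmonizedSet(h.exposure_id, h.outcome_id, flipped)
    assert ivw(hf).beta == pytest.approx(ivw(h).beta, rel=1e-12)
    assert abs(mr_egger(hf).beta) == pytest.approx(abs(mr_egger(h).beta), rel=1e-9)
    assert weighted_median(hf, seed=1).beta == pytest.approx(
        weighted_median(h, seed=1).beta, rel=1e-9)


def test_select_instruments_attrition_accounting(valid_pair):
    attrition = {}
    select_instruments(valid_pair.exposure, ld=valid_pair.ld,
                       attrition=attrition)
    assert attrition["n_total"] == valid_pair.exposure.n_variants
    assert (attrition["n_total"] >= attrition["n_significant"]
            >= attrition["n_after_clump"]
            >= attrition["n_after_maf_palindrome"]
            >= attrition["n_after_f"] > 0)
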