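from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from reopair.diffomics import (aggregate_regions, deg_ttest, dm_genes,
                               dm_loci, frequency_test,
                               rank_product_degs)


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's ('method of small p-values')."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


def labelled(n_high, n_low):
    idx = [f"H{i}" for i in range(n_high)] + [f"L{i}" for i in range(n_low)]
    labels = pd.Series(["high"] * n_high + ["low"] * n_low, index=idx)
    return idx, labels


class TestDegTtest:
    def test_shifted_gene_detected_with_direction(self):
        rng = np.random.default_rng(0)
        idx, labels = labelled(50, 50)
        expr = pd.DataFrame(rng.normal(size=(100, 20)), index=idx,
                            columns=[f"G{i}" for i in range(20)])
        expr.loc[labels == "high", "G0"] += 3.0  # +3 SD shift
        expr.loc[labels == "high", "G1"] -= 3.0
        out = deg_ttest(expr, labels, fdr_cut=0.05).set_index("feature_id")
        assert out.loc["G0", "significant"]
        assert out.loc["G0", "direction"] == "up_in_high"
        assert out.loc["G1", "significant"]
        assert out.loc["G1", "direction"] == "down_in_high"

    def test_identical_values_not_significant(self):
        idx, labels = labelled(5, 5)
        expr = pd.DataFrame({"G0": np.ones(10),
                             "G1": np.arange(10.0)}, index=idx)
        out = deg_ttest(expr, labels, fdr_cut=0.05).set_index("feature_id")
        assert out.loc["G0", "p"] == 1.0
        assert not out.loc["G0", "significant"]

    def test_null_permutations_stay_near_nominal(self):
        rng = np.random.default_rng(1)
        idx, labels = labelled(30, 30)
        expr = pd.DataFrame(rng.normal(size=(60, 150)), index=idx,
                            columns=[f"G{i}" for i in range(150)])
        fracs = []
        for _ in range(20):
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=idx)
            out = deg_ttest(expr, perm, fdr_cut=0.05)
            fracs.append(out["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_small_group_rejected(self):
        idx, labels = labelled(1, 5)
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)),
                            index=idx)
        with pytest.raises(ValueError):
            deg_ttest(expr, labels)


class TestRankProduct:
    def toy(self):
        # 2v2, 3 genes: every comparison's differences rank g1 > g2 > g3
        idx, labels = labelled(2, 2)
        expr = pd.DataFrame(
            [[10.0, 5.0, 0.0], [10.0, 5.0, 0.0],
             [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            index=idx, columns=["g1", "g2", "g3"])
        return expr, labels

    def test_hand_computed_rank_products(self):
        expr, labels = self.toy()
        out = rank_product_degs(expr, labels, n_permutations=50,
                                seed=0).set_index("feature_id")
        # up run: g1 rank 1 in all 4 comparisons -> RP 1 (minimum);
        # g3 rank 1 in every down comparison -> RP 1 in the down run
        assert out.loc["g1", "statistic"] == pytest.approx(1.0)
        assert out.loc["g1", "direction"] == "up_in_high"
        assert out.loc["g3", "statistic"] == pytest.approx(1.0)
        assert out.loc["g3", "direction"] == "down_in_high"
        assert out.loc["g2", "statistic"] == pytest.approx(2.0)

    def test_batch_shift_invariance(self):
        rng = np.random.default_rng(3)
        idx, labels = labelled(4, 4)
        expr = pd.DataFrame(rng.normal(size=(8, 30)), index=idx,
                            columns=[f"G{i}" for i in range(30)])
        shifted = expr.copy()
        shifted.iloc[0] += 100.0  # batch offset on one sample
        shifted.iloc [5] -= 7.0
        a = rank_product_degs(expr, labels, n_permutations=20, seed=1)
        b = rank_product_degs(shifted, labels, n_permutations=20, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_floor_enforced(self):
        expr, labels = self.toy()
        with pytest.raises(ValueError):
            rank_product_degs(expr, labels, n_permutations=5)

    def test_fdr_dominates_p(self):
        rng = np.random.default_rng(4)
        idx, labels = labelled(3, 3)
        expr = pd.DataFrame(rng.normal(size=(6, 25)), index=idx)
        out = rank_product_degs(expr, labels, n_permutations=40, seed=2)
        assert (out["fdr"] >= out["p"] - 1e-12).all()


class TestDmLoci:
    def test_complete_separation_significant_hyper(self):
        rng = np.random.default_rng(5)
        idx, labels = labelled(20, 20)
        meth = pd.DataFrame({
            "cg1": np.concatenate([rng.uniform(0.6, 0.9, 20),
                                   rng.uniform(0.1, 0.4, 20)]),
            "cg2": rng.uniform(0.3, 0.5, 40),
        }, index=idx)
        out = dm_loci(meth, labels, fdr_cut=0.01).set_index("feature_id")
        assert out.loc["cg1", "significant"]
        assert out.loc["cg1", "direction"] == "up_in_high"
        assert not out.loc["cg2", "significant"]

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        idx, labels = labelled(12, 12)
        meth = pd.DataFrame(rng.uniform(0.05, 0.95, size=(24, 10)),
                            index=idx, columns=[f"cg{i}" for i in range(10)])
        a = dm_loci(meth, labels)
        b = dm_loci(meth**3, labels)  # strictly increasing on (0, 1)
        assert np.allclose(a["p"], b["p"])

    def test_constant_locus_p_one(self):
        idx, labels = labelled(4, 4)
        meth = pd.DataFrame({"cg0": np.full(8, 0.5),
                             "cg1": np.linspace(0.1, 0.9, 8)}, index=idx)
        out = dm_loci(meth, labels).set_index("feature_id")
        assert out.loc["cg0", "p"] == 1.0


class TestDmGenes:
    def loci_table(self, rows):
        df = pd.DataFrame(rows, columns=["feature_id", "direction",
                                         "significant"])
        df["statistic"] = 0.0
        df["p"] = 0.001
        df["fdr"] = 0.005
        return df

    def test_aggregation_rules(self):
        table = self.loci_table([
            ("cg1", "up_in_high", True),     # geneA: hyper
            ("cg2", "up_in_high", True),     # geneB: both -> excluded
            ("cg3", "down_in_high", True),   # geneB
            ("cg4", "down_in_high", True),   # geneC: hypo
            ("cg5", "up_in_high", False),    # geneD: nothing significant
            ("cg6", "up_in_high", True),     # unmapped -> dropped
        ])
        mapping = pd.DataFrame({
            "locus_id": ["cg1", "cg2", "cg3", "cg4", "cg5"],
            "gene_id": ["geneA", "geneB", "geneB", "geneC", "geneD"],
        })
        out = dm_genes(table, mapping).set_index("gene_id")
        assert out.loc["geneA", "direction"] == "hyper"
        assert out.loc["geneC", "direction"] == "hypo"
        assert "geneB" not in out.index  # both directions -> excluded
        assert "geneD" not in out.index  # no significant locus

    def test_hyper_hypo_partition_disjoint(self, demo_cohort, demo_labels):
        loci = dm_loci(demo_cohort.methylation, demo_labels, fdr_cut=0.01)
        genes = dm_genes(loci, demo_cohort.locus_gene_map)
        hyper = set(genes.loc[genes.direction == "hyper", "gene_id"])
        hypo = set(genes.loc[genes.direction == "hypo", "gene_id"])
        assert not hyper & hypo
        assert len(genes) > 0


class TestFrequencyTest:
    def test_worked_fisher_example(self):
        # 9/10 altered in high vs 1/10 in low: p = 202/184756
        idx, labels = labelled(10, 10)
        vals = np.zeros((20, 1), dtype=int)
        vals[:9] = 1
        vals[10] = 1
        mat = pd.DataFrame(vals, index=idx, columns=["g"])
        out = frequency_test(mat, labels, mode="mutation", p_cut=0.05)
        assert out.loc[0, "p"] == pytest.approx(202 / 184756, rel=1e-9)
        assert out.loc[0, "p"] == pytest.approx(
            fisher_two_sided_oracle(9, 1, 1, 9), rel=1e-9)
        assert out.loc[0, "freq_high"] == pytest.approx(0.9)
        assert out.loc[0, "freq_low"] == pytest.approx(0.1)
        assert out.loc[0, "significant"]

    def test_symmetric_table_p_one(self):
        idx, labels = labelled(10, 10)
        vals = np.zeros((20, 1), dtype=int)
        vals[:5] = 1
        vals[10:15] = 1
        mat = pd.DataFrame(vals, index=idx, columns=["g"])
        out = frequency_test(mat, labels, mode="mutation", p_cut=0.05)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_label_swap_leaves_p(self):
        rng = np.random.default_rng(7)
        idx, labels = labelled(15, 12)
        mat = pd.DataFrame(rng.integers(0, 2, size=(27, 8)), index=idx)
        flipped = labels.map({"high": "low", "low": "high"})
        a = frequency_test(mat, labels, mode="mutation")
        b = frequency_test(mat, flipped, mode="mutation")
        assert np.allclose(a["p"], b["p"])

    def test_gain_loss_modes_collapse_gistic_calls(self):
        idx, labels = labelled(4, 4)
        mat = pd.DataFrame({"g": [2, 1, 0, -1, 0, 0, -2, 0]}, index=idx)
        gain = frequency_test(mat, labels, mode="gain")
        loss = frequency_test(mat, labels, mode="loss")
        assert gain.loc[0, "freq_high"] == pytest.approx(0.5)
        assert gain.loc[0, "freq_low"] == pytest.approx(0.0)
        assert loss.loc[0, "freq_high"] == pytest.approx(0.25)
        assert loss.loc[0, "freq_low"] == pytest.approx(0.25)

    def test_never_altered_feature_retained(self):
        idx, labels = labelled(3, 3)
        mat = pd.DataFrame({"g": np.zeros(6, dtype=int)}, index=idx)
        out = frequency_test(mat, labels, mode="mutation")
        assert out.loc[0, "p"] == 1.0
        assert out.loc[0, "freq_high"] == 0.0 == out.loc[0, "freq_low"]


class TestAggregateRegions:
    def test_any_gene_altered_rule(self):
        idx = ["s1", "s2", "s3"]
        alts = pd.DataFrame({"gA": [1, 0, 0], "gB": [0, 2, 0],
                             "gC": [0, 0, -1]}, index=idx)
        mapping = pd.DataFrame({"gene_id": ["gA", "gB", "gC", "gZ"],
                                "region_id": ["8q24", "8q24", "3p13",
                                              "8q24"]})
        gains = aggregate_regions(alts, mapping, mode="gain")
        assert list(gains["8q24"]) == [1, 1, 0]  # gZ absent: ignored
        assert list(gains["3p13"]) == [0, 0, 0]
        losses = aggregate_regions(alts, mapping, mode="loss")
        assert list(losses["3p13"]) == [0, 0, 1]

    def test_feeds_frequency_test(self):
        idx, labels = labelled(4, 4)
        alts = pd.DataFrame({"gA": [1, 1, 1, 1, 0, 0, 0, 0],
                             "gB": np.zeros(8, dtype=int)}, index=idx)
        mapping = pd.DataFrame({"gene_id": ["gA", "gB"],
                                "region_id": ["r1", "r1"]})
        regions = aggregate_regions(alts, mapping, mode="gain")
        out = frequency_test(regions, labels, mode="mutation")
        assert out.loc[0, "freq_high"] == 1.0
        assert out.loc[0, "freq_low"] == 0.0
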