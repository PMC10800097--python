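"""Frequency tables, Fisher/BH statistics, DE ranking and enrichment.

The statistical routines are checked against independent hand-written
oracles: exhaustive fixed-margin enumeration for the two-sided Fisher
exact p, direct PMF summation for the hypergeometric upper tail, and a
literal step-up computation for Benjamini-Hochberg.
"""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctcintegrins.functional_profiling import (
    GenePanel,
    bh_adjust,
    compare_vs_reference,
    default_panel,
    load_panel,
    overlap_enrichment,
    panel_frequencies,
    rank_de_genes,
    read_gmt,
    save_panel,
    significant_counts,
)
from ctcintegrins.matrix import from_dataframe
from ctcintegrins.synthetic_cohort import CohortParams, DEFAULT_DE_GENES


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of all 2x2 tables with
    the observed margins, summing the probabilities <= that of the observed
    table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(p for p in (prob(x) for x in range(lo, hi + 1))
               if p <= p_obs * (1 + 1e-9))


def hypergeom_upper_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct PMF summation."""
    denom = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x) / denom
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    )


def bh_oracle(pvalues):
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


# ---------------------------------------------------------------------------

def freq_from_counts(rows):
    """Build a frequency table from (group, gene, n_expressing, n_total)."""
    return pd.DataFrame(
        [
            {
                "group": g, "gene": gene, "category": "x",
                "n_expressing": k, "n_total": n,
                "fraction": k / n if n else float("nan"),
            }
            for g, gene, k, n in rows
        ]
    )


class TestPanelFrequencies:
    def test_simple_fraction(self):
        df = pd.DataFrame(
            {"CD44": [2, 0, 0, 0], "MYC": [0, 0, 0, 0]},
            index=[f"c{i}" for i in range(4)],
        )
        panel = GenePanel(categories={"stemness": ("CD44", "MYC")})
        labels = pd.Series([8, 8, 8, 8], index=df.index, name="group_id")
        freq = panel_frequencies(from_dataframe(df), labels, panel)
        assert freq.set_index("gene").loc["CD44", "fraction"] == 0.25
        assert freq.set_index("gene").loc["MYC", "fraction"] == 0.0

    def test_missing_panel_gene_reported_as_zero(self):
        df = pd.DataFrame({"CD44": [1]}, index=["c"])
        panel = GenePanel(categories={"s": ("CD44", "NOTPRESENT")})
        labels = pd.Series([1], index=df.index, name="group_id")
        freq = panel_frequencies(from_dataframe(df), labels, panel)
        assert freq.set_index("gene").loc["NOTPRESENT", "fraction"] == 0.0

    def test_planted_bernoulli_rate_recovered(self, planted_cohort):
        # group 8 effect genes are planted at rate 0.4 with n=500; the
        # observed fraction must fall within 3 binomial standard errors.
        matrix, truth = planted_cohort
        labels = truth.loc[truth["is_ctc"], "true_group"].rename("group_id")
        freq = panel_frequencies(matrix, labels)
        got = freq.query("group == 8 and gene == 'CD44'")["fraction"].iloc[0]
        se = np.sqrt(0.4 * 0.6 / 500)
        assert abs(got - 0.4) <= 3 * se

    def test_group_totals_equal_group_sizes(self, planted_cohort):
        matrix, truth = planted_cohort
        labels = truth.loc[truth["is_ctc"], "true_group"].rename("group_id")
        freq = panel_frequencies(matrix, labels)
        assert (freq.groupby("group")["n_total"].nunique() == 1).all()
        assert (freq.groupby("group")["n_total"].first() == 500).all()

    def test_panel_file_round_trip_and_duplicate_rejection(self, tmp_path):
        panel = default_panel()
        assert len(panel) == 36
        save_panel(panel, tmp_path / "panel.tsv")
        back = load_panel(tmp_path / "panel.tsv")
        assert back.genes == panel.genes
        with pytest.raises(ValueError, match="duplicate"):
            GenePanel(categories={"a": ("VIM",), "b": ("VIM",)})


class TestFisherComparison:
    def test_diagonal_table_two_sided_p(self):
        # [[3,0],[0,3]]: only the two extreme tables are as improbable,
        # each with probability 1/20 -> p = 0.1
        freq = freq_from_counts([(8, "G", 3, 3), (9, "G", 0, 3)])
        res = compare_vs_reference(freq, reference_group=9)
        assert res["pvalue"].iloc[0] == pytest.approx(0.1)
        assert res["pvalue"].iloc[0] == pytest.approx(
            fisher_two_sided_oracle(3, 0, 0, 3)
        )

    def test_identical_frequencies_give_p_one(self):
        freq = freq_from_counts([(1, "G", 5, 10), (9, "G", 5, 10)])
        res = compare_vs_reference(freq, reference_group=9)
        assert res["pvalue"].iloc[0] == 1.0
        assert not res["significant"].iloc[0]

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            a, b, c, d = rng.integers(0, 13, size=4)
            if a + b == 0 or c + d == 0:
                continue
            freq = freq_from_counts(
                [(2, "G", int(a), int(a + b)), (9, "G", int(c), int(c + d))]
            )
            res = compare_vs_reference(freq, reference_group=9)
            assert res["pvalue"].iloc[0] == pytest.approx(
                fisher_two_sided_oracle(int(a), int(b), int(c), int(d)),
                rel=1e-9,
            )

    def test_empty_group_flagged_untestable(self):
        freq = freq_from_counts([(3, "G", 0, 0), (9, "G", 2, 10)])
        res = compare_vs_reference(freq, reference_group=9)
        assert not res["testable"].iloc[0]
        assert not res["significant"].iloc[0]
        assert np.isnan(res["pvalue"].iloc[0])

    def test_missing_reference_group_rejected(self):
        freq = freq_from_counts([(1, "G", 1, 5)])
        with pytest.raises(ValueError, match="reference group"):
            compare_vs_reference(freq, reference_group=9)

    def test_significance_monotone_in_alpha(self, planted_cohort):
        matrix, truth = planted_cohort
        labels = truth.loc[truth["is_ctc"], "true_group"].rename("group_id")
        freq = panel_frequencies(matrix, labels)
        counts = []
        for alpha in (0.05, 0.01, 0.001):
            res = compare_vs_reference(freq, alpha=alpha)
            counts.append(int(res["significant"].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_chi2_variant_runs(self):
        freq = freq_from_counts([(1, "G", 9, 10), (9, "G", 1, 10)])
        res = compare_vs_reference(freq, reference_group=9, method="chi2")
        assert 0 <= res["pvalue"].iloc[0] <= 1


class TestBHAdjust:
    def test_hand_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_and_singleton(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_matches_literal_oracle_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40)).tolist()
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_q_at_least_p_and_in_unit_interval(self):
        rng = np.random.default_rng(3)
        p = rng.random(25)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRankDE:
    def test_planted_genes_all_in_top50_up(self, planted_cohort):
        matrix, truth = planted_cohort
        labels = truth.loc[truth["is_ctc"], "true_group"].rename("group_id")
        de = rank_de_genes(matrix, labels, target_group=8, reference_group=9)
        assert len(de) == 50
        up = set(de.loc[de["direction"] == "up", "gene"])
        assert set(DEFAULT_DE_GENES) <= up

    def test_null_gene_never_outranks_planted_effects(self, planted_cohort):
        matrix, truth = planted_cohort
        labels = truth.loc[truth["is_ctc"], "true_group"].rename("group_id")
        de = rank_de_genes(matrix, labels).set_index("gene")
        planted_worst = max(de.loc[g, "rank"] for g in DEFAULT_DE_GENES)
        # marker genes are cycled identically in every group: pure nulls
        for null_gene in ("KRT5", "KRT7", "KRT14"):
            if null_gene in de.index:
                assert de.loc[null_gene, "rank"] > planted_worst

    def test_swapping_groups_flips_directions(self, planted_cohort):
        matrix, truth = planted_cohort
        labels = truth.loc[truth["is_ctc"], "true_group"].rename("group_id")
        fwd = rank_de_genes(matrix, labels, 8, 9, top_n=20).set_index("gene")
        rev = rank_de_genes(matrix, labels, 9, 8, top_n=20).set_index("gene")
        shared = fwd.index.intersection(rev.index)
        assert len(shared) > 0
        for g in shared:
            assert fwd.loc[g, "direction"] != rev.loc[g, "direction"]

    def test_empty_group_rejected(self, planted_cohort):
        matrix, truth = planted_cohort
        labels = truth.loc[truth["is_ctc"], "true_group"].rename("group_id")
        with pytest.raises(ValueError, match="nonempty"):
            rank_de_genes(matrix, labels, target_group=8, reference_group=0)


class TestOverlapEnrichment:
    def test_worked_example_matches_direct_summation(self):
        # query of 3, set of 4, universe 10, overlap 2:
        # P(X>=2) = [C(4,2)C(6,1) + C(4,3)C(6,0)] / C(10,3) = 40/120
        res = overlap_enrichment(
            ["g1", "g2", "g3"],
            {"S": ["g1", "g2", "g4", "g5"]},
            universe_size=10,
        )
        assert res["overlap"].iloc[0] == 2
        assert res["pvalue"].iloc[0] == pytest.approx(1 / 3)
        assert res["pvalue"].iloc[0] == pytest.approx(
            hypergeom_upper_tail_oracle(2, 10, 4, 3)
        )

    def test_zero_overlap_and_forced_overlap_give_p_one(self):
        res = overlap_enrichment(["a", "b"], {"S": ["x", "y"]}, 20)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)
        res = overlap_enrichment(
            ["a", "b", "c"], {"S": ["a", "b", "c"]}, 3
        )
        assert res["overlap"].iloc[0] == 3
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_matches_pmf_summation_for_small_universes(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            N = int(rng.integers(2, 51))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(stats.hypergeom.rvs(N, K, n, random_state=rng))
            got = float(stats.hypergeom.sf(k - 1, N, K, n))
            assert got == pytest.approx(
                hypergeom_upper_tail_oracle(k, N, K, n), rel=1e-9
            )

    def test_results_sorted_by_p(self):
        res = overlap_enrichment(
            ["a", "b", "c"],
            {"hit": ["a", "b", "c", "d"], "miss": ["x", "y", "z"]},
            universe_size=30,
        )
        assert res["set"].tolist() == ["hit", "miss"]
        assert res["pvalue"].is_monotonic_increasing

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_enrichment([], {"S": ["a"]}, 10)

    def test_universe_smaller_than_query_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment(["a", "b", "c"], {"S": ["a"]}, 2)

    def test_gmt_round_trip(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text(
            "HALLMARK_A\tdesc\tVIM\tFN1\tCAV1\n"
            "HALLMARK_B\t\tMYC\tKLF4\n"
        )
        sets = read_gmt(gmt)
        assert sets == {
            "HALLMARK_A": ["VIM", "FN1", "CAV1"],
            "HALLMARK_B": ["MYC", "KLF4"],
        }
        bad = tmp_path / "bad.gmt"
        bad.write_text("only_name\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(bad)


class TestSignificantCounts:
    def test_planted_cohort_reports_26_of_36_for_group8(self, planted_cohort):
        matrix, truth = planted_cohort
        labels = truth.loc[truth["is_ctc"], "true_group"].rename("group_id")
        freq = panel_frequencies(matrix, labels)
        res = compare_vs_reference(freq, reference_group=9, alpha=0.05)
        counts = significant_counts(res)
        assert counts[8] == "26/36"
        planted = set(CohortParams().resolved_effect_genes())
        called = set(
            res.query("group == 8 and significant")["gene"]
        )
        assert called == planted
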