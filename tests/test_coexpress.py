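import numpy as np
import pandas as pd
import pytest

from lanthnet.coexpress import (
    coexpression_edges,
    combine_strains,
    group_tpm,
    intersect_evidence,
    tpm_matrix,
    trim_to_network,
)
from lanthnet.types import CoexpressionEdge, CorrelationEdge, GroupAssignment


def count_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "count", "length"])


class TestTpm:
    def test_closed_form_two_genes(self):
        table = count_table([("s1", "a", 10, 1000), ("s1", "b", 10, 2000)])
        tpm = tpm_matrix(table)
        assert tpm.loc["s1", "a"] == pytest.approx(666666.6667, rel=1e-6)
        assert tpm.loc["s1", "b"] == pytest.approx(333333.3333, rel=1e-6)

    def test_rows_sum_to_one_million(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"s{s}", f"g{g}", float(rng.poisson(20)), int(rng.integers(200, 3000)))
            for s in range(5)
            for g in range(30)
        ]
        tpm = tpm_matrix(count_table(rows))
        sums = tpm.sum(axis=1)
        expressed = sums[sums > 0]
        assert np.allclose(expressed, 1e6, rtol=1e-6)

    def test_all_zero_sample_gives_all_zero_row(self):
        table = count_table([("s1", "a", 0, 1000), ("s1", "b", 0, 2000)])
        assert (tpm_matrix(table).loc["s1"] == 0).all()

    def test_negative_count_is_an_error(self):
        with pytest.raises(ValueError, match="negative"):
            tpm_matrix(count_table([("s1", "a", -1, 1000)]))

    def test_nonpositive_length_is_an_error(self):
        with pytest.raises(ValueError):
            tpm_matrix(count_table([("s1", "a", 5, 0)]))


class TestGroupTpm:
    ASSIGNS = [
        GroupAssignment("a", "Pre_1", "precursor"),
        GroupAssignment("b", "Pre_1", "precursor"),
        GroupAssignment("c", "Prot_1", "protease"),
    ]

    def test_group_sums(self):
        expr = pd.DataFrame({"a": [100.0], "b": [50.0], "c": [10.0]}, index=["s1"])
        grouped = group_tpm(expr, self.ASSIGNS)
        assert grouped.loc["s1", "Pre_1"] == pytest.approx(150.0)
        assert grouped.loc["s1", "Prot_1"] == pytest.approx(10.0)

    def test_unassigned_genes_ignored_and_partial_cover_bound(self):
        expr = pd.DataFrame(
            {"a": [6e5], "b": [3e5], "c": [5e4], "x": [5e4]}, index=["s1"]
        )
        grouped = group_tpm(expr, self.ASSIGNS)
        assert "x" not in grouped.columns
        assert grouped.loc["s1"].sum() <= 1e6 + 1e-6

    def test_group_without_expressed_gene_has_no_column(self):
        expr = pd.DataFrame({"a": [1.0]}, index=["s1"])
        grouped = group_tpm(expr, self.ASSIGNS)
        assert list(grouped.columns) == ["Pre_1"]


class TestTrim:
    EDGES = [CorrelationEdge("G", "Pre_1", "Prot_1", 0.8, 1e-9, 1e-7, 12, 50)]

    def test_restricts_to_network_groups(self):
        expr = pd.DataFrame(
            np.ones((3, 5)),
            columns=["Pre_1", "Pre_2", "Prot_1", "Prot_2", "Prot_3"],
        )
        trimmed = trim_to_network(expr, self.EDGES)
        assert sorted(trimmed.columns) == ["Pre_1", "Prot_1"]

    def test_identity_when_all_columns_in_network(self):
        expr = pd.DataFrame(np.ones((3, 2)), columns=["Pre_1", "Prot_1"])
        assert trim_to_network(expr, self.EDGES).equals(expr)

    def test_disjoint_inputs_are_an_error(self):
        expr = pd.DataFrame(np.ones((3, 1)), columns=["Pre_9"])
        with pytest.raises(ValueError, match="refinement impossible"):
            trim_to_network(expr, self.EDGES)


class TestCoexpressionEdges:
    def test_perfect_coexpression_kept(self):
        x = np.arange(12, dtype=float)
        expr = pd.DataFrame({"Pre_1": x, "Prot_1": x**2 + 1})  # same ranks
        edges = coexpression_edges(expr)
        assert len(edges) == 1
        assert edges[0].rho == pytest.approx(1.0)

    def test_rho_exactly_at_threshold_excluded(self):
        # permutation (4,1,2,3,5) of ranks has Spearman rho exactly 0.4
        expr = pd.DataFrame({"Pre_1": [1, 2, 3, 4, 5], "Prot_1": [4, 1, 2, 3, 5]})
        assert spearman_check(expr) == pytest.approx(0.4)
        assert coexpression_edges(expr, rho_min=0.4, padj_max=1.0) == []

    def test_too_few_samples_is_an_error(self):
        expr = pd.DataFrame({"Pre_1": [1.0, 2.0], "Prot_1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 samples"):
            coexpression_edges(expr)

    def test_null_columns_raw_p_calibrated(self):
        """Independent expression: about 5% of raw p below 0.05 across 500 pairs."""
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(
            rng.lognormal(3, 1, (20, 45)),
            columns=[f"Pre_{i}" for i in range(20)] + [f"Prot_{i}" for i in range(25)],
        )
        edges = coexpression_edges(expr, rho_min=-1.1, padj_max=2.0, keep_all=True)
        assert len(edges) == 500
        frac = np.mean([e.p < 0.05 for e in edges])
        assert frac == pytest.approx(0.05, abs=0.03)


def spearman_check(expr):
    from lanthnet.corrnet import spearman_rho

    return spearman_rho(expr["Pre_1"].to_numpy(), expr["Prot_1"].to_numpy())


def coedge(pre="Pre_1", prot="Prot_1", rho=0.8, p_adj=0.01):
    return CoexpressionEdge(pre, prot, rho, p_adj / 2, p_adj, 12)


class TestCombineStrains:
    def test_edge_in_all_strains_retained(self):
        strains = [[coedge()], [coedge(rho=0.7)], [coedge(rho=0.9)]]
        combined = combine_strains(strains)
        assert [e.key for e in combined] == [("Pre_1", "Prot_1")]

    def test_edge_in_two_of_three_dropped_under_all(self):
        strains = [[coedge()], [coedge()], []]
        assert combine_strains(strains, mode="all") == []
        assert [e.key for e in combine_strains(strains, mode="any")] == [("Pre_1", "Prot_1")]

    def test_single_strain_is_identity(self):
        edges = [coedge(), coedge(prot="Prot_2")]
        assert {e.key for e in combine_strains([edges])} == {e.key for e in edges}


class TestIntersectEvidence:
    def genomic(self, prot):
        return CorrelationEdge("G", "Pre_5", prot, 0.8, 1e-9, 1e-7, 12, 50)

    def test_two_genomic_partners_reduced_to_one_coexpressed(self):
        genomic = [self.genomic("Prot_241"), self.genomic("Prot_1365")]
        coexpr = [coedge("Pre_5", "Prot_241")]
        candidates = intersect_evidence(genomic, coexpr)
        assert [c.key for c in candidates] == [("Pre_5", "Prot_241")]
        assert candidates[0].genomic.I == 12
        assert candidates[0].coexpression.rho == pytest.approx(0.8)

    def test_disjoint_sets_give_empty(self):
        assert intersect_evidence([self.genomic("Prot_1")], [coedge("Pre_5", "Prot_9")]) == []

    def test_output_is_subset_of_each_input(self):
        genomic = [self.genomic(f"Prot_{i}") for i in range(34)]
        coexpr = [coedge("Pre_5", f"Prot_{i}") for i in (1, 5, 9, 30)]
        candidates = intersect_evidence(genomic, coexpr)
        assert len(candidates) == 4
        assert {c.key for c in candidates} <= {e.key for e in genomic}
        assert {c.key for c in candidates} <= {e.key for e in coexpr}
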