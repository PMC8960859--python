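import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lanthnet.corrnet import (
    assemble_network,
    average_ranks,
    bh_adjust,
    build_count_matrix,
    correlate_genus,
    filter_edges,
    genus_partition,
    one_sided_p,
    spearman_rho,
    volcano_table,
)
from lanthnet.types import CorrelationEdge, GenomeRecord, GroupAssignment


class TestSpearman:
    def test_identical_rankings(self):
        assert spearman_rho([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_values_use_average_ranks(self):
        # ranks x = (1, 2.5, 2.5, 4), y = (1, 3, 2, 4); Pearson of ranks = 0.9487
        assert spearman_rho([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(0.9486832980505138)

    def test_constant_vector_is_undefined(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.lists(st.integers(0, 20), min_size=4, max_size=30),
        seed=st.integers(0, 2**16),
    )
    def test_invariance_under_strictly_monotone_transforms(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.poisson(2.0, len(x)).tolist()
        base = spearman_rho(x, y)
        if math.isnan(base):
            return
        transformed = spearman_rho([v**3 + 2 * v for v in x], [math.exp(0.5 * v) for v in y])
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        for _ in range(200):
            x = rng.poisson(1.0, 20)
            y = rng.poisson(1.0, 20)
            expected = stats.spearmanr(x, y).statistic
            got = spearman_rho(x, y)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestOneSidedP:
    def test_zero_rho_gives_half(self):
        assert one_sided_p(0.0, 10) == pytest.approx(0.5)

    def test_clamped_limits(self):
        assert one_sided_p(1.0, 10) == 0.0
        assert one_sided_p(-1.0, 10) == 1.0

    def test_known_value(self):
        # t = 0.6 * sqrt(10 / 0.64), df = 10
        assert one_sided_p(0.6, 12) == pytest.approx(0.0196, abs=2e-4)

    def test_small_n_is_an_error(self):
        with pytest.raises(ValueError):
            one_sided_p(0.5, 2)

    def test_negative_rho_gives_p_near_one(self):
        assert one_sided_p(-0.8, 20) > 0.99

    def test_exact_permutation_p_at_perfect_correlation(self):
        # exactly 1 of n! permutations reaches rho = 1
        assert one_sided_p(1.0, 4, exact=True) == pytest.approx(1 / 24)

    def test_exact_permutation_close_to_t_approximation(self):
        for rho in (0.0, 0.4, 0.8):
            exact = one_sided_p(rho, 8, exact=True)
            approx = one_sided_p(rho, 8)
            assert exact == pytest.approx(approx, abs=0.05)


class TestBH:
    def test_textbook_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_pvalues_invariant(self):
        assert bh_adjust([0.05, 0.05, 0.05]) == pytest.approx([0.05, 0.05, 0.05])

    def test_single_pvalue_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_order_preserved(self, pvals):
        adjusted = bh_adjust(pvals)
        assert all(a >= p - 1e-15 for a, p in zip(adjusted, pvals))
        assert all(a <= 1.0 for a in adjusted)
        order_raw = np.argsort(np.argsort(pvals, kind="stable"), kind="stable")
        # sorted order of adjusted values follows sorted order of raw p-values
        assert all(
            adjusted[i] <= adjusted[j] + 1e-15
            for i in range(len(pvals))
            for j in range(len(pvals))
            if pvals[i] < pvals[j]
        )

    def test_matches_statsmodels_on_random_lists(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 50))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)


class TestCountMatrix:
    def test_direct_counting_with_zero_rows(self):
        assigns = [
            GroupAssignment("m1", "Pre_1", "precursor"),
            GroupAssignment("m2", "Pre_1", "precursor"),
        ]
        mat = build_count_matrix(assigns, {"m1": "g1", "m2": "g1"}, ["g1", "g2"])
        assert mat["Pre_1"].tolist() == [2, 0]

    def test_empty_assignments_give_all_zero_matrix(self):
        mat = build_count_matrix([], {}, ["g1", "g2"])
        assert mat.shape == (2, 0)

    def test_column_sums_equal_group_sizes(self):
        rng = np.random.default_rng(1)
        genomes = [f"g{i}" for i in range(6)]
        assigns, mapping = [], {}
        for i in range(40):
            member = f"m{i}"
            assigns.append(GroupAssignment(member, f"Pre_{1 + i % 3}", "precursor"))
            mapping[member] = genomes[rng.integers(0, 6)]
        mat = build_count_matrix(assigns, mapping, genomes)
        sizes = pd.Series([a.group_id for a in assigns]).value_counts()
        for group in mat.columns:
            assert mat[group].sum() == sizes[group]

    def test_unknown_genome_is_an_error(self):
        assigns = [GroupAssignment("m1", "Pre_1", "precursor")]
        with pytest.raises(ValueError, match="unknown genome"):
            build_count_matrix(assigns, {"m1": "gX"}, ["g1"])


def _matrices(pre_cols, prot_cols, genomes):
    pre = pd.DataFrame(pre_cols, index=genomes)
    prot = pd.DataFrame(prot_cols, index=genomes)
    return pre, prot


class TestCorrelateGenus:
    def test_perfect_dependence_gives_rho_one(self):
        genomes = [f"g{i}" for i in range(20)]
        counts = list(range(20))
        pre, prot = _matrices({"Pre_1": counts}, {"Prot_1": counts}, genomes)
        edges = correlate_genus(pre, prot, {"G": genomes})
        assert len(edges) == 1
        e = edges[0]
        assert e.rho == pytest.approx(1.0)
        assert e.p == 0.0
        assert e.I == sum(1 for c in counts if c > 0)
        assert e.n == 20

    def test_absent_group_emits_no_edge(self):
        genomes = ["g1", "g2", "g3"]
        pre, prot = _matrices({"Pre_1": [0, 0, 0]}, {"Prot_1": [1, 2, 1]}, genomes)
        assert correlate_genus(pre, prot, {"G": genomes}) == []

    def test_constant_vector_flagged_undefined_and_outside_bh_family(self):
        genomes = [f"g{i}" for i in range(10)]
        pre, prot = _matrices(
            {"Pre_1": [3] * 10, "Pre_2": list(range(10))},
            {"Prot_1": list(range(10))},
            genomes,
        )
        edges = correlate_genus(pre, prot, {"G": genomes})
        by_pre = {e.pre_group: e for e in edges}
        assert math.isnan(by_pre["Pre_1"].rho) and math.isnan(by_pre["Pre_1"].p_adj)
        # BH family has a single defined test, so p_adj == p
        assert by_pre["Pre_2"].p_adj == pytest.approx(by_pre["Pre_2"].p)

    def test_empty_partition_is_an_error(self):
        pre, prot = _matrices({"Pre_1": [1]}, {"Prot_1": [1]}, ["g1"])
        with pytest.raises(ValueError):
            correlate_genus(pre, prot, {})

    def test_null_type_one_error_rate_is_calibrated(self):
        """Independent count columns: about 5% of raw one-sided p fall below 0.05."""
        rng = np.random.default_rng(17)
        genomes = [f"g{i}" for i in range(50)]
        pre = pd.DataFrame(rng.poisson(1.0, (50, 40)), index=genomes,
                           columns=[f"Pre_{i}" for i in range(40)])
        prot = pd.DataFrame(rng.poisson(1.0, (50, 25)), index=genomes,
                            columns=[f"Prot_{i}" for i in range(25)])
        edges = correlate_genus(pre, prot, {"G": genomes})
        pvals = [e.p for e in edges if e.defined]
        frac = np.mean([p < 0.05 for p in pvals])
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_per_genus_bh_scope(self):
        genomes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(2)
        pre = pd.DataFrame(rng.poisson(1, (12, 3)), index=genomes,
                           columns=["Pre_1", "Pre_2", "Pre_3"])
        prot = pd.DataFrame(rng.poisson(1, (12, 3)), index=genomes,
                            columns=["Prot_1", "Prot_2", "Prot_3"])
        part = {"A": genomes[:6], "B": genomes[6:]}
        pooled = correlate_genus(pre, prot, part, bh_scope="pooled")
        per_genus = correlate_genus(pre, prot, part, bh_scope="per-genus")
        assert {(e.genus, e.pre_group, e.prot_group) for e in pooled} == {
            (e.genus, e.pre_group, e.prot_group) for e in per_genus
        }
        # raw statistics identical; only the adjustment family differs
        for a, b in zip(pooled, per_genus):
            assert a.p == b.p and (a.rho == b.rho or (math.isnan(a.rho) and math.isnan(b.rho)))


class TestFilterEdges:
    def edge(self, rho, p_adj, I):
        return CorrelationEdge("G", "Pre_1", "Prot_1", rho, p_adj / 2, p_adj, I, 50)

    def test_rho_comparison_is_strict(self):
        assert filter_edges([self.edge(0.30, 1e-7, 12)]) == []

    def test_support_comparison_is_inclusive(self):
        assert len(filter_edges([self.edge(0.9, 1e-7, 10)])) == 1

    def test_padj_comparison_is_strict(self):
        assert filter_edges([self.edge(0.9, 1e-5, 12)]) == []

    def test_undefined_rho_never_passes(self):
        assert filter_edges([self.edge(float("nan"), 1e-9, 50)]) == []


class TestNetworkAndVolcano:
    def make_edges(self):
        return [
            CorrelationEdge("G", "Pre_1", "Prot_1", 0.8, 1e-9, 1e-7, 12, 50),
            CorrelationEdge("G", "Pre_1", "Prot_2", 0.5, 1e-6, 1e-5, 11, 50),
        ]

    def test_shared_precursor_gives_three_nodes_two_edges(self):
        graph = assemble_network(self.make_edges())
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2
        assert graph.nodes["Pre_1"]["kind"] == "precursor"
        assert graph.nodes["Prot_1"]["kind"] == "protease"

    def test_zero_padj_floored_before_log(self):
        edges = [CorrelationEdge("G", "Pre_1", "Prot_1", 1.0, 0.0, 0.0, 12, 50)]
        table = volcano_table(edges, epsilon=1e-300)
        assert table["neg_log10_p_adj"].iloc[0] == pytest.approx(300.0)

    def test_empty_edges_give_empty_graph_and_table(self):
        assert assemble_network([]).number_of_nodes() == 0
        assert volcano_table([]).empty

    def test_genus_partition_covers_all_genomes(self):
        genomes = [GenomeRecord("g1", "A"), GenomeRecord("g2", "B"), GenomeRecord("g3", "A")]
        part = genus_partition(genomes)
        assert part == {"A": ["g1", "g3"], "B": ["g2"]}
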