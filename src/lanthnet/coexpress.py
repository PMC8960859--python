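"""Transcriptomic refinement of the genomic correlation network.

Per-gene read counts are normalized to transcripts per million (TPM), summed
within precursor/protease groups to a samples × groups matrix, trimmed to the
groups present in the genomic network, and tested pairwise by Spearman
correlation with one-sided p-values and per-strain Benjamini–Hochberg
adjustment.  Edges recurring in every strain are combined, and the genomic and
co-expression edge sets are intersected to yield candidate precursor-protease
pairs — the step that shrinks a precursor's many genomically correlated
partners to the few that are also co-expressed with it.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corrnet import bh_adjust, one_sided_p, spearman_rho
from .types import CandidateEdge, CoexpressionEdge, CorrelationEdge, GroupAssignment

DEFAULT_RHO_MIN = 0.4
DEFAULT_PADJ_MAX = 0.05


def tpm_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Samples × genes TPM matrix from a long count table.

    ``counts`` has columns sample_id, gene_id, count, length.  For each sample,
    rate_i = count_i / length_i and TPM_i = 1e6 * rate_i / sum_j rate_j; a
    sample with no expressed gene yields an all-zero row.  Negative counts and
    non-positive lengths are errors.
    """
    required = {"sample_id", "gene_id", "count", "length"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing column(s): {sorted(missing)}")
    if (counts["count"] < 0).any():
        bad = counts.loc[counts["count"] < 0, "gene_id"].iloc[0]
        raise ValueError(f"negative count for gene {bad!r}")
    if (counts["length"] <= 0).any():
        bad = counts.loc[counts["length"] <= 0, "gene_id"].iloc[0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    wide_counts = counts.pivot_table(
        index="sample_id", columns="gene_id", values="count", fill_value=0.0
    )
    lengths = counts.drop_duplicates("gene_id").set_index("gene_id")["length"]
    rate = wide_counts / lengths.reindex(wide_counts.columns).to_numpy(dtype=float)
    totals = rate.sum(axis=1)
    tpm = rate.mul(1e6).div(totals.replace(0.0, np.nan), axis=0).fillna(0.0)
    tpm.index.name = "sample_id"
    tpm.columns.name = None
    return tpm.sort_index(axis=0).sort_index(axis=1)


def group_tpm(
    expr: pd.DataFrame, assignments: Iterable[GroupAssignment]
) -> pd.DataFrame:
    """Sum gene-level TPM within groups → samples × groups matrix.

    Genes without an assignment are ignored; groups with no expressed gene in
    the matrix simply have no column.
    """
    gene_to_group = {a.member_id: a.group_id for a in assignments}
    covered = [g for g in expr.columns if g in gene_to_group]
    if not covered:
        return pd.DataFrame(index=expr.index)
    grouped = expr[covered].T.groupby(
        [gene_to_group[g] for g in covered]
    ).sum().T
    grouped.columns.name = None
    return grouped.sort_index(axis=1)


def trim_to_network(
    expr_groups: pd.DataFrame, network_edges: Sequence[CorrelationEdge]
) -> pd.DataFrame:
    """Restrict group columns to groups appearing in the genomic network.

    A complete lack of overlap signals mismatched inputs and is an error —
    refinement would be impossible.
    """
    network_groups = {e.pre_group for e in network_edges} | {
        e.prot_group for e in network_edges
    }
    kept = [c for c in expr_groups.columns if c in network_groups]
    if not kept:
        raise ValueError(
            "no expression-matrix group appears in the correlation network; "
            "refinement impossible (mismatched inputs?)"
        )
    return expr_groups[kept]


def coexpression_edges(
    expr_groups: pd.DataFrame,
    rho_min: float = DEFAULT_RHO_MIN,
    padj_max: float = DEFAULT_PADJ_MAX,
    keep_all: bool = False,
) -> list[CoexpressionEdge]:
    """Spearman co-expression tests between precursor and protease groups.

    Columns are split by their ``Pre_``/``Prot_`` label prefix; every
    precursor-group × protease-group pair is tested across samples, with BH
    adjustment over this matrix's family of tests.  Kept iff rho > rho_min and
    pAdj < padj_max (both strict) unless ``keep_all``.  Fewer than three
    samples is an error.
    """
    n = len(expr_groups.index)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    pre_cols = sorted(c for c in expr_groups.columns if c.startswith("Pre_"))
    prot_cols = sorted(c for c in expr_groups.columns if c.startswith("Prot_"))
    tests: list[tuple[str, str, float, float]] = []
    for pre_g in pre_cols:
        x = expr_groups[pre_g].to_numpy(dtype=float)
        for prot_g in prot_cols:
            y = expr_groups[prot_g].to_numpy(dtype=float)
            rho = spearman_rho(x, y)
            if np.isnan(rho):
                continue  # constant profile: test undefined, excluded from family
            tests.append((pre_g, prot_g, rho, one_sided_p(rho, n)))
    adjusted = bh_adjust([t[3] for t in tests])
    edges = [
        CoexpressionEdge(pre, prot, rho, p, p_adj, n)
        for (pre, prot, rho, p), p_adj in zip(tests, adjusted)
    ]
    if keep_all:
        return edges
    return [e for e in edges if e.rho > rho_min and e.p_adj < padj_max]


def combine_strains(
    per_strain_edges: Sequence[Sequence[CoexpressionEdge]], mode: str = "all"
) -> list[CoexpressionEdge]:
    """Combine per-strain co-expression edges across strains.

    ``mode="all"`` keeps pairs present in every strain's edge list (default,
    the strict reading); ``mode="any"`` takes the union.  The representative
    edge kept for a pair is the one with the smallest adjusted p-value.
    """
    if not per_strain_edges:
        raise ValueError("need at least one strain edge list")
    if mode not in ("all", "any"):
        raise ValueError(f"unknown combine mode {mode!r}")
    key_sets = [{e.key for e in edges} for edges in per_strain_edges]
    kept = set.intersection(*key_sets) if mode == "all" else set.union(*key_sets)
    best: dict[tuple[str, str], CoexpressionEdge] = {}
    for edges in per_strain_edges:
        for e in edges:
            if e.key in kept and (e.key not in best or e.p_adj < best[e.key].p_adj):
                best[e.key] = e
    return [best[k] for k in sorted(kept)]


def intersect_evidence(
    genomic_edges: Iterable[CorrelationEdge],
    coexpr_edges: Iterable[CoexpressionEdge],
) -> list[CandidateEdge]:
    """Candidate pairs supported by both genomic correlation and co-expression.

    Keyed by (precursor group, protease group); each candidate carries both
    evidence records.  When a pair is genomically significant in several
    genera, the edge with the smallest adjusted p-value represents it.
    """
    genomic_best: dict[tuple[str, str], CorrelationEdge] = {}
    for e in genomic_edges:
        if e.key not in genomic_best or e.p_adj < genomic_best[e.key].p_adj:
            genomic_best[e.key] = e
    coexpr_by_key = {e.key: e for e in coexpr_edges}
    shared = sorted(set(genomic_best) & set(coexpr_by_key))
    return [
        CandidateEdge(pre, prot, genomic_best[(pre, prot)], coexpr_by_key[(pre, prot)])
        for pre, prot in shared
    ]
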