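"""Per-genus Spearman correlation networks over group-occurrence counts.

The central statistic of the pipeline: occurrences of every precursor group
and protease group are counted per genome; within each genus, every
precursor-group × protease-group pair with both groups present in at least one
genome is tested by Spearman rank correlation over the counts of *all* genomes
of the genus.  A one-sided p-value (upper tail: the workflow looks for
positive co-occurrence) comes from the t approximation

    t = rho * sqrt((n - 2) / (1 - rho^2)),   df = n - 2,

with clamped limits at |rho| = 1.  P-values are Benjamini–Hochberg adjusted —
by default once across all genus-level tests pooled (the conservative reading;
per-genus families are available) — and edges are prioritized by
rho > 0.3, pAdj < 1e-5, and genome support I >= 10.

Rank correlation is used deliberately: group-occurrence counts are sparse,
zero-inflated and far from normal, and Spearman's rho depends only on ranks.
Constant count vectors leave rho undefined; such pairs are flagged, excluded
from the multiple-testing family (silently assigning rho = 0 would inflate the
test count), and never enter the filters.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import CorrelationEdge, GenomeRecord, GroupAssignment

DEFAULT_RHO_MIN = 0.3
DEFAULT_PADJ_MAX = 1e-5
DEFAULT_MIN_I = 10


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean rank of the tied block."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _rank_columns(m: np.ndarray) -> np.ndarray:
    return np.column_stack([average_ranks(m[:, j]) for j in range(m.shape[1])])


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks.

    Returns NaN when either vector is constant (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two observations")
    rx, ry = average_ranks(x), average_ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    sx, sy = np.sqrt((dx**2).sum()), np.sqrt((dy**2).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((dx * dy).sum() / (sx * sy))


def one_sided_p(rho: float, n: int, exact: bool = False) -> float:
    """Upper-tail p-value for a positive Spearman correlation.

    Student-t approximation with ``n - 2`` degrees of freedom; the limits are
    clamped: rho = 1 gives 0, rho = -1 gives 1.  ``exact=True`` switches to the
    exact permutation null (all n! rank permutations), feasible for n <= 10.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if math.isnan(rho):
        raise ValueError("rho is undefined")
    if exact:
        if n > 10:
            raise ValueError("exact permutation p-value only supported for n <= 10")
        return _exact_permutation_p(rho, n)
    if rho >= 1.0:
        return 0.0
    if rho <= -1.0:
        return 1.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(stats.t.sf(t, df=n - 2))


def _exact_permutation_p(rho: float, n: int) -> float:
    """P(rho_perm >= rho) under the uniform-permutation null of untied ranks."""
    base = np.arange(1, n + 1, dtype=float)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = spearman_rho(base, base[list(perm)])
        if r >= rho - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()


def genus_partition(genomes: Iterable[GenomeRecord]) -> dict[str, list[str]]:
    """genus → sorted genome ids; every genus has at least one genome."""
    part: dict[str, list[str]] = {}
    for g in genomes:
        part.setdefault(g.genus, []).append(g.genome_id)
    return {genus: sorted(ids) for genus, ids in sorted(part.items())}


def build_count_matrix(
    assignments: Iterable[GroupAssignment],
    member_to_genome: Mapping[str, str],
    genomes: Sequence[GenomeRecord | str],
) -> pd.DataFrame:
    """Genomes × groups occurrence-count matrix.

    Cell (g, G) is the number of members of group G located in genome g.
    Genomes without any member appear as all-zero rows; a member mapping to an
    unlisted genome is an error.
    """
    genome_ids = [g.genome_id if isinstance(g, GenomeRecord) else g for g in genomes]
    assignments = list(assignments)
    groups = sorted({a.group_id for a in assignments})
    row_of = {g: i for i, g in enumerate(genome_ids)}
    col_of = {g: j for j, g in enumerate(groups)}
    values = np.zeros((len(genome_ids), len(groups)), dtype=int)
    for a in assignments:
        genome = member_to_genome.get(a.member_id)
        if genome is None:
            raise ValueError(f"member {a.member_id!r} has no genome mapping")
        row = row_of.get(genome)
        if row is None:
            raise ValueError(f"member {a.member_id!r} maps to unknown genome {genome!r}")
        values[row, col_of[a.group_id]] += 1
    return pd.DataFrame(
        values, index=pd.Index(genome_ids, name="genome_id"), columns=groups
    )


def correlate_genus(
    pre_counts: pd.DataFrame,
    prot_counts: pd.DataFrame,
    partition: Mapping[str, Sequence[str]],
    bh_scope: str = "pooled",
    exact_p: bool = False,
) -> list[CorrelationEdge]:
    """Test every precursor × protease group pair within each genus.

    A pair is tested in a genus iff both groups occur in at least one genome of
    the genus; the correlation itself runs over the counts of all ``n`` genomes
    of the genus.  ``I`` is the number of genomes containing both groups.
    ``bh_scope`` is ``"pooled"`` (one family across all genera, default) or
    ``"per-genus"``.
    """
    if not partition:
        raise ValueError("genus partition is empty")
    if bh_scope not in ("pooled", "per-genus"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")

    records: list[tuple[str, str, str, float, float, int, int]] = []
    for genus in sorted(partition):
        genome_ids = list(partition[genus])
        missing = [g for g in genome_ids if g not in pre_counts.index]
        if missing:
            raise ValueError(f"genus {genus!r}: genomes missing from count matrix: {missing}")
        pre = pre_counts.loc[genome_ids]
        prot = prot_counts.loc[genome_ids]
        n = len(genome_ids)
        pre_cols = [c for c in pre.columns if pre[c].to_numpy().sum() > 0]
        prot_cols = [c for c in prot.columns if prot[c].to_numpy().sum() > 0]
        if not pre_cols or not prot_cols or n < 3:
            continue
        pm = pre[pre_cols].to_numpy(dtype=float)
        qm = prot[prot_cols].to_numpy(dtype=float)

        rp, rq = _rank_columns(pm), _rank_columns(qm)
        zp = rp - rp.mean(axis=0)
        zq = rq - rq.mean(axis=0)
        sp = np.sqrt((zp**2).sum(axis=0))
        sq = np.sqrt((zq**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (zp.T @ zq) / np.outer(sp, sq)  # NaN where a vector is constant
        support = (pm > 0).T.astype(int) @ (qm > 0).astype(int)

        for i, pre_g in enumerate(pre_cols):
            for j, prot_g in enumerate(prot_cols):
                r = float(rho[i, j])
                if math.isnan(r):
                    p = float("nan")
                else:
                    p = one_sided_p(r, n, exact=exact_p)
                records.append((genus, pre_g, prot_g, r, p, int(support[i, j]), n))

    defined_idx = [k for k, rec in enumerate(records) if not math.isnan(rec[3])]
    p_adj = [float("nan")] * len(records)
    if bh_scope == "pooled":
        adjusted = bh_adjust([records[k][4] for k in defined_idx])
        for k, a in zip(defined_idx, adjusted):
            p_adj[k] = a
    else:
        by_genus: dict[str, list[int]] = {}
        for k in defined_idx:
            by_genus.setdefault(records[k][0], []).append(k)
        for idxs in by_genus.values():
            adjusted = bh_adjust([records[k][4] for k in idxs])
            for k, a in zip(idxs, adjusted):
                p_adj[k] = a

    return [
        CorrelationEdge(genus, pre_g, prot_g, rho=r, p=p, p_adj=p_adj[k], I=i_cnt, n=n)
        for k, (genus, pre_g, prot_g, r, p, i_cnt, n) in enumerate(records)
    ]


def filter_edges(
    edges: Iterable[CorrelationEdge],
    rho_min: float = DEFAULT_RHO_MIN,
    padj_max: float = DEFAULT_PADJ_MAX,
    min_i: int = DEFAULT_MIN_I,
) -> list[CorrelationEdge]:
    """Prioritization filter: rho > rho_min, pAdj < padj_max, I >= min_i.

    The rho and pAdj comparisons are strict, the genome-support comparison is
    not; undefined-rho edges never pass.
    """
    return [
        e
        for e in edges
        if e.defined and e.rho > rho_min and e.p_adj < padj_max and e.I >= min_i
    ]


def assemble_network(
    edges: Sequence[CorrelationEdge],
    member_counts: Optional[Mapping] = None,
) -> nx.Graph:
    """Bipartite precursor/protease graph.

    Node attribute ``size`` carries the genus-level member count of the group
    when ``member_counts`` is given (keyed by group id, or by
    ``(genus, group id)``); edge attribute ``weight`` carries rho so edge width
    can encode correlation strength.
    """
    graph = nx.Graph()
    for e in edges:
        if not e.defined:
            continue
        for node, kind in ((e.pre_group, "precursor"), (e.prot_group, "protease")):
            if node not in graph:
                graph.add_node(node, kind=kind, bipartite=0 if kind == "precursor" else 1)
            if member_counts is not None:
                count = member_counts.get((e.genus, node), member_counts.get(node))
                if count is not None:
                    graph.nodes[node]["size"] = int(count)
        graph.add_edge(
            e.pre_group, e.prot_group, weight=float(e.rho), p_adj=float(e.p_adj),
            I=int(e.I), genus=e.genus,
        )
    return graph


def volcano_table(
    edges: Iterable[CorrelationEdge], epsilon: float = 1e-300
) -> pd.DataFrame:
    """(rho, −log10 pAdj) per tested pair, for volcano plotting.

    Adjusted p-values are floored at ``epsilon`` before the log so clamped
    p = 0 cases stay finite; undefined-rho pairs are omitted.
    """
    rows = [
        {
            "genus": e.genus,
            "pre_group": e.pre_group,
            "prot_group": e.prot_group,
            "rho": e.rho,
            "neg_log10_p_adj": -math.log10(max(e.p_adj, epsilon)),
        }
        for e in edges
        if e.defined
    ]
    return pd.DataFrame(
        rows, columns=["genus", "pre_group", "prot_group", "rho", "neg_log10_p_adj"]
    )
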