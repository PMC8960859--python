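"""Readers and writers for the tabular, sequence, and network formats.

All tables are UTF-8 TSV with a fixed header; missing optional fields are
serialized as ``"."``.  An undefined Spearman rho (constant count vector) is
serialized as ``"NA"`` rather than silently dropped.  Every writer/reader pair
round-trips exactly (floats are written with ``repr`` precision).
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    BgcRecord,
    CoexpressionEdge,
    CorrelationEdge,
    DomainHit,
    GenomeRecord,
    GroupAssignment,
    ProteinFeature,
)

MISSING = "."

ANNOTATION_COLUMNS = [
    "genome_id",
    "genus",
    "organism",
    "protein_id",
    "contig",
    "start",
    "end",
    "strand",
    "product",
    "bgc_id",
    "bgc_start",
    "bgc_end",
    "lan_class",
    "anchor_start",
    "anchor_end",
]

DOMAIN_COLUMNS = ["protein_id", "pfam_acc", "score"]
ASSIGNMENT_COLUMNS = ["member_id", "group_id", "group_kind"]
EDGE_COLUMNS = ["genus", "pre_group", "prot_group", "rho", "p", "p_adj", "I", "n"]
COEXPR_COLUMNS = ["pre_group", "prot_group", "rho", "p", "p_adj", "n_samples"]
GENE_COUNT_COLUMNS = ["sample_id", "gene_id", "count", "length"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _opt(value: str) -> Optional[str]:
    return None if value == MISSING or value == "" else value


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return "NA" if math.isnan(value) else repr(value)
    return str(value)


def read_annotation_table(
    path: str,
) -> tuple[list[GenomeRecord], list[ProteinFeature], list[BgcRecord]]:
    """Parse one annotation TSV into typed genome, protein, and BGC records.

    One row per protein.  BGC records are assembled from the rows that carry a
    ``bgc_id``; all rows of a BGC must agree on its coordinates and class.
    Referential integrity is validated: a row with ``bgc_id`` set but no BGC
    coordinates is a hard error listing the offenders.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, str(path))

    genomes: dict[str, GenomeRecord] = {}
    features: list[ProteinFeature] = []
    bgc_rows: dict[str, dict] = {}
    dangling: list[str] = []

    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        gid = row.genome_id
        if gid not in genomes:
            genomes[gid] = GenomeRecord(gid, row.genus, _opt(row.organism))
        elif genomes[gid].genus != row.genus:
            raise ValueError(f"{path}: genome {gid!r} listed with two genera (line {i})")
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: non-integer coordinate") from exc
        try:
            feat = ProteinFeature(
                protein_id=row.protein_id,
                genome_id=gid,
                contig=row.contig,
                start=start,
                end=end,
                strand=row.strand,
                product=row.product,
                bgc_id=_opt(row.bgc_id),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        features.append(feat)

        if feat.bgc_id is not None:
            if _opt(row.bgc_start) is None or _opt(row.bgc_end) is None:
                dangling.append(f"{feat.protein_id} -> {feat.bgc_id}")
                continue
            rec = {
                "bgc_id": feat.bgc_id,
                "genome_id": gid,
                "contig": row.contig,
                "start": int(row.bgc_start),
                "end": int(row.bgc_end),
                "lan_class": _opt(row.lan_class) or "unknown",
                "anchor_start": int(row.anchor_start) if _opt(row.anchor_start) else None,
                "anchor_end": int(row.anchor_end) if _opt(row.anchor_end) else None,
            }
            prev = bgc_rows.setdefault(feat.bgc_id, rec)
            if prev != rec and (prev["start"], prev["end"]) != (rec["start"], rec["end"]):
                raise ValueError(
                    f"{path}: BGC {feat.bgc_id!r} has inconsistent coordinates (line {i})"
                )

    if dangling:
        raise ValueError(
            f"{path}: bgc_id set without BGC coordinates for: {', '.join(dangling)}"
        )

    seen: set[str] = set()
    for feat in features:
        if feat.protein_id in seen:
            raise ValueError(f"{path}: duplicate protein_id {feat.protein_id!r}")
        seen.add(feat.protein_id)

    bgcs = [BgcRecord(**rec) for rec in bgc_rows.values()]
    return list(genomes.values()), features, bgcs


def write_annotation_table(
    genomes: Iterable[GenomeRecord],
    features: Iterable[ProteinFeature],
    bgcs: Iterable[BgcRecord],
    path: str,
) -> None:
    genome_by_id = {g.genome_id: g for g in genomes}
    bgc_by_id = {b.bgc_id: b for b in bgcs}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for f in features:
            g = genome_by_id[f.genome_id]
            b = bgc_by_id.get(f.bgc_id) if f.bgc_id else None
            row = [
                f.genome_id,
                g.genus,
                _fmt(g.organism),
                f.protein_id,
                f.contig,
                str(f.start),
                str(f.end),
                f.strand,
                f.product,
                _fmt(f.bgc_id),
                _fmt(b.start if b else None),
                _fmt(b.end if b else None),
                _fmt(b.lan_class if b else None),
                _fmt(b.anchor_start if b else None),
                _fmt(b.anchor_end if b else None),
            ]
            fh.write("\t".join(row) + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an id → sequence mapping; duplicate ids are an error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_domain_hits(path: str) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, DOMAIN_COLUMNS, str(path))
    return [
        DomainHit(r.protein_id, r.pfam_acc, float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_domain_hits(hits: Iterable[DomainHit], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(DOMAIN_COLUMNS) + "\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.pfam_acc}\t{_fmt(h.score)}\n")


def read_assignments(path: str) -> list[GroupAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ASSIGNMENT_COLUMNS, str(path))
    return [
        GroupAssignment(r.member_id, r.group_id, r.group_kind)
        for r in df.itertuples(index=False)
    ]


def write_assignments(assignments: Iterable[GroupAssignment], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in assignments:
            fh.write(f"{a.member_id}\t{a.group_id}\t{a.group_kind}\n")


def read_count_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(int)


def write_count_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_edge_table(path: str) -> list[CorrelationEdge]:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[], comment=None
    )
    _require_columns(df, EDGE_COLUMNS, str(path))
    return [
        CorrelationEdge(
            genus=r.genus,
            pre_group=r.pre_group,
            prot_group=r.prot_group,
            rho=_float_or_na(r.rho),
            p=_float_or_na(r.p),
            p_adj=_float_or_na(r.p_adj),
            I=int(r.I),
            n=int(r.n),
        )
        for r in df.itertuples(index=False)
    ]


def _float_or_na(value: str) -> float:
    return float("nan") if value == "NA" else float(value)


def write_edge_table(edges: Iterable[CorrelationEdge], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in edges:
            fh.write(
                "\t".join(
                    [e.genus, e.pre_group, e.prot_group, _fmt(e.rho), _fmt(e.p),
                     _fmt(e.p_adj), str(e.I), str(e.n)]
                )
                + "\n"
            )


def read_coexpression_edges(path: str) -> list[CoexpressionEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, COEXPR_COLUMNS, str(path))
    return [
        CoexpressionEdge(
            pre_group=r.pre_group,
            prot_group=r.prot_group,
            rho=float("nan") if r.rho == "NA" else float(r.rho),
            p=float(r.p),
            p_adj=float(r.p_adj),
            n_samples=int(r.n_samples),
        )
        for r in df.itertuples(index=False)
    ]


def write_coexpression_edges(edges: Iterable[CoexpressionEdge], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(COEXPR_COLUMNS) + "\n")
        for e in edges:
            fh.write(
                "\t".join(
                    [e.pre_group, e.prot_group, _fmt(e.rho), _fmt(e.p), _fmt(e.p_adj),
                     str(e.n_samples)]
                )
                + "\n"
            )


def read_expression_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_counts(path: str) -> pd.DataFrame:
    """Read a per-gene read-count table (sample_id, gene_id, count, length)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, GENE_COUNT_COLUMNS, str(path))
    out = df[GENE_COUNT_COLUMNS].copy()
    out["count"] = out["count"].astype(float)
    out["length"] = out["length"].astype(int)
    return out


def write_gene_counts(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, columns=GENE_COUNT_COLUMNS)


def write_graphml(
    edges: Iterable[CorrelationEdge],
    path: str,
    member_counts: Optional[Mapping[tuple[str, str], int]] = None,
) -> None:
    """Write a bipartite precursor/protease graph for Cytoscape import.

    Node attribute ``size`` is the genus-level member count of the group
    (when provided); edge attribute ``weight`` is Spearman's rho, so that
    downstream styling can map node size to group abundance and edge width to
    correlation strength.
    """
    from .corrnet import assemble_network

    graph = assemble_network(list(edges), member_counts=member_counts)
    nx.write_graphml(graph, str(path))


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
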