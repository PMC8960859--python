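"""Orchestration: the five-stage analysis over files, plus the run manifest.

``run_all`` executes mine → cluster → network → coexpress → intersect on a
directory of input tables (optionally generating them first with the
synthetic-dataset builder), writing every intermediate table under the output
directory and finally a ``manifest.json`` that records the configuration, the
seed, per-stage row counts and the package version.  Given identical inputs
and configuration the run is deterministic down to the bytes of every output
file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import __version__, io
from .coexpress import (
    coexpression_edges,
    combine_strains,
    group_tpm,
    intersect_evidence,
    tpm_matrix,
    trim_to_network,
)
from .corrnet import (
    build_count_matrix,
    correlate_genus,
    filter_edges,
    genus_partition,
    volcano_table,
)
from .dataset import simulate_dataset
from .grouping import cluster_members, filter_groups, name_groups
from .mining import (
    DEFAULT_KEYWORDS,
    build_pfam_pool,
    flag_unclustered_bgcs,
    select_bgc_proteases,
    select_genome_proteases,
)
from .synth import SimConfig


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the offender."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs, outputs and thresholds of one pipeline run.

    Threshold defaults are the reference operating point of the workflow: protease/precursor
    identity cutoffs 0.45/0.6 with group-size minima 100/10, correlation
    filters rho > 0.3, pAdj < 1e-5, I >= 10 (pooled BH family), co-expression
    filters rho > 0.4, pAdj < 0.05 with per-strain adjustment combined across
    all strains, protease keywords and the Pfam-pool rule (score > 0, >= 5
    occurrences), and the 10-kb clustered-protease window.
    """

    outdir: str = "results/run"
    seed: int = 0
    # inputs; filled automatically when `simulate` is set
    annotations: Optional[str] = None
    domain_hits: Optional[str] = None
    precursor_fasta: Optional[str] = None
    protease_fasta: Optional[str] = None
    transcriptomes: list[str] = field(default_factory=list)
    simulate: Optional[SimConfig] = None
    # mining
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    min_score: float = 0.0
    min_occurrences: int = 5
    window: int = 10_000
    pool_allow: Optional[list[str]] = None
    pool_deny: Optional[list[str]] = None
    # grouping
    min_identity_protease: float = 0.45
    min_identity_precursor: float = 0.6
    min_size_protease: int = 100
    min_size_precursor: int = 10
    # correlation network
    rho_min: float = 0.3
    padj_max: float = 1e-5
    min_i: int = 10
    bh_scope: str = "pooled"
    # co-expression
    coexpr_rho_min: float = 0.4
    coexpr_padj_max: float = 0.05
    combine: str = "all"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["keywords"] = list(self.keywords)
        return data


def _write_pool(pool, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pfam_acc\toccurrences\n")
        for acc in sorted(pool.accessions):
            fh.write(f"{acc}\t{pool.provenance.get(acc, 0)}\n")


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dictionary.

    Any stage failure raises :class:`StageError` naming the stage.  The run is
    idempotent: identical inputs and configuration produce byte-identical
    outputs including the manifest.
    """
    out = io.ensure_dir(config.outdir)
    stages: dict[str, dict] = {}

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        paths = simulate_dataset(sim_cfg, os.path.join(out, "inputs"))
        config.annotations = paths.annotations
        config.domain_hits = paths.domain_hits
        config.precursor_fasta = paths.precursor_fasta
        config.protease_fasta = paths.protease_fasta
        config.transcriptomes = list(paths.transcriptomes)
        stages["simulate"] = {"transcriptome_strains": len(paths.transcriptomes)}

    for name, path in (
        ("annotations", config.annotations),
        ("domain_hits", config.domain_hits),
        ("precursor_fasta", config.precursor_fasta),
        ("protease_fasta", config.protease_fasta),
    ):
        if path is None or not os.path.exists(path):
            raise StageError("inputs", f"required input {name!r} is missing ({path})")

    # ------------------------------------------------------------------ mine
    try:
        genomes, features, bgcs = io.read_annotation_table(config.annotations)
        hits = io.read_domain_hits(config.domain_hits)
        bgc_proteases = select_bgc_proteases(features, config.keywords)
        bgc_ids = {f.protein_id for f in bgc_proteases}
        pool = build_pfam_pool(
            [h for h in hits if h.protein_id in bgc_ids],
            min_score=config.min_score,
            min_occurrences=config.min_occurrences,
            allow=config.pool_allow,
            deny=config.pool_deny,
        )
        selected = select_genome_proteases(hits, pool, min_score=config.min_score)
        flags = flag_unclustered_bgcs(bgcs, features, selected, window=config.window)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("mine", str(exc)) from exc
    _write_pool(pool, os.path.join(out, "pfam_pool.tsv"))
    with open(os.path.join(out, "selected_proteases.tsv"), "w", encoding="utf-8") as fh:
        fh.write("protein_id\n")
        for pid in sorted(selected):
            fh.write(pid + "\n")
    with open(os.path.join(out, "bgc_clustered_protease.tsv"), "w", encoding="utf-8") as fh:
        fh.write("bgc_id\thas_clustered_protease\n")
        for bgc_id in sorted(flags):
            fh.write(f"{bgc_id}\t{str(flags[bgc_id]).lower()}\n")
    stages["mine"] = {
        "bgc_proteases": len(bgc_proteases),
        "pool_size": len(pool),
        "selected_proteases": len(selected),
        "bgcs_without_clustered_protease": sum(1 for v in flags.values() if not v),
    }

    # --------------------------------------------------------------- cluster
    try:
        pre_seqs = io.read_fasta(config.precursor_fasta)
        prot_seqs = io.read_fasta(config.protease_fasta)
        prot_seqs = {k: v for k, v in prot_seqs.items() if k in selected}
        pre_groups = filter_groups(
            cluster_members(pre_seqs, config.min_identity_precursor),
            config.min_size_precursor,
        )
        prot_groups = filter_groups(
            cluster_members(prot_seqs, config.min_identity_protease),
            config.min_size_protease,
        )
        assignments = name_groups(pre_groups, "precursor") + name_groups(
            prot_groups, "protease"
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("cluster", str(exc)) from exc
    io.write_assignments(assignments, os.path.join(out, "assignments.tsv"))
    stages["cluster"] = {
        "precursor_groups": len(pre_groups),
        "protease_groups": len(prot_groups),
        "assigned_members": len(assignments),
    }

    # --------------------------------------------------------------- network
    try:
        member_to_genome = {f.protein_id: f.genome_id for f in features}
        pre_counts = build_count_matrix(
            [a for a in assignments if a.group_kind == "precursor"],
            member_to_genome,
            genomes,
        )
        prot_counts = build_count_matrix(
            [a for a in assignments if a.group_kind == "protease"],
            member_to_genome,
            genomes,
        )
        partition = genus_partition(genomes)
        edges = correlate_genus(pre_counts, prot_counts, partition, bh_scope=config.bh_scope)
        kept = filter_edges(edges, config.rho_min, config.padj_max, config.min_i)
        member_counts: dict[tuple[str, str], int] = {}
        genus_of = {g.genome_id: g.genus for g in genomes}
        for mat in (pre_counts, prot_counts):
            by_genus = mat.groupby([genus_of[g] for g in mat.index]).sum()
            for genus in by_genus.index:
                for group in by_genus.columns:
                    member_counts[(genus, group)] = int(by_genus.loc[genus, group])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("network", str(exc)) from exc
    io.write_count_matrix(pre_counts, os.path.join(out, "precursor_counts.tsv"))
    io.write_count_matrix(prot_counts, os.path.join(out, "protease_counts.tsv"))
    io.write_edge_table(edges, os.path.join(out, "edges.tsv"))
    io.write_edge_table(kept, os.path.join(out, "filtered_edges.tsv"))
    io.write_graphml(kept, os.path.join(out, "network.graphml"), member_counts)
    volcano_table(edges).to_csv(os.path.join(out, "volcano.tsv"), sep="\t", index=False)
    stages["network"] = {"tested_pairs": len(edges), "significant_edges": len(kept)}

    # ------------------------------------------------------------- coexpress
    candidates = []
    if config.transcriptomes:
        try:
            per_strain = []
            for path in config.transcriptomes:
                counts = io.read_gene_counts(path)
                expr = tpm_matrix(counts)
                grouped = group_tpm(expr, assignments)
                trimmed = trim_to_network(grouped, kept)
                per_strain.append(
                    coexpression_edges(
                        trimmed, config.coexpr_rho_min, config.coexpr_padj_max
                    )
                )
            combined = combine_strains(per_strain, mode=config.combine)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("coexpress", str(exc)) from exc
        io.write_coexpression_edges(combined, os.path.join(out, "coexpression_edges.tsv"))
        stages["coexpress"] = {
            "strains": len(per_strain),
            "combined_edges": len(combined),
        }

        # ------------------------------------------------------- intersect
        try:
            candidates = intersect_evidence(kept, combined)
        except Exception as exc:
            raise StageError("intersect", str(exc)) from exc
        rows = [
            {
                "pre_group": c.pre_group,
                "prot_group": c.prot_group,
                "genus": c.genomic.genus,
                "rho_genomic": c.genomic.rho,
                "p_adj_genomic": c.genomic.p_adj,
                "I": c.genomic.I,
                "rho_coexpr": c.coexpression.rho,
                "p_adj_coexpr": c.coexpression.p_adj,
            }
            for c in candidates
        ]
        pd.DataFrame(
            rows,
            columns=[
                "pre_group", "prot_group", "genus", "rho_genomic", "p_adj_genomic",
                "I", "rho_coexpr", "p_adj_coexpr",
            ],
        ).to_csv(os.path.join(out, "candidates.tsv"), sep="\t", index=False)
        stages["intersect"] = {"candidates": len(candidates)}

    config_dict = config.to_dict()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "stages": stages,
    }
    with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def demo_config(outdir: str, seed: int = 0) -> RunConfig:
    """A desk-scale end-to-end configuration over a generated dataset.

    Three genera of 40 genomes, two planted precursor units (each with one
    co-expressed protease partner and one genomic-only decoy), four background
    groups per side, and three transcriptome strains of 20 samples.  Group-size
    minima are lowered to 10/10 — the default 100-member protease cutoff is
    meaningless at a few hundred genomes — and the genome-support filter stays
    at the default I >= 10.
    """
    sim = SimConfig(
        n_genera=3,
        genomes_per_genus=40,
        n_planted_pairs=2,
        n_coexpressed_partners=1,
        n_decoy_partners=1,
        n_background_pre=4,
        n_background_prot=4,
        effect=0.9,
        n_samples=20,
        n_strains=3,
        seed=seed,
    )
    return RunConfig(
        outdir=outdir,
        seed=seed,
        simulate=sim,
        min_size_protease=10,
        min_size_precursor=10,
    )
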