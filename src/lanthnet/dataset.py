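"""Materialize a complete synthetic input dataset on disk.

:func:`simulate_dataset` turns the in-memory generators into the files the
pipeline front-end consumes: an annotation TSV (genomes, proteins, BGCs with
synthetase anchors), a Pfam domain-hit TSV, precursor and protease FASTA
files whose sequence families coincide with the planted groups, per-strain
transcriptome count tables, and truth tables for scoring.  Running the full
pipeline on such a dataset therefore exercises mining, clustering, network
construction and co-expression refinement end to end against a known answer.

Layout conventions (one contig ``c1`` per genome): the BGC synthetase anchor
sits at 10,000–10,999; precursor genes precede it inside the BGC; the first
protease gene of a genome is placed inside the BGC window (11,500) with a
keyword-bearing product unless its BGC was planted protease-free, in which
case every protease gene moves beyond the 10-kb window (>= 40,000).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io
from .synth import SimConfig, make_family_sequences, simulate_genomic, simulate_transcriptome
from .types import BgcRecord, DomainHit, ProteinFeature

#: Pfam accessions used for planted protease domain hits (pool candidates).
POOL_ACCESSIONS = ["PF00082", "PF05193", "PF01435", "PF13365", "PF00326", "PF10118"]
NOISE_NEGATIVE_ACC = "PF90000"  # always hit with score <= 0
NOISE_RARE_ACC = "PF91111"  # hit fewer than min_occurrences times
DISTRACTOR_ACC = "PF92222"  # only on non-protease distractor proteins

PRECURSOR_LENGTH = 30


@dataclass
class DatasetPaths:
    root: str
    annotations: str
    domain_hits: str
    precursor_fasta: str
    protease_fasta: str
    transcriptomes: list[str]
    truth_pairs: str
    truth_families: str
    truth_bgc_free: str


def simulate_dataset(cfg: SimConfig, outdir: str) -> DatasetPaths:
    """Write a full synthetic input set under ``outdir`` and return its paths."""
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xDA7A]))
    genomic = simulate_genomic(cfg)

    members_by_genome: dict[str, dict[str, list[str]]] = {}
    for a in genomic.assignments:
        genome = genomic.member_to_genome[a.member_id]
        members_by_genome.setdefault(genome, {}).setdefault(a.group_kind, []).append(
            a.member_id
        )
    kind_of = {a.member_id: a.group_kind for a in genomic.assignments}
    group_of = {a.member_id: a.group_id for a in genomic.assignments}

    features: list[ProteinFeature] = []
    bgcs: list[BgcRecord] = []
    genomes_with_bgc: list[str] = []
    for g in genomic.genomes:
        if members_by_genome.get(g.genome_id, {}).get("precursor"):
            genomes_with_bgc.append(g.genome_id)

    # Plant protease-free BGCs: exactly round(frac * n_bgc) of them, choosing
    # genomes that do have protease genes (forced-free genomes without any
    # protease gene count first).
    n_bgc = len(genomes_with_bgc)
    k_target = int(round(cfg.frac_bgc_without_protease * n_bgc))
    forced = [
        gid for gid in genomes_with_bgc if not members_by_genome[gid].get("protease")
    ]
    if len(forced) > k_target:
        raise ValueError(
            f"{len(forced)} BGC genomes lack protease genes entirely; cannot plant "
            f"a protease-free fraction of {cfg.frac_bgc_without_protease}"
        )
    eligible = sorted(set(genomes_with_bgc) - set(forced))
    extra = rng.permutation(len(eligible))[: k_target - len(forced)]
    protease_free = set(forced) | {eligible[i] for i in sorted(extra)}

    bgc_protease_ids: list[str] = []
    for g in genomic.genomes:
        gid = g.genome_id
        groups = members_by_genome.get(gid, {})
        pre_members = sorted(groups.get("precursor", []))
        prot_members = sorted(groups.get("protease", []))
        has_bgc = bool(pre_members)
        bgc_id = f"BGC|{gid}" if has_bgc else None

        if has_bgc:
            anchor_id = f"{gid}|lanKC"
            features.append(
                ProteinFeature(
                    anchor_id, gid, "c1", 10_000, 10_999, "+",
                    product="class III lanthipeptide synthetase LanKC", bgc_id=bgc_id,
                )
            )
            for i, member in enumerate(pre_members):
                start = 8_000 + i * 150
                features.append(
                    ProteinFeature(
                        member, gid, "c1", start, start + 119, "+",
                        product="lanthipeptide precursor peptide", bgc_id=bgc_id,
                    )
                )
            bgcs.append(
                BgcRecord(
                    bgc_id, gid, "c1", 6_900, 12_500, lan_class="III",
                    anchor_start=10_000, anchor_end=10_999,
                )
            )

        # Every genome carries a non-protease marker gene so that protein-less
        # genomes still appear in the annotation table (inside the BGC when one
        # exists, to exercise the keyword rule on non-protease BGC members).
        features.append(
            ProteinFeature(
                f"{gid}|perm", gid, "c1", 7_000, 7_800, "-",
                product="ABC transporter permease", bgc_id=bgc_id,
            )
        )

        far_members = prot_members
        if has_bgc and prot_members and gid not in protease_free:
            clustered = prot_members[0]
            features.append(
                ProteinFeature(
                    clustered, gid, "c1", 11_500, 12_400, "+",
                    product="zinc metallopeptidase", bgc_id=bgc_id,
                )
            )
            bgc_protease_ids.append(clustered)
            far_members = prot_members[1:]
        for i, member in enumerate(far_members):
            start = 40_000 + i * 1_500
            features.append(
                ProteinFeature(
                    member, gid, "c1", start, start + 899, "+",
                    product="putative peptidase", bgc_id=None,
                )
            )

    # Domain hits: every protease member gets one pool-accession hit with a
    # positive score; accessions rotate separately over BGC proteases (so the
    # pool rule "score > 0, >= 5 occurrences" recovers each used accession)
    # and over the remaining proteases.
    min_occ = 5
    if len(bgc_protease_ids) < min_occ:
        raise ValueError(
            f"only {len(bgc_protease_ids)} clustered BGC proteases; the Pfam pool "
            f"needs at least {min_occ} to plant one accession"
        )
    n_accs = max(1, min(len(POOL_ACCESSIONS), len(bgc_protease_ids) // min_occ))
    used_accs = POOL_ACCESSIONS[:n_accs]
    hits: list[DomainHit] = []
    bgc_sorted = sorted(bgc_protease_ids)
    other_prots = sorted(
        m for m, k in kind_of.items() if k == "protease" and m not in set(bgc_sorted)
    )
    for i, member in enumerate(bgc_sorted):
        hits.append(DomainHit(member, used_accs[i % n_accs], float(rng.uniform(5, 60))))
        hits.append(DomainHit(member, NOISE_NEGATIVE_ACC, float(-rng.uniform(0.5, 5))))
    for i, member in enumerate(bgc_sorted[: min_occ - 1]):
        hits.append(DomainHit(member, NOISE_RARE_ACC, float(rng.uniform(5, 20))))
    for i, member in enumerate(other_prots):
        hits.append(DomainHit(member, used_accs[i % n_accs], float(rng.uniform(5, 60))))
    for g in genomic.genomes:
        hits.append(
            DomainHit(f"{g.genome_id}|perm", DISTRACTOR_ACC, float(rng.uniform(5, 20)))
        )

    # Sequences: one point-mutation family per planted/background group.
    pre_families: dict[str, list[str]] = {}
    prot_families: dict[str, list[str]] = {}
    for a in genomic.assignments:
        target = pre_families if a.group_kind == "precursor" else prot_families
        target.setdefault(a.group_id, []).append(a.member_id)
    pre_seqs = make_family_sequences(
        {k: sorted(v) for k, v in sorted(pre_families.items())},
        PRECURSOR_LENGTH, cfg.seq_mutation_rate, rng, verify_members=False,
    )
    prot_seqs = make_family_sequences(
        {k: sorted(v) for k, v in sorted(prot_families.items())},
        cfg.seq_length, cfg.seq_mutation_rate, rng, verify_members=False,
    )

    transcriptome = simulate_transcriptome(cfg, genomic)

    paths = DatasetPaths(
        root=outdir,
        annotations=os.path.join(outdir, "annotations.tsv"),
        domain_hits=os.path.join(outdir, "domain_hits.tsv"),
        precursor_fasta=os.path.join(outdir, "precursors.fasta"),
        protease_fasta=os.path.join(outdir, "proteases.fasta"),
        transcriptomes=[],
        truth_pairs=os.path.join(outdir, "truth_pairs.tsv"),
        truth_families=os.path.join(outdir, "truth_families.tsv"),
        truth_bgc_free=os.path.join(outdir, "truth_bgc_protease_free.tsv"),
    )
    io.write_annotation_table(genomic.genomes, features, bgcs, paths.annotations)
    io.write_domain_hits(hits, paths.domain_hits)
    io.write_fasta(pre_seqs, paths.precursor_fasta)
    io.write_fasta(prot_seqs, paths.protease_fasta)
    for strain in sorted(transcriptome.strain_tables):
        p = os.path.join(outdir, f"transcriptome_{strain}.tsv")
        io.write_gene_counts(transcriptome.strain_tables[strain], p)
        paths.transcriptomes.append(p)
    genomic.truth.to_csv(paths.truth_pairs, sep="\t", index=False)
    pd.DataFrame(
        [(m, group_of[m], kind_of[m]) for m in sorted(group_of)],
        columns=["member_id", "group_id", "group_kind"],
    ).to_csv(paths.truth_families, sep="\t", index=False)
    pd.DataFrame(
        [(f"BGC|{gid}", gid in protease_free) for gid in sorted(genomes_with_bgc)],
        columns=["bgc_id", "planted_protease_free"],
    ).to_csv(paths.truth_bgc_free, sep="\t", index=False)
    return paths
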