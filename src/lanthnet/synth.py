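"""Synthetic data emulating the statistical structure of the analysis.

Three generators make every pipeline stage testable at desk scale without any
download:

* :func:`simulate_genomic` — genus-structured genome collections with sparse,
  zero-inflated group-occurrence counts; planted precursor-protease pairs
  whose per-genome counts are rank-dependent with tunable strength; and
  independent background groups.  The planted dependence duplicates the
  precursor's count vector in exactly ``round(effect * n)`` genomes of the
  genus (the rest stay independent), so the population Spearman correlation is
  0 at effect 0, monotone in effect, equal to the effect to within Monte-Carlo
  error, and exactly 1 at effect 1.  Fixing the duplicated-genome *count*
  (rather than tossing a per-genome coin) removes the binomial component of
  the sampling noise — a variance-controlled design for recovery experiments.
* :func:`simulate_sequences` — point-mutated families around random consensus
  sequences, with within-family identity >= 0.8 enforced by construction and
  cross-family identity <= 0.3 verified post hoc.
* :func:`simulate_transcriptome` — per-strain gene-level count tables where
  the genes of a co-expressed planted pair share a per-sample latent
  expression factor, while decoy partners (genomically planted, co-expression
  off) and background groups get independent expression.

Every generator is a pure function of :class:`SimConfig` including its seed;
truth tables suffice to score precision/recall of every downstream stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grouping import pairwise_identity
from .types import GenomeRecord, GroupAssignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic world.

    The genomic defaults describe a modest genus-structured collection: 20
    genera of 50 genomes, 50 independent background groups on each side, and
    zero-inflated Poisson occurrence counts (mean 1, 30% structural zeros)
    matching the sparse, non-normal distribution of gene-family counts that
    motivates a rank statistic.  One planted precursor unit per genus carries
    the dependence signal; ``effect`` is the planted dependence strength
    (equal to the population Spearman rho to within Monte-Carlo error, see
    :func:`calibrate_effect`).
    """

    n_genera: int = 20
    genomes_per_genus: int = 50
    n_planted_pairs: int = 20
    n_coexpressed_partners: int = 1
    n_decoy_partners: int = 0
    n_background_pre: int = 50
    n_background_prot: int = 50
    effect: float = 0.7
    background_rate: float = 1.0
    zero_inflation: float = 0.3
    # transcriptome
    n_samples: int = 20
    n_strains: int = 3
    coexpr_strength: float = 1.5
    expr_noise: float = 0.5
    n_housekeeping_genes: int = 200
    # sequence families
    seq_families: int = 3
    seq_members_per_family: int = 12
    seq_length: int = 60
    seq_mutation_rate: float = 0.05
    # annotation layout
    frac_bgc_without_protease: float = 1 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        for name in (
            "n_genera",
            "genomes_per_genus",
            "n_planted_pairs",
            "n_coexpressed_partners",
            "n_decoy_partners",
            "n_background_pre",
            "n_background_prot",
            "n_samples",
            "n_strains",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_planted_pairs > 0 and self.n_genera == 0:
            raise ValueError("planted pairs require at least one genus")
        if self.seq_length < 20:
            raise ValueError("per-family consensus length must be >= 20")


@dataclass
class GenomicSimulation:
    """Output of :func:`simulate_genomic`."""

    genomes: list[GenomeRecord]
    assignments: list[GroupAssignment]
    member_to_genome: dict[str, str]
    truth: pd.DataFrame  # columns: genus, pre_group, prot_group, coexpressed
    pre_counts: pd.DataFrame
    prot_counts: pd.DataFrame

    @property
    def genus_partition(self) -> dict[str, list[str]]:
        part: dict[str, list[str]] = {}
        for g in self.genomes:
            part.setdefault(g.genus, []).append(g.genome_id)
        return {k: sorted(v) for k, v in sorted(part.items())}


def _zip_counts(rng: np.random.Generator, n: int, rate: float, zero_inflation: float) -> np.ndarray:
    counts = rng.poisson(rate, n)
    counts[rng.random(n) < zero_inflation] = 0
    return counts


def simulate_genomic(cfg: SimConfig) -> GenomicSimulation:
    """Generate genomes, group assignments and the planted-pair truth table.

    Planted unit ``u`` lives in genus ``u mod n_genera`` and consists of one
    precursor group plus ``n_coexpressed_partners + n_decoy_partners``
    protease partner groups, each sharing the precursor's count vector in
    exactly ``round(effect * genomes_per_genus)`` genomes.  Background groups
    are independent zero-inflated Poisson counts across all genomes.  The
    truth table marks which partners also carry the co-expression signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x67]))
    genera = [f"Genus{g + 1:02d}" for g in range(cfg.n_genera)]
    genome_ids: list[str] = []
    genomes: list[GenomeRecord] = []
    for genus in genera:
        for k in range(cfg.genomes_per_genus):
            gid = f"{genus}_g{k + 1:03d}"
            genome_ids.append(gid)
            genomes.append(GenomeRecord(gid, genus, organism=f"{genus} sp. {k + 1}"))
    n_total = len(genome_ids)
    genus_rows = {
        genus: slice(i * cfg.genomes_per_genus, (i + 1) * cfg.genomes_per_genus)
        for i, genus in enumerate(genera)
    }

    partners_per_unit = cfg.n_coexpressed_partners + cfg.n_decoy_partners
    pre_cols: dict[str, np.ndarray] = {}
    prot_cols: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []

    prot_index = itertools.count(1)
    n_dup = int(round(cfg.effect * cfg.genomes_per_genus))
    for u in range(cfg.n_planted_pairs):
        genus = genera[u % cfg.n_genera]
        rows = genus_rows[genus]
        pre_label = f"Pre_{u + 1}"
        pre_counts = np.zeros(n_total, dtype=int)
        pre_counts[rows] = _zip_counts(
            rng, cfg.genomes_per_genus, cfg.background_rate, cfg.zero_inflation
        )
        pre_cols[pre_label] = pre_counts
        for k in range(partners_per_unit):
            prot_label = f"Prot_{next(prot_index)}"
            partner = np.zeros(n_total, dtype=int)
            own = _zip_counts(
                rng, cfg.genomes_per_genus, cfg.background_rate, cfg.zero_inflation
            )
            dup_idx = rng.permutation(cfg.genomes_per_genus)[:n_dup]
            own[dup_idx] = pre_counts[rows][dup_idx]
            partner[rows] = own
            prot_cols[prot_label] = partner
            truth_rows.append(
                {
                    "genus": genus,
                    "pre_group": pre_label,
                    "prot_group": prot_label,
                    "coexpressed": k < cfg.n_coexpressed_partners,
                }
            )

    for b in range(cfg.n_background_pre):
        label = f"Pre_{cfg.n_planted_pairs + b + 1}"
        pre_cols[label] = _zip_counts(rng, n_total, cfg.background_rate, cfg.zero_inflation)
    n_planted_prot = cfg.n_planted_pairs * partners_per_unit
    for b in range(cfg.n_background_prot):
        label = f"Prot_{n_planted_prot + b + 1}"
        prot_cols[label] = _zip_counts(rng, n_total, cfg.background_rate, cfg.zero_inflation)

    index = pd.Index(genome_ids, name="genome_id")
    pre_mat = pd.DataFrame(pre_cols, index=index).sort_index(axis=1)
    prot_mat = pd.DataFrame(prot_cols, index=index).sort_index(axis=1)

    assignments: list[GroupAssignment] = []
    member_to_genome: dict[str, str] = {}
    for kind, mat in (("precursor", pre_mat), ("protease", prot_mat)):
        values = mat.to_numpy()
        for j, group in enumerate(mat.columns):
            for i in np.nonzero(values[:, j])[0]:
                genome = genome_ids[i]
                for c in range(values[i, j]):
                    member = f"{genome}|{group}|{c + 1}"
                    assignments.append(GroupAssignment(member, group, kind))
                    member_to_genome[member] = genome

    truth = pd.DataFrame(
        truth_rows, columns=["genus", "pre_group", "prot_group", "coexpressed"]
    )
    return GenomicSimulation(
        genomes=genomes,
        assignments=assignments,
        member_to_genome=member_to_genome,
        truth=truth,
        pre_counts=pre_mat,
        prot_counts=prot_mat,
    )


def empirical_effect_rho(
    effect: float,
    rate: float = 1.0,
    zero_inflation: float = 0.3,
    n: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the population Spearman rho at a given effect."""
    from .corrnet import spearman_rho

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
    pre = _zip_counts(rng, n, rate, zero_inflation)
    prot = _zip_counts(rng, n, rate, zero_inflation)
    k = int(round(effect * n))
    idx = rng.permutation(n)[:k]
    prot[idx] = pre[idx]
    return spearman_rho(pre, prot)


def calibrate_effect(
    target_rho: float,
    rate: float = 1.0,
    zero_inflation: float = 0.3,
    n: int = 200_000,
    seed: int = 0,
    tol: float = 0.005,
) -> float:
    """Find the effect whose population Spearman rho matches ``target_rho``.

    Bisection over the monotone effect → rho map, resolved empirically rather
    than through a claimed closed form.  For the duplication construction the
    map is near-identity, so this converges in a few iterations.
    """
    if not 0.0 <= target_rho <= 1.0:
        raise ValueError("target_rho must lie in [0, 1]")
    lo, hi = 0.0, 1.0
    for _ in range(20):
        mid = (lo + hi) / 2.0
        rho = empirical_effect_rho(mid, rate, zero_inflation, n, seed)
        if abs(rho - target_rho) <= tol:
            return mid
        if rho < target_rho:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass
class SequenceSimulation:
    """Output of :func:`simulate_sequences`."""

    precursors: dict[str, str]
    proteases: dict[str, str]
    families: dict[str, str]  # member id -> planted family label


def _mutate(
    consensus: str, rng: np.random.Generator, rate: float, max_fraction: float = 0.1
) -> str:
    """Point-mutated copy with at most ``max_fraction`` of positions changed.

    The cap guarantees any two family members share identity >= 1 - 2 *
    max_fraction even in the gap-free alignment, so the within-family bound
    holds by construction.
    """
    length = len(consensus)
    cap = int(np.floor(max_fraction * length))
    for _ in range(100):
        mask = rng.random(length) < rate
        if mask.sum() <= cap:
            break
    out = list(consensus)
    for pos in np.nonzero(mask)[0]:
        choices = AMINO_ACIDS.replace(out[pos], "")
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_family_sequences(
    families: dict[str, Sequence[str]],
    length: int,
    mutation_rate: float,
    rng: np.random.Generator,
    cross_max: float = 0.3,
    verify_members: bool = True,
) -> dict[str, str]:
    """Generate one mutated-consensus family per entry of ``families``.

    ``families`` maps a family label to its member ids.  Consensi are drawn
    randomly and redrawn (up to 200 attempts) until all consensus pairs fall
    at or below ``cross_max`` identity; member pairs across families are then
    verified post hoc when the total member count is small enough to afford
    the all-vs-all check, and a violation is an error (the identity
    constraints are unsatisfiable at the requested sizes).
    """
    consensi: dict[str, str] = {}
    for label in families:
        for attempt in range(200):
            candidate = "".join(
                AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)
            )
            if all(pairwise_identity(candidate, c) <= cross_max for c in consensi.values()):
                consensi[label] = candidate
                break
        else:
            raise ValueError(
                f"could not draw a consensus for family {label!r} with cross-family "
                f"identity <= {cross_max}"
            )
    sequences: dict[str, str] = {}
    for label, members in families.items():
        for member in members:
            sequences[member] = _mutate(consensi[label], rng, mutation_rate)

    total = sum(len(m) for m in families.values())
    if verify_members and total <= 400:
        labels = list(families)
        for a_label, b_label in itertools.combinations(labels, 2):
            for ma in families[a_label]:
                for mb in families[b_label]:
                    ident = pairwise_identity(sequences[ma], sequences[mb])
                    if ident > cross_max + 2 * 0.1:
                        raise ValueError(
                            f"cross-family identity {ident:.2f} between {ma!r} and "
                            f"{mb!r} exceeds the construction bound"
                        )
    return sequences


def simulate_sequences(cfg: SimConfig) -> SequenceSimulation:
    """Planted sequence families for the clustering stage.

    Generates ``seq_families`` precursor families and ``seq_families`` protease
    families of ``seq_members_per_family`` members each; member ids encode
    nothing about the family — the returned ``families`` map is the truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E9]))
    pre_families = {
        f"prefam{k + 1}": [f"preseq_{k + 1}_{i + 1}" for i in range(cfg.seq_members_per_family)]
        for k in range(cfg.seq_families)
    }
    prot_families = {
        f"protfam{k + 1}": [f"protseq_{k + 1}_{i + 1}" for i in range(cfg.seq_members_per_family)]
        for k in range(cfg.seq_families)
    }
    precursors = make_family_sequences(
        pre_families, max(20, cfg.seq_length // 2), cfg.seq_mutation_rate, rng
    )
    proteases = make_family_sequences(
        prot_families, cfg.seq_length, cfg.seq_mutation_rate, rng
    )
    families = {
        member: label
        for fam in (pre_families, prot_families)
        for label, members in fam.items()
        for member in members
    }
    return SequenceSimulation(precursors=precursors, proteases=proteases, families=families)


@dataclass
class TranscriptomeSimulation:
    """Output of :func:`simulate_transcriptome`."""

    strain_tables: dict[str, pd.DataFrame]  # strain genome id -> long count table
    gene_lengths: dict[str, int]


def simulate_transcriptome(
    cfg: SimConfig,
    genomic: GenomicSimulation,
    strains: Optional[Sequence[str]] = None,
) -> TranscriptomeSimulation:
    """Per-strain gene-level count tables with planted co-expression.

    Strains are genomes of the first planted unit's genus in which both the
    precursor group and every co-expressed partner group have at least one
    member (the strain "expresses" the precursor); genes are the member
    proteins of that genome.  For each sample, genes of a co-expressed planted
    pair share a latent log-expression factor of strength ``coexpr_strength``;
    decoy partners and background groups get independent expression.  Counts
    are Poisson around length-scaled expected expression, so TPM recovers the
    latent structure.
    """
    if cfg.n_samples < 3:
        raise ValueError("need n_samples >= 3")
    if genomic.truth.empty:
        raise ValueError("transcriptome simulation requires at least one planted unit")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7BA]))

    focal = genomic.truth.iloc[0]
    focal_genus = focal["genus"]
    unit_groups = genomic.truth[genomic.truth["genus"] == focal_genus]
    required = {focal["pre_group"]} | set(
        unit_groups.loc[unit_groups["coexpressed"], "prot_group"]
    )

    if strains is None:
        candidates = []
        for gid in genomic.genus_partition[focal_genus]:
            pre_ok = genomic.pre_counts.loc[gid, focal["pre_group"]] > 0
            prot_ok = all(
                genomic.prot_counts.loc[gid, g] > 0
                for g in required
                if g in genomic.prot_counts.columns
            )
            if pre_ok and prot_ok:
                candidates.append(gid)
        if len(candidates) < cfg.n_strains:
            raise ValueError(
                f"only {len(candidates)} genomes express the focal planted unit; "
                f"{cfg.n_strains} strains requested"
            )
        strains = candidates[: cfg.n_strains]

    # Unit membership of each group: genes of the precursor group and of its
    # co-expressed partners follow that unit's latent factor.
    unit_of_pre = {g: i for i, g in enumerate(dict.fromkeys(genomic.truth["pre_group"]))}
    group_unit: dict[str, int] = dict(unit_of_pre)
    for _, row in genomic.truth.iterrows():
        if row["coexpressed"]:
            group_unit[row["prot_group"]] = unit_of_pre[row["pre_group"]]

    genes_by_genome: dict[str, list[tuple[str, str]]] = {}
    for a in genomic.assignments:
        genome = genomic.member_to_genome[a.member_id]
        genes_by_genome.setdefault(genome, []).append((a.member_id, a.group_id))

    gene_lengths: dict[str, int] = {}
    strain_tables: dict[str, pd.DataFrame] = {}
    n_units = len(genomic.truth["pre_group"].unique())
    for strain in strains:
        genes = sorted(genes_by_genome.get(strain, []))
        if not genes:
            raise ValueError(f"strain {strain!r} has no member genes")
        # Housekeeping genes dominate the library so that TPM's compositional
        # coupling between member groups stays negligible.
        genes = genes + [
            (f"{strain}|hk{i + 1:03d}", None) for i in range(cfg.n_housekeeping_genes)
        ]
        base = rng.uniform(3.5, 7.0, len(genes))
        lengths = rng.integers(300, 3001, len(genes))
        for (gene, _), length in zip(genes, lengths):
            gene_lengths[gene] = int(length)
        latent = rng.normal(0.0, 1.0, (cfg.n_samples, max(n_units, 1)))
        depth = rng.normal(0.0, 0.3, cfg.n_samples)
        rows = []
        for s in range(cfg.n_samples):
            sample_id = f"{strain}|s{s + 1:02d}"
            noise = rng.normal(0.0, cfg.expr_noise, len(genes))
            for j, (gene, group) in enumerate(genes):
                log_mu = base[j] + noise[j] + depth[s]
                unit = group_unit.get(group)
                if unit is not None:
                    log_mu += cfg.coexpr_strength * latent[s, unit]
                mean = np.exp(log_mu) * gene_lengths[gene] / 1000.0
                rows.append(
                    {
                        "sample_id": sample_id,
                        "gene_id": gene,
                        "count": float(rng.poisson(mean)),
                        "length": gene_lengths[gene],
                    }
                )
        strain_tables[strain] = pd.DataFrame(
            rows, columns=["sample_id", "gene_id", "count", "length"]
        )
    return TranscriptomeSimulation(strain_tables=strain_tables, gene_lengths=gene_lengths)
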