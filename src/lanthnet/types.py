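"""Domain types shared by every pipeline stage.

The pipeline links groups of lanthipeptide precursor peptides to groups of
candidate maturation proteases.  Records here mirror the tabular inputs:
genome annotation rows (one protein per row, with optional biosynthetic gene
cluster membership), Pfam domain-hit rows in the shape of hmmsearch tabular
output, member-to-group assignments produced by sequence clustering, and the
per-test correlation results.

Coordinates are 1-based inclusive throughout (GFF convention).  Count and
expression matrices are plain :class:`pandas.DataFrame` objects — genomes (or
samples) as the index, group (or gene) labels as columns — rather than bespoke
containers; the functions that produce them document the orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

LAN_CLASSES = frozenset({"I", "II", "III", "IV", "unknown"})

#: Group-kind → label prefix used by :func:`lanthnet.grouping.name_groups`.
GROUP_PREFIX = {"precursor": "Pre", "protease": "Prot"}


@dataclass(frozen=True)
class GenomeRecord:
    """One genome in the collection.

    ``genus`` is the stratification variable: every correlation test is run
    within a single genus to blunt phylogenetic confounding.
    """

    genome_id: str
    genus: str
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValueError(f"genome {self.genome_id!r}: genus must be non-empty")


@dataclass(frozen=True)
class ProteinFeature:
    """One annotated protein-coding gene.

    ``bgc_id`` is set when the gene lies inside a detected lanthipeptide
    biosynthetic gene cluster; ``sequence`` is optional until a stage needs it.
    """

    protein_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    bgc_id: Optional[str] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"protein {self.protein_id!r}: coordinates must be positive")
        if self.start > self.end:
            raise ValueError(
                f"protein {self.protein_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"protein {self.protein_id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class BgcRecord:
    """One lanthipeptide biosynthetic gene cluster.

    ``anchor_start``/``anchor_end`` hold the coordinates of the LanC-like /
    synthetase anchor gene; the clustered-protease check scans a window up-
    and downstream of this anchor.
    """

    bgc_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    lan_class: str = "unknown"
    anchor_start: Optional[int] = None
    anchor_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"BGC {self.bgc_id!r}: start {self.start} > end {self.end}")
        if self.lan_class not in LAN_CLASSES:
            raise ValueError(
                f"BGC {self.bgc_id!r}: lan_class {self.lan_class!r} not in {sorted(LAN_CLASSES)}"
            )
        if (self.anchor_start is None) != (self.anchor_end is None):
            raise ValueError(f"BGC {self.bgc_id!r}: anchor coordinates must be set together")


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain hit on a protein (hmmsearch tabular row shape).

    The bit score may be any real number; filtering (score > 0) happens
    downstream, never at parse time.
    """

    protein_id: str
    pfam_acc: str
    score: float


@dataclass(frozen=True)
class GroupAssignment:
    """Membership of one sequence in one group.

    ``group_id`` follows the ``Pre_<k>`` / ``Prot_<k>`` labelling, with ``k``
    ranked by descending group size.
    """

    member_id: str
    group_id: str
    group_kind: str  # "precursor" | "protease"

    def __post_init__(self) -> None:
        if self.group_kind not in GROUP_PREFIX:
            raise ValueError(f"unknown group_kind {self.group_kind!r}")
        prefix = GROUP_PREFIX[self.group_kind]
        if not self.group_id.startswith(prefix + "_"):
            raise ValueError(
                f"group label {self.group_id!r} does not match kind {self.group_kind!r}"
            )


@dataclass(frozen=True)
class CorrelationEdge:
    """One precursor-group × protease-group test within one genus.

    ``rho`` is Spearman's rank correlation over the per-genome occurrence
    counts of the two groups across all ``n`` genomes of the genus (NaN when
    either count vector is constant — the test is then undefined and the edge
    is excluded from the multiple-testing family and from all filters).
    ``I`` counts the genomes of the genus containing at least one member of
    both groups.
    """

    genus: str
    pre_group: str
    prot_group: str
    rho: float
    p: float
    p_adj: float
    I: int
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)

    @property
    def key(self) -> tuple[str, str]:
        return (self.pre_group, self.prot_group)


@dataclass(frozen=True)
class CoexpressionEdge:
    """One precursor-group × protease-group co-expression test across samples."""

    pre_group: str
    prot_group: str
    rho: float
    p: float
    p_adj: float
    n_samples: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.pre_group, self.prot_group)


@dataclass(frozen=True)
class CandidateEdge:
    """A pair supported by both genomic correlation and co-expression."""

    pre_group: str
    prot_group: str
    genomic: CorrelationEdge
    coexpression: CoexpressionEdge

    @property
    def key(self) -> tuple[str, str]:
        return (self.pre_group, self.prot_group)


@dataclass(frozen=True)
class PfamPool:
    """Pool of Pfam accessions considered diagnostic of lanthipeptide proteases.

    ``provenance`` maps each accession to its qualifying-hit count among
    BGC-associated proteases; every retained accession met the occurrence
    threshold used to build the pool.
    """

    accessions: frozenset[str]
    provenance: dict[str, int] = field(default_factory=dict)

    def __contains__(self, acc: str) -> bool:
        return acc in self.accessions

    def __len__(self) -> int:
        return len(self.accessions)
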