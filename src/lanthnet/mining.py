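"""Protease mining: keyword selection, Pfam pool, genome-wide harvest.

The mining logic follows the staged widening of the search space: proteases
inside lanthipeptide biosynthetic gene clusters are first picked by annotation
keywords, their Pfam domains are pooled (keeping accessions with a positive
bit score seen at least ``min_occurrences`` times across BGC proteases), and
the pool is then used to harvest candidate proteases genome-wide — clustered
or not.  A per-BGC window check flags clusters that lack any protease gene
within a fixed distance of the synthetase anchor, the situation that motivates
looking for "hidden" proteases elsewhere in the genome.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional, Sequence

from .types import BgcRecord, DomainHit, PfamPool, ProteinFeature

#: Annotation keywords marking a protein as a candidate protease.
DEFAULT_KEYWORDS = ("peptidase", "proteinase", "protease", "hydrolase", "beta-lactamase")

#: Half-width (nt) of the clustered-protease window around the BGC anchor gene.
DEFAULT_WINDOW = 10_000

DEFAULT_MIN_SCORE = 0.0
DEFAULT_MIN_OCCURRENCES = 5


def select_bgc_proteases(
    features: Iterable[ProteinFeature],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> list[ProteinFeature]:
    """Select BGC-associated proteins whose product annotation matches a keyword.

    Matching is a case-insensitive substring test on the product field; only
    features with ``bgc_id`` set are considered.  An empty keyword list is an
    error (it would silently select nothing).
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    return [
        f
        for f in features
        if f.bgc_id is not None and any(k in f.product.lower() for k in lowered)
    ]


def build_pfam_pool(
    hits: Iterable[DomainHit],
    min_score: float = DEFAULT_MIN_SCORE,
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    allow: Optional[Iterable[str]] = None,
    deny: Optional[Iterable[str]] = None,
) -> PfamPool:
    """Build the protease Pfam-domain pool from BGC-protease domain hits.

    An accession enters the pool iff its number of hits with score strictly
    above ``min_score`` is at least ``min_occurrences``.  The manual-curation
    step often applied to such domain pools is modelled as an optional
    ``allow``/``deny`` accession list; no curation heuristic is invented.
    """
    counts: Counter[str] = Counter()
    for h in hits:
        if h.score > min_score:
            counts[h.pfam_acc] += 1
    kept = {acc: c for acc, c in counts.items() if c >= min_occurrences}
    if allow is not None:
        allowed = set(allow)
        kept = {acc: c for acc, c in kept.items() if acc in allowed}
    if deny is not None:
        denied = set(deny)
        kept = {acc: c for acc, c in kept.items() if acc not in denied}
    return PfamPool(accessions=frozenset(kept), provenance=dict(sorted(kept.items())))


def select_genome_proteases(
    all_hits: Iterable[DomainHit],
    pool: PfamPool,
    min_score: float = DEFAULT_MIN_SCORE,
) -> set[str]:
    """Harvest candidate proteases genome-wide.

    A protein is selected iff it carries at least one hit to a pool accession
    with score strictly above ``min_score``, regardless of BGC membership.
    """
    return {
        h.protein_id for h in all_hits if h.pfam_acc in pool and h.score > min_score
    }


def bgc_has_clustered_protease(
    bgc: BgcRecord,
    proteases: Iterable[ProteinFeature],
    window: int = DEFAULT_WINDOW,
) -> bool:
    """True iff any selected protease lies within ``window`` nt of the BGC anchor.

    The scanned interval is ``[anchor_start - window, anchor_end + window]``
    (closed); a protease overlaps if its own closed interval intersects it and
    it sits on the same genome and contig.  BGCs without anchor coordinates
    cannot be evaluated and raise.
    """
    if bgc.anchor_start is None or bgc.anchor_end is None:
        raise ValueError(f"BGC {bgc.bgc_id!r}: anchor coordinates are required")
    lo = bgc.anchor_start - window
    hi = bgc.anchor_end + window
    for f in proteases:
        if f.genome_id != bgc.genome_id or f.contig != bgc.contig:
            continue
        if f.start <= hi and f.end >= lo:
            return True
    return False


def flag_unclustered_bgcs(
    bgcs: Iterable[BgcRecord],
    features: Iterable[ProteinFeature],
    selected_protein_ids: set[str],
    window: int = DEFAULT_WINDOW,
) -> dict[str, bool]:
    """Map bgc_id → whether a selected protease is clustered within the window."""
    selected = [f for f in features if f.protein_id in selected_protein_ids]
    by_genome: dict[str, list[ProteinFeature]] = {}
    for f in selected:
        by_genome.setdefault(f.genome_id, []).append(f)
    return {
        b.bgc_id: bgc_has_clustered_protease(b, by_genome.get(b.genome_id, ()), window)
        for b in bgcs
    }
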