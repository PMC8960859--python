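#!/usr/bin/env python
"""Refine the genomic network with transcriptomic co-expression.

Per strain: gene counts -> TPM -> group-summed TPM, trimmed to the groups in
the genomic network; Spearman co-expression edges (rho > 0.4, pAdj < 0.05,
per-strain BH) are intersected across all strains and then with the genomic
edges.  The planted co-expressed partner should survive; the genomic-only
decoy partner should not.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from common import DATA_DIR, RESULTS_DIR  # noqa: E402

import pandas as pd  # noqa: E402

from lanthnet import io  # noqa: E402
from lanthnet.coexpress import (  # noqa: E402
    coexpression_edges,
    combine_strains,
    group_tpm,
    intersect_evidence,
    tpm_matrix,
    trim_to_network,
)


def main() -> None:
    assignments = io.read_assignments(RESULTS_DIR / "assignments.tsv")
    kept = io.read_edge_table(RESULTS_DIR / "filtered_edges.tsv")

    per_strain = []
    for path in sorted(DATA_DIR.glob("transcriptome_*.tsv")):
        expr = tpm_matrix(io.read_gene_counts(path))
        trimmed = trim_to_network(group_tpm(expr, assignments), kept)
        edges = coexpression_edges(trimmed)
        per_strain.append(edges)
        print(f"{path.name}: {len(edges)} co-expression edges (rho>0.4, pAdj<0.05)")

    combined = combine_strains(per_strain, mode="all")
    io.write_coexpression_edges(combined, RESULTS_DIR / "coexpression_edges.tsv")
    candidates = intersect_evidence(kept, combined)
    pd.DataFrame(
        [
            {
                "pre_group": c.pre_group,
                "prot_group": c.prot_group,
                "rho_genomic": round(c.genomic.rho, 3),
                "p_adj_genomic": c.genomic.p_adj,
                "I": c.genomic.I,
                "rho_coexpr": round(c.coexpression.rho, 3),
                "p_adj_coexpr": c.coexpression.p_adj,
            }
            for c in candidates
        ]
    ).to_csv(RESULTS_DIR / "candidates.tsv", sep="\t", index=False)

    genomic_partners = {(e.pre_group, e.prot_group) for e in kept}
    print(f"edges recurring in all {len(per_strain)} strains: {len(combined)}")
    print(
        f"intersection of genomic ({len(genomic_partners)} pairs) and co-expression "
        f"evidence -> {len(candidates)} candidate(s):"
    )
    for c in candidates:
        print(
            f"  {c.pre_group} -- {c.prot_group} "
            f"(genomic rho={c.genomic.rho:.2f}, co-expression rho={c.coexpression.rho:.2f})"
        )


if __name__ == "__main__":
    main()
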