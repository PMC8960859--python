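#!/usr/bin/env python
"""Build the per-genus Spearman correlation network over occurrence counts.

Counts every group's occurrences per genome, tests all precursor x protease
group pairs within each genus (one-sided t p-values, pooled BH adjustment),
and prioritizes edges with rho > 0.3, pAdj < 1e-5, I >= 10.  The kept edges
are checked against the planted precursor-protease pairs, and the volcano
table plus a Cytoscape-ready GraphML file are written.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from common import DATA_DIR, RESULTS_DIR  # noqa: E402

import pandas as pd  # noqa: E402

from lanthnet import io  # noqa: E402
from lanthnet.corrnet import (  # noqa: E402
    build_count_matrix,
    correlate_genus,
    filter_edges,
    genus_partition,
    volcano_table,
)


def main() -> None:
    genomes, features, _ = io.read_annotation_table(DATA_DIR / "annotations.tsv")
    assignments = io.read_assignments(RESULTS_DIR / "assignments.tsv")
    member_to_genome = {f.protein_id: f.genome_id for f in features}

    pre_counts = build_count_matrix(
        [a for a in assignments if a.group_kind == "precursor"], member_to_genome, genomes
    )
    prot_counts = build_count_matrix(
        [a for a in assignments if a.group_kind == "protease"], member_to_genome, genomes
    )
    edges = correlate_genus(pre_counts, prot_counts, genus_partition(genomes))
    kept = filter_edges(edges)

    io.write_count_matrix(pre_counts, RESULTS_DIR / "precursor_counts.tsv")
    io.write_count_matrix(prot_counts, RESULTS_DIR / "protease_counts.tsv")
    io.write_edge_table(edges, RESULTS_DIR / "edges.tsv")
    io.write_edge_table(kept, RESULTS_DIR / "filtered_edges.tsv")
    io.write_graphml(kept, RESULTS_DIR / "network.graphml")
    volcano_table(edges).to_csv(RESULTS_DIR / "volcano.tsv", sep="\t", index=False)

    print(f"{len(edges)} genus-level pairs tested; {len(kept)} pass rho>0.3, pAdj<1e-5, I>=10:")
    for e in kept:
        print(
            f"  {e.genus}: {e.pre_group} -- {e.prot_group} "
            f"(rho={e.rho:.2f}, pAdj={e.p_adj:.2e}, I={e.I}, n={e.n})"
        )
    n_planted = len(pd.read_csv(DATA_DIR / "truth_pairs.tsv", sep="\t"))
    print(f"planted precursor-protease pairs: {n_planted}")


if __name__ == "__main__":
    main()
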