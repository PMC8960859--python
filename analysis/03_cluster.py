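#!/usr/bin/env python
"""Group precursors and proteases by identity-threshold connected components.

Precursors cluster at identity >= 0.6 and proteases (restricted to the mined
candidates) at >= 0.45; groups with fewer than 10 members are dropped and the
survivors are labelled Pre_k / Prot_k by descending size.  The recovered
partition is compared against the planted families (adjusted Rand index).
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from common import DATA_DIR, RESULTS_DIR  # noqa: E402

import pandas as pd  # noqa: E402
from sklearn.metrics import adjusted_rand_score  # noqa: E402

from lanthnet import io  # noqa: E402
from lanthnet.grouping import cluster_members, filter_groups, name_groups  # noqa: E402

MIN_SIZE = 10  # the default 100-member protease cutoff presumes >1e5 genomes


def main() -> None:
    selected = set(
        pd.read_csv(RESULTS_DIR / "selected_proteases.tsv", sep="\t").protein_id
    )
    pre_seqs = io.read_fasta(DATA_DIR / "precursors.fasta")
    prot_seqs = {
        k: v for k, v in io.read_fasta(DATA_DIR / "proteases.fasta").items() if k in selected
    }

    assignments = []
    truth = pd.read_csv(DATA_DIR / "truth_families.tsv", sep="\t")
    planted = dict(zip(truth.member_id, truth.group_id))
    for kind, seqs, threshold in (
        ("precursor", pre_seqs, 0.6),
        ("protease", prot_seqs, 0.45),
    ):
        groups = filter_groups(cluster_members(seqs, threshold), MIN_SIZE)
        named = name_groups(groups, kind)
        assignments.extend(named)
        clustered = {a.member_id: a.group_id for a in named}
        members = sorted(clustered)
        ari = adjusted_rand_score(
            [planted[m] for m in members], [clustered[m] for m in members]
        )
        print(
            f"{kind}: {len(seqs)} sequences -> {len(groups)} groups at identity "
            f">= {threshold} (ARI vs planted families: {ari:.3f})"
        )

    io.write_assignments(assignments, RESULTS_DIR / "assignments.tsv")
    print(f"wrote {len(assignments)} member assignments to results/assignments.tsv")


if __name__ == "__main__":
    main()
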