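#!/usr/bin/env python
"""Generate the synthetic study dataset used by the downstream analyses.

Three genera of 40 genomes; two planted precursor units, each with one
co-expressed protease partner and one genomic-only decoy partner (dependence
strength 0.9); four independent background groups per side; one third of the
BGCs planted without a clustered protease; three transcriptome strains of 20
samples each.  Inputs and truth tables land under results/data/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from common import DATA_DIR, RESULTS_DIR, demo_sim_config  # noqa: E402

from lanthnet.dataset import simulate_dataset  # noqa: E402


def main() -> None:
    cfg = demo_sim_config()
    paths = simulate_dataset(cfg, str(DATA_DIR))
    print(f"wrote synthetic dataset under {paths.root}")
    print(f"  annotations:   {paths.annotations}")
    print(f"  domain hits:   {paths.domain_hits}")
    print(f"  sequences:     {paths.precursor_fasta}, {paths.protease_fasta}")
    print(f"  transcriptomes ({len(paths.transcriptomes)} strains):")
    for p in paths.transcriptomes:
        print(f"    {p}")
    print(f"  truth tables:  {paths.truth_pairs}, {paths.truth_families}, {paths.truth_bgc_free}")


if __name__ == "__main__":
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    main()
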