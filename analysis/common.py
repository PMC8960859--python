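"""Shared paths and the study configuration for the analysis scripts."""

import pathlib

from lanthnet.synth import SimConfig

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS_DIR = ROOT / "results"
DATA_DIR = RESULTS_DIR / "data"

SEED = 0


def demo_sim_config(seed: int = SEED) -> SimConfig:
    """Desk-scale study conditions shared by every analysis script."""
    return SimConfig(
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
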