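import numpy as np
import pytest

from lanthnet.synth import SimConfig, simulate_genomic
from lanthnet.types import BgcRecord, DomainHit, GenomeRecord, ProteinFeature


@pytest.fixture
def toy_annotation_tsv(tmp_path):
    """3 proteins over 2 genomes, one BGC with an anchor gene."""
    header = (
        "genome_id\tgenus\torganism\tprotein_id\tcontig\tstart\tend\tstrand\t"
        "product\tbgc_id\tbgc_start\tbgc_end\tlan_class\tanchor_start\tanchor_end"
    )
    rows = [
        "g1\tStreptomyces\tStreptomyces sp. 1\tp1\tc1\t100\t400\t+\t"
        "lanthipeptide precursor peptide\tB1\t50\t5000\tIII\t1000\t2000",
        "g1\tStreptomyces\tStreptomyces sp. 1\tp2\tc1\t1000\t2000\t+\t"
        "class III lanthipeptide synthetase\tB1\t50\t5000\tIII\t1000\t2000",
        "g2\tPaenibacillus\t.\tp3\tc2\t10\t900\t-\tzinc metallopeptidase\t.\t.\t.\t.\t.\t.",
    ]
    path = tmp_path / "annotations.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


@pytest.fixture
def small_genomic_sim():
    """Two planted units with one decoy each, strong effect, small background."""
    cfg = SimConfig(
        n_genera=3,
        genomes_per_genus=40,
        n_planted_pairs=2,
        n_coexpressed_partners=1,
        n_decoy_partners=1,
        n_background_pre=4,
        n_background_prot=4,
        effect=0.9,
        seed=42,
    )
    return cfg, simulate_genomic(cfg)


@pytest.fixture
def window_bgc():
    return BgcRecord(
        "B1", "g1", "c1", 9_000, 13_000, lan_class="III",
        anchor_start=10_000, anchor_end=12_000,
    )


def make_protein(pid, start, end, genome="g1", contig="c1", product="peptidase", bgc=None):
    return ProteinFeature(pid, genome, contig, start, end, "+", product=product, bgc_id=bgc)


@pytest.fixture(name="make_protein")
def make_protein_fixture():
    return make_protein
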