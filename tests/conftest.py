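import numpy as np
import pytest

from cerealqtl.io import AlignmentHit
from cerealqtl.simulate import (
    GenomeSpec,
    MirnaPlanting,
    SimulationConfig,
    StructuralEvent,
    simulate_locus_set,
)


def make_hit(qid="q", sid="chr1", pident=95.0, aln_len=100, mismatches=5,
             gap_opens=0, qstart=1, qend=100, sstart=1000, send=1099,
             evalue=1e-30, bitscore=180.0, qlen=100, slen=100000) -> AlignmentHit:
    return AlignmentHit(qid, sid, pident, aln_len, mismatches, gap_opens,
                        qstart, qend, sstart, send, evalue, bitscore, qlen, slen)


def small_config(seed: int, **overrides) -> SimulationConfig:
    """A compact locus set: fast enough for per-test simulation while
    keeping the multi-genome structure (wheat pair + barley + rice)."""
    defaults = dict(
        seed=seed,
        genomes=[
            GenomeSpec("svevo", "wheat", 0.0),
            GenomeSpec("zavitan", "wheat", 0.01),
            GenomeSpec("barley", "barley_rye", 0.05),
            GenomeSpec("rice", "rice", 0.12),
        ],
        genes_per_locus=8,
        gene_length=(400, 900),
        intergenic_length=(400, 900),
        n_markers=8,
        marker_length=(90, 140),
        flank_length=800,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """One compact simulated locus set shared across read-only tests."""
    cfg = small_config(
        seed=11,
        structural_events=[StructuralEvent("barley", "inversion", 2, 5)],
        mirna_plantings=[
            MirnaPlanting("miR9101"),
            MirnaPlanting("miR9102", "duplex"),
        ],
    )
    return simulate_locus_set(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
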