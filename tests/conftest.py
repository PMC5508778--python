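import numpy as np
import pytest

from hicscaffold import Contig, ContigSet, PairedAlignment, SimConfig, simulate_all


def make_pair(
    contig1,
    pos1,
    contig2=None,
    pos2=None,
    read_len=10,
    mapq=60,
    read_id="p",
    end1=None,
    end2=None,
):
    """Compact PairedAlignment constructor for tests."""
    contig2 = contig2 if contig2 is not None else contig1
    pos2 = pos2 if pos2 is not None else pos1
    return PairedAlignment(
        read_id=read_id,
        contig1=contig1,
        pos1=pos1,
        end1=end1 if end1 is not None else pos1 + read_len,
        strand1="+",
        mapq1=mapq,
        contig2=contig2,
        pos2=pos2,
        end2=end2 if end2 is not None else pos2 + read_len,
        strand2="-",
        mapq2=mapq,
    )


@pytest.fixture
def toy_contigs():
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def seq(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()

    return ContigSet(
        [
            Contig("c1", 1000, seq(1000)),
            Contig("c2", 800, seq(800)),
            Contig("c3", 600, seq(600)),
            Contig("c4", 400, seq(400)),
        ]
    )


# A small, fast simulation shared by several test modules: two 500-kb
# chromosomes cut into ~14 contigs, 40k pairs.
SMALL_SIM = SimConfig(
    n_chromosomes=2,
    chromosome_length=500_000,
    contig_length_min=30_000,
    contig_length_max=90_000,
    intra_decay_scale=8_000.0,
    p_inter=0.05,
    n_pairs=40_000,
    read_length=100,
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_all(SMALL_SIM)
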