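import numpy as np
import pytest

from fragbias.fraglen import truncated_gaussian
from fragbias.simulate import (
    SimulationConfig,
    generate_transcriptome,
    simulate_fragments,
)
from fragbias.transcriptome import Transcript, group_loci


def make_transcript(seq: str, tid: str = "T1", chrom: str = "chr1",
                    strand: str = "+") -> Transcript:
    return Transcript(id=tid, chrom=chrom, strand=strand,
                      exons=[(0, len(seq))], sequence=seq)


def random_transcript(rng, length: int, tid: str = "T1") -> Transcript:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return make_transcript(seq, tid=tid, chrom=f"c_{tid}")


@pytest.fixture(scope="session")
def small_sim():
    """A modest planted-bias simulation shared by several tests."""
    cfg = SimulationConfig(n_transcripts=20, n_fragments=30_000, seed=7,
                           seq_bias_strength=0.5)
    transcripts, chromosomes = generate_transcriptome(cfg)
    sim = simulate_fragments(transcripts, cfg)
    loci = group_loci(transcripts)
    return transcripts, chromosomes, loci, sim


@pytest.fixture
def short_fld():
    """A narrow fragment-length distribution for tiny test transcripts."""
    return truncated_gaussian(mean=30, sd=8, min_len=15, max_len=60)
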