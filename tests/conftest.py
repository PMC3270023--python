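import numpy as np
import pytest

from circkit.align import ReadPair
from circkit.genome_model import GeneModel, GenomicInterval

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def pairs_from_sim(sim):
    return [ReadPair(r.read_id, r.mate1, r.mate2) for r in sim.read_pairs]


@pytest.fixture
def rng():
    return np.random.default_rng(20120201)


@pytest.fixture
def toy_gene():
    """Plus-strand gene with 4 exons of lengths 100, 120, 80, 150."""
    lengths = [100, 120, 80, 150]
    exons = []
    pos = 50
    for ln in lengths:
        exons.append(GenomicInterval("chrT", pos, pos + ln, "+"))
        pos += ln + 300
    return GeneModel(gene_id="toy", exons=exons)


@pytest.fixture
def toy_chromosome(toy_gene, rng):
    end = toy_gene.exons[-1].end + 50
    return {"chrT": random_seq(rng, end)}
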