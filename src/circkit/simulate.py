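"""Seeded simulator of genes, isoform pools, and paired-end reads.

The generator emulates the study conditions of a random-primed, paired-end
library built from fragmented total RNA:

* multi-exon genes with random sequence, one per synthetic chromosome;
* per gene, a mixture of a canonical linear isoform, optionally a circular
  isoform (exons Y..X joined by a backsplice) at molecule fraction phi,
  and optionally a tandem-duplicated isoform (exons Y..X duplicated in
  canonical order) at fraction tau;
* fragmentation with a trapezoidal insert-length distribution: uniform
  core 300-500 bp with linear tails of width 100 bp on both sides — a
  concrete reading of inserts of roughly 300-500 bp with ~100 bp tails;
* 80-bp paired-end reads with i.i.d. substitution errors;
* poly-adenylation status (circular isoforms never carry poly-A) and a
  leaky poly-A selection step that retains poly-A+ fragments with
  probability ``polya_retention`` and leaks poly-A- fragments into the
  selected fraction with probability ``polya_leakage``.

Everything is driven by one integer seed and is reproducible bit for bit.
An off-by-default template-switch mode replaces a configurable fraction of
fragments with boundary-random intra-transcript chimeras, to exercise the
1/len^2 boundary-coincidence argument empirically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GeneModel, GenomicInterval, reverse_complement, write_bed12

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (4, 8)
    exon_length_range: tuple[int, int] = (100, 250)
    intron_length_range: tuple[int, int] = (200, 800)
    circular_fraction: float = 0.5  # phi: molecule fraction of the circular isoform
    tandem_fraction: float = 0.0  # tau: molecule fraction of the tandem-dup isoform
    coverage: float = 30.0
    read_length: int = 80
    insert_core: tuple[int, int] = (300, 500)
    insert_tail: int = 100
    error_rate: float = 0.001
    polya_retention: float = 0.95  # s+: P(polyA+ fragment enters selected fraction)
    polya_leakage: float = 0.05  # s-: P(polyA- fragment enters selected fraction)
    acceptor_bias_exon2: float = 0.0  # P(force acceptor Y = 2) for enrichment fixtures
    circle_span_range: tuple[int, int] | None = None  # exons per circle/tandem block; None: uniform up to gene end
    template_switch_rate: float = 0.0
    flank: int = 50  # chromosome padding around each gene

    def __post_init__(self) -> None:
        phi, tau = self.circular_fraction, self.tandem_fraction
        if not (0 <= phi <= 1 and 0 <= tau <= 1 and phi + tau <= 1):
            raise ConfigError("require 0 <= phi, tau and phi + tau <= 1")
        for rate in (self.error_rate, self.polya_retention, self.polya_leakage,
                     self.acceptor_bias_exon2, self.template_switch_rate):
            if not 0 <= rate <= 1:
                raise ConfigError("rates must be in [0, 1]")
        if self.exon_count_range[0] < 1 or self.exon_count_range[0] > self.exon_count_range[1]:
            raise ConfigError("infeasible exon count range")
        if self.exon_length_range[0] < 1 or self.exon_length_range[0] > self.exon_length_range[1]:
            raise ConfigError("infeasible exon length range")
        if self.insert_core[0] > self.insert_core[1] or self.insert_tail < 0:
            raise ConfigError("infeasible insert model")
        if self.insert_core[0] - self.insert_tail < self.read_length:
            raise ConfigError("insert model admits fragments shorter than a read")


@dataclass
class Isoform:
    isoform_id: str
    gene_id: str
    structure: str  # linear | circular | tandem_dup | template_switch
    donor_index: int | None
    acceptor_index: int | None
    abundance: float
    polyadenylated: bool
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimReadPair:
    read_id: str
    mate1: str
    mate2: str
    gene_id: str
    isoform_id: str
    structure: str
    frag_start: int
    frag_len: int
    crosses_backsplice: bool
    polyadenylated: bool


@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    chromosomes: dict[str, str]
    isoforms: list[Isoform]
    read_pairs: list[SimReadPair] = field(default_factory=list)

    @property
    def isoform_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "isoform_id": i.isoform_id,
                    "gene_id": i.gene_id,
                    "structure": i.structure,
                    "donor_exon": i.donor_index,
                    "acceptor_exon": i.acceptor_index,
                    "abundance": i.abundance,
                    "polyadenylated": i.polyadenylated,
                    "length": i.length,
                }
                for i in self.isoforms
            ]
        )

    @property
    def read_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": r.read_id,
                    "gene_id": r.gene_id,
                    "isoform_id": r.isoform_id,
                    "structure": r.structure,
                    "frag_start": r.frag_start,
                    "frag_len": r.frag_len,
                    "crosses_backsplice": r.crosses_backsplice,
                    "polyadenylated": r.polyadenylated,
                }
                for r in self.read_pairs
            ]
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _choose_span(
    rng: np.random.Generator,
    k: int,
    bias_exon2: float,
    span_range: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """(donor X, acceptor Y) with Y drawn from eligible acceptors 2..k.

    ``span_range`` bounds the number of exons Y..X in the block; by
    default the donor is uniform over Y..k.
    """
    if k < 2:
        raise ConfigError("spans require at least 2 exons")
    if bias_exon2 > 0 and rng.random() < bias_exon2:
        y = 2
    else:
        y = int(rng.integers(2, k + 1))
    if span_range is None:
        x = int(rng.integers(y, k + 1))
    else:
        lo, hi = span_range
        hi = min(hi, k - y + 1)
        if hi < lo:
            hi = lo
        span = int(rng.integers(lo, hi + 1))
        x = min(y + span - 1, k)
    return x, y


def simulate_transcriptome(config: SimConfig) -> SimResult:
    """Generate gene models, chromosome sequences, and the isoform pool."""
    rng = np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    chroms: dict[str, str] = {}
    isoforms: list[Isoform] = []
    phi, tau = config.circular_fraction, config.tandem_fraction

    for gi in range(config.n_genes):
        gene_id = f"gene{gi:04d}"
        chrom = f"chr_{gene_id}"
        k = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        exon_lens = rng.integers(
            config.exon_length_range[0], config.exon_length_range[1] + 1, size=k
        )
        intron_lens = rng.integers(
            config.intron_length_range[0], config.intron_length_range[1] + 1, size=max(k - 1, 0)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        pos = config.flank
        genomic_exons = []
        for i in range(k):
            genomic_exons.append(
                GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand)
            )
            pos += int(exon_lens[i])
            if i < k - 1:
                pos += int(intron_lens[i])
        chrom_len = pos + config.flank
        chroms[chrom] = _random_seq(rng, chrom_len)
        exons = genomic_exons if strand == "+" else genomic_exons[::-1]
        gene = GeneModel(gene_id=gene_id, exons=exons)
        genes.append(gene)

        from .genome_model import SequenceSource, exon_sequence

        seqs = SequenceSource(chroms)
        exon_seqs = [exon_sequence(gene, i, seqs) for i in range(1, k + 1)]
        linear_seq = "".join(exon_seqs)
        linear_frac = 1.0 - phi - tau
        if linear_frac > 0:
            isoforms.append(
                Isoform(f"{gene_id}.linear", gene_id, "linear", None, None,
                        linear_frac, True, linear_seq)
            )
        if phi > 0:
            x, y = _choose_span(rng, k, config.acceptor_bias_exon2, config.circle_span_range)
            circ_seq = "".join(exon_seqs[y - 1 : x])
            isoforms.append(
                Isoform(f"{gene_id}.circ", gene_id, "circular", x, y, phi, False, circ_seq)
            )
        if tau > 0:
            x, y = _choose_span(rng, k, config.acceptor_bias_exon2, config.circle_span_range)
            tandem_seq = (
                "".join(exon_seqs[:x])
                + "".join(exon_seqs[y - 1 : x])
                + "".join(exon_seqs[x:])
            )
            isoforms.append(
                Isoform(f"{gene_id}.tandem", gene_id, "tandem_dup", x, y, tau, True, tandem_seq)
            )
    return SimResult(config=config, genes=genes, chromosomes=chroms, isoforms=isoforms)


def _trapezoid_sampler(config: SimConfig):
    lo = config.insert_core[0] - config.insert_tail
    hi = config.insert_core[1] + config.insert_tail
    scale = hi - lo
    if scale == 0:  # degenerate constant-length library
        return lambda rng: int(lo)
    c = (config.insert_core[0] - lo) / scale
    d = (config.insert_core[1] - lo) / scale
    dist = stats.trapezoid(c, d, loc=lo, scale=scale)

    def sample(rng: np.random.Generator) -> int:
        return int(round(float(dist.rvs(random_state=rng))))

    return sample


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def _make_chimera(rng: np.random.Generator, transcript: str, frag_len: int) -> tuple[str, int]:
    """Template-switch artifact: join two uniformly random breakpoints."""
    half = frag_len // 2
    p1 = int(rng.integers(half, len(transcript)))
    p2 = int(rng.integers(0, len(transcript) - (frag_len - half)))
    return transcript[p1 - half : p1] + transcript[p2 : p2 + frag_len - half], p1


def fragment_and_read(sim: SimResult, max_retries: int = 20) -> SimResult:
    """Fragment the isoform pool and emit paired reads with ground truth.

    Fragment starts are uniform on each molecule; on circular molecules
    the start is uniform on the circle, the length is truncated at the
    circle length, and the fragment wraps the backsplice.  Mates are the
    fragment's two ends (mate of the 3' end reverse-complemented); the
    sequenced strand of the fragment is random, emulating a random-primed,
    unstranded library.
    """
    config = sim.config
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    sample_insert = _trapezoid_sampler(config)
    rl = config.read_length
    by_gene: dict[str, list[Isoform]] = {}
    for iso in sim.isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)

    read_pairs: list[SimReadPair] = []
    counter = 0
    for gene in sim.genes:
        pool = by_gene.get(gene.gene_id, [])
        if not pool:
            continue
        weights = np.array([i.abundance for i in pool], dtype=float)
        weights /= weights.sum()
        n_frags = int(round(config.coverage * gene.mature_length / (2 * rl)))
        iso_idx = rng.choice(len(pool), size=n_frags, p=weights)
        for ii in iso_idx:
            iso = pool[ii]
            circular = iso.structure == "circular"
            L = iso.length
            frag = None
            for _ in range(max_retries):
                frag_len = sample_insert(rng)
                if circular:
                    frag_len = min(frag_len, L)
                if frag_len < rl or (not circular and frag_len > L):
                    continue
                if circular:
                    start = int(rng.integers(0, L))
                    frag = (iso.sequence * 2)[start : start + frag_len]
                    crosses = start + frag_len > L
                else:
                    start = int(rng.integers(0, L - frag_len + 1))
                    frag = iso.sequence[start : start + frag_len]
                    crosses = False
                break
            if frag is None:
                logger.warning(
                    "no feasible fragment for %s after %d tries; skipped",
                    iso.isoform_id, max_retries,
                )
                continue
            structure = iso.structure
            if (
                config.template_switch_rate > 0
                and structure == "linear"
                and rng.random() < config.template_switch_rate
            ):
                frag, start = _make_chimera(rng, iso.sequence, len(frag))
                structure = "template_switch"
            mate1 = frag[:rl]
            mate2 = reverse_complement(frag[-rl:])
            if rng.random() < 0.5:
                # sequencing the fragment's other strand swaps the two ends
                mate1, mate2 = mate2, mate1
            mate1 = _apply_errors(rng, mate1, config.error_rate)
            mate2 = _apply_errors(rng, mate2, config.error_rate)
            read_pairs.append(
                SimReadPair(
                    read_id=f"sim{counter:07d}",
                    mate1=mate1,
                    mate2=mate2,
                    gene_id=iso.gene_id,
                    isoform_id=iso.isoform_id,
                    structure=structure,
                    frag_start=start,
                    frag_len=len(frag),
                    crosses_backsplice=crosses,
                    polyadenylated=iso.polyadenylated,
                )
            )
            counter += 1
    sim.read_pairs = read_pairs
    return sim


def simulate(config: SimConfig) -> SimResult:
    """Full generator: transcriptome, isoform pool, and paired reads."""
    return fragment_and_read(simulate_transcriptome(config))


def polya_partition(
    sim: SimResult,
) -> tuple[list[SimReadPair], list[SimReadPair]]:
    """Split read pairs into (selected, depleted) poly-A fractions.

    Fragments from polyadenylated molecules enter the selected fraction
    with probability ``polya_retention``, otherwise flow through;
    non-polyadenylated fragments leak into the selected fraction with
    probability ``polya_leakage``.
    """
    config = sim.config
    if not config.polya_retention > config.polya_leakage:
        logger.warning("polya_retention <= polya_leakage: partition is uninformative")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    selected, depleted = [], []
    for rp in sim.read_pairs:
        p_sel = config.polya_retention if rp.polyadenylated else config.polya_leakage
        (selected if rng.random() < p_sel else depleted).append(rp)
    return selected, depleted


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_fasta(chromosomes: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in chromosomes:
            fh.write(f">{name}\n")
            seq = chromosomes[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq_pair(
    read_pairs: Sequence[SimReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as fh1, open(path2, "w") as fh2:
        for rp in read_pairs:
            fh1.write(f"@{rp.read_id}/1\n{rp.mate1}\n+\n{'I' * len(rp.mate1)}\n")
            fh2.write(f"@{rp.read_id}/2\n{rp.mate2}\n+\n{'I' * len(rp.mate2)}\n")


def write_single_fastq(read_pairs: Sequence[SimReadPair], path: str | Path) -> None:
    """Both mates of each pair as single-end reads (poly-A fraction files)."""
    with open(path, "w") as fh:
        for rp in read_pairs:
            fh.write(f"@{rp.read_id}/1\n{rp.mate1}\n+\n{'I' * len(rp.mate1)}\n")
            fh.write(f"@{rp.read_id}/2\n{rp.mate2}\n+\n{'I' * len(rp.mate2)}\n")


def write_outputs(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write BED12 + FASTA + paired FASTQ + truth TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "genes.bed12",
        "genome": outdir / "genome.fasta",
        "reads1": outdir / "reads_1.fastq",
        "reads2": outdir / "reads_2.fastq",
        "isoform_truth": outdir / "truth_isoforms.tsv",
        "read_truth": outdir / "truth_reads.tsv",
    }
    write_bed12(sim.genes, paths["annotation"])
    write_fasta(sim.chromosomes, paths["genome"])
    write_fastq_pair(sim.read_pairs, paths["reads1"], paths["reads2"])
    sim.isoform_truth.to_csv(paths["isoform_truth"], sep="\t", index=False)
    sim.read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    return paths
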