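"""Gene annotation model and exon-exon junction database construction.

A gene is represented by one ordered chain of exons (the representative
transcript) on one strand.  Exon indices are 1-based in transcription order
everywhere they are reported: for a minus-strand gene, exon 1 is the 3'-most
genomic block.  Coordinates are 0-based half-open internally.

A junction joins a donor exon X to an acceptor exon Y.  Junctions with
X >= Y ("scrambled") place a downstream donor upstream of an acceptor and
are the signature of either a circular RNA or a tandem exon duplication.
The junction database enumerates all ordered (X, Y) pairs within each gene
and records the reference sequence a read crossing the junction would have.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


class InvalidJunctionError(ValueError):
    """Raised when a donor/acceptor index pair violates its contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One representative exon chain for a gene.

    ``exons`` are in transcription order (5'->3' of the mature transcript);
    genomically they ascend for plus-strand genes and descend for minus.
    """

    gene_id: str
    exons: list[GenomicInterval]
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"gene {self.gene_id}: exons span multiple chroms/strands"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise AnnotationError(f"gene {self.gene_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if expected != self.exons:
            raise AnnotationError(
                f"gene {self.gene_id}: exons not in transcription order"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [len(e) for e in self.exons]

    @property
    def mature_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def intron_lengths(self) -> list[int]:
        """Genomic gap between consecutive exons, in transcription order.

        ``intron_lengths[i]`` is intron i+1, between exons i+1 and i+2
        (1-based).
        """
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            gap = b.start - a.end if self.strand == "+" else a.start - b.end
            out.append(gap)
        return out

    def exon_tx_span(self, index: int) -> tuple[int, int]:
        """Transcript-coordinate half-open span of 1-based exon ``index``."""
        if not 1 <= index <= self.n_exons:
            raise IndexError(f"exon {index} out of range for {self.gene_id}")
        start = sum(self.exon_lengths[: index - 1])
        return start, start + self.exon_lengths[index - 1]

    def exon_at_tx(self, pos: int) -> int:
        """1-based exon index containing transcript coordinate ``pos``."""
        if not 0 <= pos < self.mature_length:
            raise IndexError(f"position {pos} outside transcript {self.gene_id}")
        off = 0
        for i, ln in enumerate(self.exon_lengths, start=1):
            off += ln
            if pos < off:
                return i
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ExonJunction:
    """A donor->acceptor exon join with its reference junction sequence.

    ``junction_seq`` is the donor-side window followed by the acceptor-side
    window; ``breakpoint_offset`` is the length of the donor-side window,
    i.e. the position of the join within ``junction_seq``.
    """

    gene_id: str
    donor_index: int
    acceptor_index: int
    junction_seq: str
    breakpoint_offset: int

    @property
    def scrambled(self) -> bool:
        return self.donor_index >= self.acceptor_index

    @property
    def record_id(self) -> str:
        return (
            f"{self.gene_id}|{self.donor_index}|{self.acceptor_index}|"
            f"{'scrambled' if self.scrambled else 'forward'}"
        )


def parse_junction_record_id(record_id: str) -> tuple[str, int, int, bool]:
    gene_id, x, y, flag = record_id.rsplit("|", 3)
    return gene_id, int(x), int(y), flag == "scrambled"


def circle_length(gene: GeneModel, donor_index: int, acceptor_index: int) -> int:
    """Length of the hypothesized circle: exons acceptor..donor inclusive."""
    if donor_index < acceptor_index:
        raise InvalidJunctionError(
            f"donor {donor_index} < acceptor {acceptor_index}: not a scrambled junction"
        )
    if acceptor_index < 1 or donor_index > gene.n_exons:
        raise InvalidJunctionError(
            f"indices ({donor_index},{acceptor_index}) out of range for "
            f"{gene.gene_id} with {gene.n_exons} exons"
        )
    return sum(gene.exon_lengths[acceptor_index - 1 : donor_index])


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def _pick_representative(
    transcripts: Mapping[str, list[GenomicInterval]],
) -> tuple[str, list[GenomicInterval]]:
    """Most exons, ties by longest mature length, then lexicographic id."""

    def key(item: tuple[str, list[GenomicInterval]]):
        tx_id, exons = item
        return (-len(exons), -sum(len(e) for e in exons), tx_id)

    return min(transcripts.items(), key=key)


def _parse_bed12_line(line: str, lineno: int) -> tuple[str, str, list[GenomicInterval]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise AnnotationError(f"line {lineno}: expected 12 BED columns, got {len(fields)}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from exc
    if len(sizes) != block_count or len(starts) != block_count:
        raise AnnotationError(f"line {lineno}: block fields disagree with blockCount")
    exons = [
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(starts, sizes)
    ]
    if strand == "-":
        exons = exons[::-1]
    if "|" in name:
        gene_id, tx_id = name.split("|", 1)
    else:
        gene_id = tx_id = name
    return gene_id, tx_id, exons


def _load_bed12(path: Path) -> dict[str, dict[str, list[GenomicInterval]]]:
    per_gene: dict[str, dict[str, list[GenomicInterval]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            gene_id, tx_id, exons = _parse_bed12_line(line, lineno)
            per_gene.setdefault(gene_id, {})[tx_id] = exons
    return per_gene


def _load_gtf(path: Path) -> dict[str, dict[str, list[GenomicInterval]]]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict[str, list[GenomicInterval]]] = {}
    for exon in db.features_of_type("exon"):
        try:
            gene_id = exon.attributes["gene_id"][0]
            tx_id = exon.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"exon at {exon.seqid}:{exon.start} missing {exc} attribute"
            ) from exc
        iv = GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        per_gene.setdefault(gene_id, {}).setdefault(tx_id, []).append(iv)
    for transcripts in per_gene.values():
        for tx_id, exons in transcripts.items():
            exons.sort(key=lambda e: e.start)
            if exons[0].strand == "-":
                exons.reverse()
    return per_gene


def load_annotation(path: str | Path, dialect: str = "BED12") -> list[GeneModel]:
    """Load gene models, choosing one representative transcript per gene.

    ``dialect`` is ``"GTF"`` or ``"BED12"``.  Genes are returned sorted by
    gene_id.  Zero-exon genes are skipped with a warning.
    """
    path = Path(path)
    dialect = dialect.upper()
    if dialect == "BED12":
        per_gene = _load_bed12(path)
    elif dialect == "GTF":
        per_gene = _load_gtf(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    genes: list[GeneModel] = []
    for gene_id in sorted(per_gene):
        transcripts = {t: e for t, e in per_gene[gene_id].items() if e}
        if not transcripts:
            logger.warning("gene %s has no exons; skipped", gene_id)
            continue
        tx_id, exons = _pick_representative(transcripts)
        genes.append(GeneModel(gene_id=gene_id, exons=exons, transcript_id=tx_id))
    return genes


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit one BED12 line per gene (representative transcript)."""
    with open(path, "w") as fh:
        for g in genes:
            genomic = sorted(g.exons, key=lambda e: e.start)
            start = genomic[0].start
            end = genomic[-1].end
            sizes = ",".join(str(len(e)) for e in genomic)
            offsets = ",".join(str(e.start - start) for e in genomic)
            name = g.gene_id if g.transcript_id in (None, g.gene_id) else f"{g.gene_id}|{g.transcript_id}"
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(start),
                        str(end),
                        name,
                        "0",
                        g.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(genomic)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sequence extraction and junction database
# ---------------------------------------------------------------------------


class SequenceSource:
    """Uniform access to chromosome sequences from a FASTA path, a pyfaidx
    Fasta, or a plain ``{name: sequence}`` mapping."""

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta

            self._fa = Fasta(str(source))
            self._map = None
        elif isinstance(source, Mapping):
            self._fa = None
            self._map = source
        else:  # assume pyfaidx.Fasta-like
            self._fa = source
            self._map = None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self._map is not None:
            if chrom not in self._map:
                raise KeyError(chrom)
            seq = self._map[chrom][start:end]
        else:
            seq = str(self._fa[chrom][start:end])
        if len(seq) != end - start:
            raise ValueError(
                f"sequence {chrom}:{start}-{end} truncated (got {len(seq)} nt)"
            )
        return seq.upper()


def exon_sequence(gene: GeneModel, index: int, seqs: SequenceSource) -> str:
    """Sequence of 1-based exon ``index`` in transcript orientation."""
    e = gene.exons[index - 1]
    raw = seqs.fetch(e.chrom, e.start, e.end)
    return reverse_complement(raw) if gene.strand == "-" else raw


def transcript_sequence(gene: GeneModel, seqs: SequenceSource) -> str:
    return "".join(exon_sequence(gene, i, seqs) for i in range(1, gene.n_exons + 1))


def build_junction_database(
    genes: Iterable[GeneModel],
    sequences,
    read_length: int = 80,
    min_flank: int = 11,
    expressed_only: set[str] | None = None,
) -> list[ExonJunction]:
    """Enumerate all ordered within-gene exon pairs with junction sequences.

    For a gene with k exons this emits k^2 junctions, of which k(k+1)/2
    (donor >= acceptor, including self-joins) are scrambled.  The junction
    sequence is the last ``read_length - min_flank`` nt of the donor exon
    followed by the first ``read_length - min_flank`` nt of the acceptor
    exon; exons shorter than the window contribute their full length only.
    """
    if min_flank < 1:
        raise ValueError("min_flank must be >= 1")
    if read_length <= 2 * min_flank:
        raise ValueError("read_length must exceed 2*min_flank")
    window = read_length - min_flank
    seqs = sequences if isinstance(sequences, SequenceSource) else SequenceSource(sequences)

    junctions: list[ExonJunction] = []
    for gene in genes:
        if expressed_only is not None and gene.gene_id not in expressed_only:
            continue
        try:
            exon_seqs = [
                exon_sequence(gene, i, seqs) for i in range(1, gene.n_exons + 1)
            ]
        except (KeyError, ValueError) as exc:
            raise AnnotationError(
                f"sequence unavailable for gene {gene.gene_id}: {exc}"
            ) from exc
        for donor in range(1, gene.n_exons + 1):
            donor_side = exon_seqs[donor - 1][-window:]
            for acceptor in range(1, gene.n_exons + 1):
                acceptor_side = exon_seqs[acceptor - 1][:window]
                junctions.append(
                    ExonJunction(
                        gene_id=gene.gene_id,
                        donor_index=donor,
                        acceptor_index=acceptor,
                        junction_seq=donor_side + acceptor_side,
                        breakpoint_offset=len(donor_side),
                    )
                )
    return junctions


def write_junction_fasta(junctions: Iterable[ExonJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(f">{j.record_id}\n{j.junction_seq}\n")


def write_junction_manifest(
    junctions: Sequence[ExonJunction],
    genes: Iterable[GeneModel],
    path: str | Path,
    exon_base: int = 1,
) -> None:
    """TSV manifest of the junction database.

    ``exon_base`` shifts reported exon indices (some published tables number
    exons from 0); internal indices are always 1-based.
    """
    by_id = {g.gene_id: g for g in genes}
    shift = exon_base - 1
    with open(path, "w") as fh:
        fh.write("gene_id\tdonor_exon\tacceptor_exon\tscrambled\tcircle_length\tjunction_seq_length\n")
        for j in junctions:
            L = (
                circle_length(by_id[j.gene_id], j.donor_index, j.acceptor_index)
                if j.scrambled
                else ""
            )
            fh.write(
                f"{j.gene_id}\t{j.donor_index + shift}\t{j.acceptor_index + shift}\t"
                f"{int(j.scrambled)}\t{L}\t{len(j.junction_seq)}\n"
            )
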