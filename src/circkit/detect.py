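"""Per-junction evidence: mate-consistency classification and deduplication.

A junctional read supporting a scrambled X->Y join can be explained by two
structures: a circular RNA of exons Y..X, or a linear transcript with a
tandem duplication of those exons.  The two make different predictions for
the junctional read's mate: under circularity the mate must come from
inside exons Y..X; a mate unambiguously outside (upstream of Y or
downstream of X) is evidence for the linear/tandem structure.

Counting is deduplicated: read pairs with identical (junction offset, mate
offset, mismatch profiles) are counted once, so PCR duplicates do not
inflate junctional support.

``window_scan`` is the annotation-free alternative: genes are tiled in
fixed bins (default 200 bp of transcript) and read pairs are split into
orientation-consistent (category 2) and orientation-inconsistent
(category 1) classes; category-1 pairs arise from fragments crossing a
backsplice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .align import Alignment, FORWARD, REVERSE
from .genome_model import ExonJunction, GeneModel, circle_length


class PairClass(Enum):
    CIRCLE_CONSISTENT = "circle_consistent"
    LINEAR_EVIDENCE = "linear_evidence"
    AMBIGUOUS = "ambiguous"


@dataclass
class ClassifiedPair:
    """One junctional read pair, keyed by its dedup signature."""

    junction_offset: int
    junction_profile: tuple[tuple[int, str], ...]
    mate_offset: int | None
    mate_profile: tuple[tuple[int, str], ...] | None
    pair_class: PairClass

    @property
    def signature(self):
        return (
            self.junction_offset,
            self.mate_offset,
            self.junction_profile,
            self.mate_profile,
        )


@dataclass
class ScrambleEvidence:
    junction: ExonJunction
    n_distinct: int
    n_circle_consistent: int
    n_linear_evidence: int
    n_ambiguous: int

    @property
    def gene_id(self) -> str:
        return self.junction.gene_id


def classify_pair(
    junction_alignment: Alignment,
    mate_alignment: Alignment | None,
    gene: GeneModel,
    junction: ExonJunction,
    read_length: int,
    min_flank: int = 11,
) -> PairClass:
    """Classify a junctional pair under the circle vs tandem models.

    The mate must be uniquely aligned to the same gene's transcript.  If
    its full span lies inside the circle's exon block (transcript
    coordinates of exons Y..X) the pair is circle-consistent.  If the mate
    extends outside the block with at least ``min_flank`` mismatch-free
    bases beyond the boundary, the fragment cannot have come from the
    circle: linear evidence.  Anything else — unaligned, non-unique or
    other-gene mate, or an extension too short/dirty to trust — is
    ambiguous.

    The linear-evidence event "fragment extends beyond the block" is the
    event whose probability the insert-length statistic 1 - F(L)
    approximates (up to the junction alignment offset), keeping the p0
    calibration and this classifier consistent.  The mismatch-free-flank
    requirement mirrors the junctional read criterion and prevents a
    backsplice-crossing mate, whose few wrapped terminal bases get
    absorbed as reference mismatches, from masquerading as evidence for
    linearity.
    """
    if not junction.scrambled:
        raise ValueError("classify_pair requires a scrambled junction")
    if mate_alignment is None or not mate_alignment.unique:
        return PairClass.AMBIGUOUS
    if mate_alignment.target_id != gene.gene_id:
        return PairClass.AMBIGUOUS
    block_start, _ = gene.exon_tx_span(junction.acceptor_index)
    _, block_end = gene.exon_tx_span(junction.donor_index)
    m_start = mate_alignment.offset
    m_end = mate_alignment.offset + read_length
    if block_start <= m_start and m_end <= block_end:
        return PairClass.CIRCLE_CONSISTENT
    mismatch_positions = {m_start + pos for pos, _ in mate_alignment.mismatch_profile}

    def clean(lo: int, hi: int) -> int:
        return sum(1 for t in range(lo, hi) if t not in mismatch_positions)

    if m_start < block_start and clean(m_start, min(m_end, block_start)) >= min_flank:
        return PairClass.LINEAR_EVIDENCE
    if m_end > block_end and clean(max(m_start, block_end), m_end) >= min_flank:
        return PairClass.LINEAR_EVIDENCE
    return PairClass.AMBIGUOUS


def dedup_and_count(
    junction: ExonJunction, pairs: Iterable[ClassifiedPair]
) -> ScrambleEvidence:
    """Collapse duplicate pairs and tally mate classes.

    Distinctness is over (junction offset, mate offset, mismatch profiles);
    each distinct tuple contributes once to n_distinct and to the tally of
    its class.
    """
    seen: dict[tuple, PairClass] = {}
    for p in pairs:
        seen.setdefault(p.signature, p.pair_class)
    counts = {cls: 0 for cls in PairClass}
    for cls in seen.values():
        counts[cls] += 1
    return ScrambleEvidence(
        junction=junction,
        n_distinct=len(seen),
        n_circle_consistent=counts[PairClass.CIRCLE_CONSISTENT],
        n_linear_evidence=counts[PairClass.LINEAR_EVIDENCE],
        n_ambiguous=counts[PairClass.AMBIGUOUS],
    )


# ---------------------------------------------------------------------------
# Annotation-free window scan
# ---------------------------------------------------------------------------


@dataclass
class WindowPairMatrix:
    gene_id: str
    bin_size: int
    counts: dict[tuple[int, int, int], int] = field(default_factory=dict)

    def add(self, bin_a: int, bin_b: int, category: int) -> None:
        key = (bin_a, bin_b, category)
        self.counts[key] = self.counts.get(key, 0) + 1

    def category_total(self, category: int) -> int:
        return sum(v for (_, _, c), v in self.counts.items() if c == category)

    def conditional_ratios(self, bin_a: int) -> dict[tuple[int, int], float]:
        """Per (binB, category) fraction of pairs conditional on binA."""
        total = sum(v for (a, _, _), v in self.counts.items() if a == bin_a)
        if total == 0:
            return {}
        return {
            (b, c): v / total
            for (a, b, c), v in self.counts.items()
            if a == bin_a
        }


def window_scan(
    gene: GeneModel,
    pair_alignments: Iterable[tuple[Alignment, Alignment]],
    bin_size: int = 200,
) -> WindowPairMatrix:
    """Bin uniquely-mapped read pairs by transcript position and orientation.

    Category 2 is the canonical inward-facing geometry (forward-oriented
    mate 5' of the reverse-oriented mate); category 1 is the inverted
    geometry diagnostic of a fragment crossing a backsplice.  Pairs with
    both mates in the same orientation are discarded.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    matrix = WindowPairMatrix(gene_id=gene.gene_id, bin_size=bin_size)
    for a1, a2 in pair_alignments:
        if a1.target_id != gene.gene_id or a2.target_id != gene.gene_id:
            continue
        if a1.orientation == a2.orientation:
            continue
        fwd, rev = (a1, a2) if a1.orientation == FORWARD else (a2, a1)
        category = 2 if fwd.offset <= rev.offset else 1
        matrix.add(a1.offset // bin_size, a2.offset // bin_size, category)
    return matrix


def scrambled_bins(matrix: WindowPairMatrix, min_pairs: int = 2) -> list[tuple[int, int]]:
    """Bin pairs with category-1 support at or above ``min_pairs``."""
    return sorted(
        {(a, b) for (a, b, c), v in matrix.counts.items() if c == 1 and v >= min_pairs}
    )


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------


def write_evidence_tsv(
    evidence: Sequence[ScrambleEvidence],
    genes: Iterable[GeneModel],
    path: str | Path,
    exon_base: int = 1,
) -> None:
    by_id = {g.gene_id: g for g in genes}
    shift = exon_base - 1
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tdonor_exon\tacceptor_exon\tcircle_length\tn_distinct\t"
            "n_circle_consistent\tn_linear_evidence\tn_ambiguous\n"
        )
        for ev in evidence:
            j = ev.junction
            L = circle_length(by_id[j.gene_id], j.donor_index, j.acceptor_index)
            fh.write(
                f"{j.gene_id}\t{j.donor_index + shift}\t{j.acceptor_index + shift}\t{L}\t"
                f"{ev.n_distinct}\t{ev.n_circle_consistent}\t{ev.n_linear_evidence}\t"
                f"{ev.n_ambiguous}\n"
            )


def write_window_matrix_tsv(matrices: Iterable[WindowPairMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbin_a\tbin_b\tcategory\tcount\n")
        for m in matrices:
            for (a, b, c), v in sorted(m.counts.items()):
                fh.write(f"{m.gene_id}\t{a}\t{b}\t{c}\t{v}\n")
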