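"""End-to-end orchestration: junction database -> alignment -> evidence ->
abundance -> circularity statistics.

The pipeline ordering is mandatory: mates are aligned to the spliced
transcriptome first; only mates that fail there are aligned to the
junction database.  Uniquely aligned single reads define gene expression;
uniquely aligned proper pairs define the insert-length distribution;
unique junctional alignments to scrambled records, paired with their
mate's transcriptome position, become per-junction scramble evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import circ_stats, detect, quantify
from .align import Aligner, Alignment, FORWARD, ReadPair, is_junctional
from .detect import ClassifiedPair, PairClass, ScrambleEvidence, WindowPairMatrix
from .genome_model import (
    ExonJunction,
    GeneModel,
    SequenceSource,
    build_junction_database,
    parse_junction_record_id,
    transcript_sequence,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds; defaults follow the published analysis where it
    states a value (3 mismatches, 11-base mismatch-free flanks, more than
    one junctional read, 10% abundance, 200-bp bins, 80-bp reads)."""

    read_length: int = 80
    max_mismatches: int = 3
    min_flank: int = 11
    min_junctional_reads: int = 2
    min_fraction: float = 0.10
    bin_size: int = 200
    exon_base: int = 1
    offset_averaged: bool = False
    min_insert_pairs: int = 100


@dataclass
class PipelineResult:
    config: RunConfig
    genes: list[GeneModel]
    junctions: list[ExonJunction]
    expression: dict[str, int]
    insert_distribution: circ_stats.InsertLengthDistribution | None
    evidence: list[ScrambleEvidence]
    canonical_pair_counts: dict[tuple[str, int], int]
    forward_junction_counts: dict[tuple[str, int, int], int]
    estimates: list[quantify.AbundanceEstimate]
    histogram: dict[str, int]
    assessments: list[circ_stats.CircularityAssessment]
    expected_linear: tuple[float, float] | None
    window_matrices: dict[str, WindowPairMatrix]
    summary: dict = field(default_factory=dict)

    def evidence_for(self, gene_id: str, donor: int, acceptor: int) -> ScrambleEvidence | None:
        for ev in self.evidence:
            j = ev.junction
            if (j.gene_id, j.donor_index, j.acceptor_index) == (gene_id, donor, acceptor):
                return ev
        return None


def _unique_hit(hits: Sequence[Alignment] | None) -> Alignment | None:
    if not hits:
        return None
    for a in hits:
        if a.unique:
            return a
    return None


def _spans_boundary_clean(
    aln: Alignment, boundary: int, min_flank: int, read_length: int
) -> bool:
    """Read covers a transcript-coordinate exon boundary with min_flank
    mismatch-free bases on both sides (the junctional criterion applied to
    a canonical junction)."""
    start, end = aln.offset, aln.offset + read_length
    if boundary - start < min_flank or end - boundary < min_flank:
        return False
    return all(
        not (boundary - min_flank <= start + pos < boundary + min_flank)
        for pos, _ in aln.mismatch_profile
    )


def detect_scrambles(
    genes: Sequence[GeneModel],
    sequences,
    read_pairs: Iterable[ReadPair],
    config: RunConfig = RunConfig(),
    expressed_only: set[str] | None = None,
) -> PipelineResult:
    """Run the full detection pipeline on in-memory objects."""
    seqs = sequences if isinstance(sequences, SequenceSource) else SequenceSource(sequences)
    by_id = {g.gene_id: g for g in genes}
    transcripts = {g.gene_id: transcript_sequence(g, seqs) for g in genes}
    tx_aligner = Aligner(transcripts)
    rl = config.read_length

    pair_hits: list[tuple[ReadPair, list[Alignment], list[Alignment]]] = []
    for rp in read_pairs:
        h1 = tx_aligner.align_read(f"{rp.read_id}/1", rp.mate1, config.max_mismatches)
        h2 = tx_aligner.align_read(f"{rp.read_id}/2", rp.mate2, config.max_mismatches)
        pair_hits.append((rp, h1, h2))
    if not pair_hits:
        raise ValueError("no read pairs supplied")

    # --- expression, inserts, window scan, canonical junction support -----
    expression: dict[str, int] = {g.gene_id: 0 for g in genes}
    inserts: list[int] = []
    window_input: dict[str, list[tuple[Alignment, Alignment]]] = {}
    canonical_sets: dict[tuple[str, int], set] = {}
    for rp, h1, h2 in pair_hits:
        u1, u2 = _unique_hit(h1), _unique_hit(h2)
        for u in (u1, u2):
            if u is not None:
                expression[u.target_id] += 1
        if u1 is None or u2 is None or u1.target_id != u2.target_id:
            continue
        gene = by_id[u1.target_id]
        if u1.orientation != u2.orientation:
            fwd, rev = (u1, u2) if u1.orientation == FORWARD else (u2, u1)
            if fwd.offset <= rev.offset:
                inserts.append(rev.offset + rl - fwd.offset)
            window_input.setdefault(gene.gene_id, []).append((u1, u2))
        # canonical junction-crossing support, deduplicated like scrambles
        boundaries = [sum(gene.exon_lengths[: i + 1]) for i in range(gene.n_exons - 1)]
        for u, mate in ((u1, u2), (u2, u1)):
            for bi, boundary in enumerate(boundaries, start=1):
                if _spans_boundary_clean(u, boundary, config.min_flank, rl):
                    canonical_sets.setdefault((gene.gene_id, bi), set()).add(
                        (u.offset, mate.offset, u.mismatch_profile, mate.mismatch_profile)
                    )
    canonical_counts = {k: len(v) for k, v in canonical_sets.items()}

    window_matrices = {
        gid: detect.window_scan(by_id[gid], pairs, config.bin_size)
        for gid, pairs in window_input.items()
    }

    insert_dist = None
    if len(inserts) >= config.min_insert_pairs:
        insert_dist = circ_stats.empirical_insert_distribution(
            inserts, min_pairs=config.min_insert_pairs
        )
    else:
        logger.warning(
            "only %d proper pairs: insert distribution not estimated", len(inserts)
        )

    # --- junction database and junctional evidence ------------------------
    junctions = build_junction_database(
        genes, seqs, read_length=rl, min_flank=config.min_flank,
        expressed_only=expressed_only,
    )
    junction_by_record = {j.record_id: j for j in junctions}
    jdb_aligner = Aligner({j.record_id: j.junction_seq for j in junctions})

    classified: dict[str, list[ClassifiedPair]] = {}
    forward_counts: dict[tuple[str, int, int], int] = {}
    for rp, h1, h2 in pair_hits:
        for mate_seq, own_hits, other_hits in (
            (rp.mate1, h1, h2),
            (rp.mate2, h2, h1),
        ):
            if own_hits:  # pipeline ordering: transcriptome-aligned reads stop there
                continue
            jhits = jdb_aligner.align_read(rp.read_id, mate_seq, config.max_mismatches)
            ja = _unique_hit(jhits)
            if ja is None:
                continue
            junction = junction_by_record[ja.target_id]
            if not is_junctional(ja, junction.breakpoint_offset, config.min_flank, read_length=rl):
                continue
            if not junction.scrambled:
                key = (junction.gene_id, junction.donor_index, junction.acceptor_index)
                forward_counts[key] = forward_counts.get(key, 0) + 1
                continue
            mate_unique = _unique_hit(other_hits)
            cls = detect.classify_pair(
                ja, mate_unique, by_id[junction.gene_id], junction, rl,
                min_flank=config.min_flank,
            )
            classified.setdefault(ja.target_id, []).append(
                ClassifiedPair(
                    junction_offset=ja.offset,
                    junction_profile=ja.mismatch_profile,
                    mate_offset=None if mate_unique is None else mate_unique.offset,
                    mate_profile=None if mate_unique is None else mate_unique.mismatch_profile,
                    pair_class=cls,
                )
            )

    evidence = [
        detect.dedup_and_count(junction_by_record[rec], pairs)
        for rec, pairs in sorted(classified.items())
    ]

    # --- quantification ----------------------------------------------------
    estimates: list[quantify.AbundanceEstimate] = []
    for ev in evidence:
        j = ev.junction
        gene = by_id[j.gene_id]
        jj, e, ratio = quantify.estimate_rates(
            ev.n_distinct, expression[j.gene_id], gene.mature_length, rl, config.min_flank
        )
        # canonical comparison junctions: the ones between Y and X adjacent
        # to the scramble (internal to the circle, so circular molecules
        # contribute to them too); a self-junction falls back to the
        # flanking canonical junctions
        if j.donor_index > j.acceptor_index:
            donor_count = canonical_counts.get((j.gene_id, j.donor_index - 1), 0)
            acceptor_count = canonical_counts.get((j.gene_id, j.acceptor_index), 0)
        else:
            donor_count = (
                canonical_counts.get((j.gene_id, j.donor_index), 0)
                if j.donor_index < gene.n_exons
                else None
            )
            acceptor_count = (
                canonical_counts.get((j.gene_id, j.acceptor_index - 1), 0)
                if j.acceptor_index >= 2
                else None
            )
        try:
            frac = quantify.method1_fraction(
                ev.n_circle_consistent, donor_count, acceptor_count
            )
        except quantify.UndefinedFractionError:
            frac = None
        estimates.append(
            quantify.AbundanceEstimate(
                gene_id=j.gene_id,
                donor_index=j.donor_index,
                acceptor_index=j.acceptor_index,
                j=jj,
                e=e,
                ratio_je=ratio,
                fraction_method1=frac,
                abundance_bin=None if frac is None else quantify.assign_bin(frac),
            )
        )
    histogram = quantify.abundance_histogram(estimates)

    # --- circularity statistics -------------------------------------------
    assessments: list[circ_stats.CircularityAssessment] = []
    expected = None
    if insert_dist is not None and evidence:
        assessments = circ_stats.assess_circularity(
            evidence, genes, insert_dist, offset_averaged=config.offset_averaged
        )
        expected = circ_stats.genomewide_expected_linear([a.p0 for a in assessments])

    scrambled_genes = sorted(
        {
            ev.junction.gene_id
            for ev in evidence
            if ev.n_distinct >= config.min_junctional_reads
        }
    )
    summary = {
        "n_read_pairs": len(pair_hits),
        "n_proper_pairs": len(inserts),
        "n_scrambled_junctions": len(evidence),
        "scrambled_genes": scrambled_genes,
        "n_scrambled_genes": len(scrambled_genes),
        "n_junctions_min_fraction": sum(
            1
            for est in estimates
            if est.fraction_method1 is not None
            and est.fraction_method1 >= config.min_fraction
        ),
        "abundance_histogram": histogram,
        "n_testable": sum(1 for a in assessments if a.testable),
        "n_untestable": sum(1 for a in assessments if not a.testable),
        "expected_linear_binned": None if expected is None else expected[0],
        "expected_linear_exact": None if expected is None else expected[1],
    }

    return PipelineResult(
        config=config,
        genes=list(genes),
        junctions=junctions,
        expression=expression,
        insert_distribution=insert_dist,
        evidence=evidence,
        canonical_pair_counts=canonical_counts,
        forward_junction_counts=forward_counts,
        estimates=estimates,
        histogram=histogram,
        assessments=assessments,
        expected_linear=expected,
        window_matrices=window_matrices,
        summary=summary,
    )
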