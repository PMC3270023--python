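"""Annotation model, circle-length arithmetic, and junction database."""

import numpy as np
import pytest

from circkit.genome_model import (
    AnnotationError,
    GeneModel,
    GenomicInterval,
    InvalidJunctionError,
    build_junction_database,
    circle_length,
    exon_sequence,
    load_annotation,
    transcript_sequence,
    write_bed12,
)
from conftest import random_seq


def bed12_line(chrom, start, name, strand, sizes, offsets):
    end = start + offsets[-1] + sizes[-1]
    return "\t".join(
        [chrom, str(start), str(end), name, "0", strand, str(start), str(end), "0",
         str(len(sizes)), ",".join(map(str, sizes)), ",".join(map(str, offsets))]
    )


class TestLoadAnnotation:
    def test_bed12_block_count_maps_to_exons(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(bed12_line("chr1", 100, "g1", "+", [50, 60, 70], [0, 200, 500]) + "\n")
        (gene,) = load_annotation(p, "BED12")
        assert gene.n_exons == 3
        assert gene.exon_lengths == [50, 60, 70]
        assert gene.exons[0].start == 100

    def test_minus_strand_exon1_is_threeprime_most_block(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(bed12_line("chr1", 100, "g1", "-", [50, 60], [0, 200]) + "\n")
        (gene,) = load_annotation(p, "BED12")
        # exon 1 in transcription order is the genomically last block
        assert gene.exons[0].start == 300
        assert gene.exon_lengths == [60, 50]

    def test_representative_transcript_has_most_exons(self, tmp_path):
        p = tmp_path / "a.bed"
        lines = [
            bed12_line("chr1", 100, "g1|txA", "+", [50, 60], [0, 200]),
            bed12_line("chr1", 100, "g1|txB", "+", [50, 60, 70], [0, 200, 500]),
        ]
        p.write_text("\n".join(lines) + "\n")
        (gene,) = load_annotation(p, "BED12")
        assert gene.transcript_id == "txB"
        assert gene.n_exons == 3

    def test_representative_tie_broken_by_mature_length_then_id(self, tmp_path):
        p = tmp_path / "a.bed"
        lines = [
            bed12_line("chr1", 100, "g1|txA", "+", [50, 60], [0, 200]),
            bed12_line("chr1", 100, "g1|txB", "+", [50, 90], [0, 200]),
            bed12_line("chr2", 100, "g2|txD", "+", [50, 60], [0, 200]),
            bed12_line("chr2", 100, "g2|txC", "+", [50, 60], [0, 300]),
        ]
        p.write_text("\n".join(lines) + "\n")
        genes = load_annotation(p, "BED12")
        assert genes[0].transcript_id == "txB"  # longer mature length
        assert genes[1].transcript_id == "txC"  # lexicographic tie-break

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\tnot-an-int\n")
        with pytest.raises(AnnotationError, match="line 1"):
            load_annotation(p, "BED12")

    def test_bed12_round_trip(self, tmp_path, rng):
        p = tmp_path / "a.bed"
        lines = [
            bed12_line("chr1", 100, "g1", "+", [50, 60, 70], [0, 200, 500]),
            bed12_line("chr2", 30, "g2", "-", [40, 90], [0, 400]),
        ]
        p.write_text("\n".join(lines) + "\n")
        genes = load_annotation(p, "BED12")
        out = tmp_path / "b.bed"
        write_bed12(genes, out)
        again = load_annotation(out, "BED12")
        assert [(g.gene_id, g.exons) for g in again] == [(g.gene_id, g.exons) for g in genes]

    def test_gtf_agrees_with_bed12(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text(bed12_line("chr1", 100, "g1|t1", "+", [50, 60], [0, 200]) + "\n")
        gtf = tmp_path / "a.gtf"
        rows = [
            ("chr1", "src", "exon", 101, 150, ".", "+", ".", 'gene_id "g1"; transcript_id "t1";'),
            ("chr1", "src", "exon", 301, 360, ".", "+", ".", 'gene_id "g1"; transcript_id "t1";'),
        ]
        gtf.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        (from_bed,) = load_annotation(bed, "BED12")
        (from_gtf,) = load_annotation(gtf, "GTF")
        assert from_gtf.exons == from_bed.exons


class TestCircleLength:
    def test_sum_of_exons_acceptor_through_donor(self):
        exons = [GenomicInterval("c", i * 1000, i * 1000 + ln, "+")
                 for i, ln in enumerate([90, 100, 120])]
        gene = GeneModel("g", exons)
        assert circle_length(gene, 3, 2) == 220

    def test_self_junction_circle_is_single_exon_length(self):
        # a 3-3 self-junction on a 338 bp exon predicts a 338 bp circle
        exons = [GenomicInterval("c", i * 1000, i * 1000 + ln, "+")
                 for i, ln in enumerate([100, 150, 338])]
        gene = GeneModel("REXO4-like", exons)
        assert circle_length(gene, 3, 3) == 338

    def test_forward_junction_rejected(self, toy_gene):
        with pytest.raises(InvalidJunctionError):
            circle_length(toy_gene, 2, 3)

    def test_additivity(self, toy_gene):
        for y in range(1, toy_gene.n_exons + 1):
            for x in range(y + 1, toy_gene.n_exons + 1):
                assert circle_length(toy_gene, x, y) == (
                    circle_length(toy_gene, x - 1, y) + toy_gene.exon_lengths[x - 1]
                )
                assert circle_length(toy_gene, x, y) > 0


class TestJunctionDatabase:
    @pytest.mark.parametrize("k", range(1, 9))
    def test_combinatorics_all_ordered_pairs(self, k, rng):
        exons = [GenomicInterval("c", i * 500, i * 500 + 200, "+") for i in range(k)]
        gene = GeneModel("g", exons)
        chrom = {"c": random_seq(rng, 500 * k)}
        junctions = build_junction_database([gene], chrom)
        assert len(junctions) == k * k
        assert sum(j.scrambled for j in junctions) == k * (k + 1) // 2

    def test_junction_seq_window_and_breakpoint(self, toy_gene, toy_chromosome):
        junctions = build_junction_database(
            [toy_gene], toy_chromosome, read_length=80, min_flank=11
        )
        j32 = next(j for j in junctions if (j.donor_index, j.acceptor_index) == (3, 2))
        assert len(j32.junction_seq) == 138  # 2 * (80 - 11)
        assert j32.breakpoint_offset == 69
        from circkit.genome_model import SequenceSource

        donor_seq = exon_sequence(toy_gene, 3, SequenceSource(toy_chromosome))
        assert j32.junction_seq[:69] == donor_seq[-69:]

    def test_short_exon_contributes_full_length_only(self, rng):
        exons = [GenomicInterval("c", 100, 140, "+"), GenomicInterval("c", 500, 700, "+")]
        gene = GeneModel("g", exons)
        chrom = {"c": random_seq(rng, 800)}
        junctions = build_junction_database([gene], chrom, read_length=80, min_flank=11)
        j = next(x for x in junctions if (x.donor_index, x.acceptor_index) == (1, 2))
        assert j.breakpoint_offset == 40  # whole 40 bp exon, no spill
        assert len(j.junction_seq) == 40 + 69

    def test_single_exon_gene_self_junction(self, rng):
        gene = GeneModel("g", [GenomicInterval("c", 0, 300, "+")])
        junctions = build_junction_database([gene], {"c": random_seq(rng, 300)})
        assert len(junctions) == 1
        assert junctions[0].scrambled

    def test_missing_sequence_names_gene(self, toy_gene):
        with pytest.raises(AnnotationError, match="toy"):
            build_junction_database([toy_gene], {"other": "ACGT" * 100})


def test_minus_strand_transcript_is_revcomp_of_blocks(rng=None):
    r = np.random.default_rng(7)
    seq = random_seq(r, 1000)
    exons = [GenomicInterval("c", 600, 700, "-"), GenomicInterval("c", 100, 250, "-")]
    gene = GeneModel("g", exons)
    from circkit.genome_model import SequenceSource, reverse_complement

    tx = transcript_sequence(gene, SequenceSource({"c": seq}))
    assert tx == reverse_complement(seq[600:700]) + reverse_complement(seq[100:250])
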