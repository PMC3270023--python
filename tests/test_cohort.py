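"""Cohort analyses: poly-A enrichment, complement search, permutation tests,
intron-length quantiles."""

import numpy as np
import pytest

from circkit.cohort import (
    PolyAEnrichment,
    acceptor_position_enrichment,
    complementary_splice_search,
    intron_length_quantiles,
    polya_enrichment,
    supported_percent,
)
from circkit.genome_model import ExonJunction, GeneModel, GenomicInterval
from conftest import random_seq


class TestPolyAEnrichment:
    def test_pseudocount_ratio(self):
        p = PolyAEnrichment(ExonJunction("g", 2, 2, "A" * 138, 69), 2, 20)
        assert p.enrichment == pytest.approx(21 / 3)

    def test_zero_counts_uninformative(self):
        p = PolyAEnrichment(ExonJunction("g", 2, 2, "A" * 138, 69), 0, 0)
        assert p.enrichment == 1.0

    def test_counts_unique_junctional_reads_per_fraction(self, rng):
        seq = random_seq(rng, 138)
        j = ExonJunction("g", 3, 2, seq, 69)
        crossing = seq[29:109]  # covers 40/40 around the breakpoint
        non_crossing = seq[:75]  # only 6 bases on the acceptor side: not junctional
        per, agg = polya_enrichment(
            [j],
            selected_reads=[("s1", crossing)],
            depleted_reads=[("d1", crossing), ("d2", crossing), ("d3", non_crossing)],
        )
        assert per[0].count_selected == 1
        assert per[0].count_depleted == 2
        assert agg == pytest.approx(3 / 2)

    def test_empty_fraction_rejected(self):
        j = ExonJunction("g", 2, 2, "A" * 138, 69)
        with pytest.raises(ValueError):
            polya_enrichment([j], [], [("d", "A" * 80)])

    def test_aggregate_invariant_to_read_order(self, rng):
        seq = random_seq(rng, 138)
        j = ExonJunction("g", 2, 2, seq, 69)
        reads = [(f"r{i}", seq[o : o + 80]) for i, o in enumerate(range(12, 58, 5))]
        _, agg1 = polya_enrichment([j], reads, reads[::-1])
        _, agg2 = polya_enrichment([j], reads[::-1], reads)
        assert agg1 == agg2 == 1.0


class TestComplementSearch:
    def make_gene(self, lengths):
        exons = [GenomicInterval("c", i * 1000, i * 1000 + ln, "+") for i, ln in enumerate(lengths)]
        return GeneModel("g", exons)

    def test_frame_preserving_block(self):
        gene = self.make_gene([90, 100, 122, 80])  # block 2..3 = 222 bp
        ev = complementary_splice_search(gene, 3, 2, {("g", 1, 4): 5})
        assert ev.frame_preserving is True
        assert (ev.complement_donor, ev.complement_acceptor) == (1, 4)
        assert ev.support == 5 and ev.supported

    def test_frame_breaking_block(self):
        gene = self.make_gene([90, 100, 120, 80])  # block 2..3 = 220 bp
        ev = complementary_splice_search(gene, 3, 2, {})
        assert ev.frame_preserving is False

    def test_single_read_not_supported(self):
        gene = self.make_gene([90, 100, 122, 80])
        ev = complementary_splice_search(gene, 3, 2, {("g", 1, 4): 1})
        assert ev.support == 1 and not ev.supported

    def test_terminal_circle_complement_undefined(self):
        gene = self.make_gene([90, 100, 122, 80])
        ev = complementary_splice_search(gene, 4, 2, {})
        assert not ev.complement_defined and not ev.supported

    def test_supported_percent_truncates_one_decimal(self):
        assert supported_percent(13, 576) == 2.2
        assert supported_percent(1, 3) == 33.3


def make_genes(n, k, seed=0):
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n):
        lengths = rng.integers(80, 200, size=k)
        exons = []
        pos = 0
        for ln in lengths:
            exons.append(GenomicInterval(f"c{i}", pos, pos + int(ln), "+"))
            pos += int(ln) + int(rng.integers(100, 1000))
        genes.append(GeneModel(f"g{i}", exons))
    return genes


class TestAcceptorEnrichment:
    def test_all_exon2_acceptors_min_pvalue(self):
        genes = make_genes(10, 7)
        junctions = [(g.gene_id, 2) for g in genes for _ in range(3)]
        obs, p = acceptor_position_enrichment(junctions, genes, n_permutations=1000, seed=1)
        assert obs == 1.0
        assert p == pytest.approx(1 / 1001)

    def test_two_exon_gene_single_junction_p_is_one(self):
        genes = make_genes(1, 2)
        obs, p = acceptor_position_enrichment([("g0", 2)], genes, n_permutations=1000, seed=1)
        assert p == 1.0

    def test_pvalue_bounds_and_seed_reproducibility(self):
        genes = make_genes(8, 6)
        rng = np.random.default_rng(4)
        junctions = [(g.gene_id, int(rng.integers(2, 7))) for g in genes for _ in range(4)]
        out1 = acceptor_position_enrichment(junctions, genes, n_permutations=1000, seed=9)
        out2 = acceptor_position_enrichment(junctions, genes, n_permutations=1000, seed=9)
        assert out1 == out2
        assert 1 / 1001 <= out1[1] <= 1.0

    def test_no_junctions_rejected(self):
        with pytest.raises(ValueError):
            acceptor_position_enrichment([], make_genes(2, 4), n_permutations=1000, seed=0)


class TestIntronQuantiles:
    def test_hand_computed_rank_on_toy_fixture(self):
        # 10 genes whose first intron lengths are 100, 200, ..., 1000
        genes = []
        for i in range(10):
            intron = (i + 1) * 100
            exons = [
                GenomicInterval(f"c{i}", 0, 100, "+"),
                GenomicInterval(f"c{i}", 100 + intron, 200 + intron, "+"),
                GenomicInterval(f"c{i}", 2600 + intron, 2700 + intron, "+"),
            ]
            genes.append(GeneModel(f"g{i}", exons))
        # circle genes: the ones with intron-1 lengths 800, 900, 1000
        circles = [("g7", 2, 2), ("g8", 2, 2), ("g9", 2, 2)]
        df = intron_length_quantiles(circles, genes, max_index=2)
        row = df[(df.stratum == "donor") & (df.exon_index == 2) & (df.intron_index == 1)].iloc[0]
        # median 900 ranks 8.5th of 10 values (mean rank)
        assert row["quantile"] == pytest.approx(0.85)

    def test_null_sample_sits_mid_distribution(self):
        genes = make_genes(40, 5, seed=3)
        circles = [(g.gene_id, 3, 2) for g in genes]  # every gene: quantile of overall median
        df = intron_length_quantiles(circles, genes)
        got = df.dropna(subset=["quantile"])
        assert ((got["quantile"] - 0.5).abs() < 0.15).all()

    def test_small_strata_emitted_missing(self):
        genes = make_genes(10, 5, seed=3)
        df = intron_length_quantiles([("g0", 3, 2), ("g1", 3, 2)], genes)
        assert df["quantile"].isna().all()
        assert (df["n_genes"] <= 2).all()
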