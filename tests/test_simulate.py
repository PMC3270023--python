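"""Synthetic-data generator: determinism, structure mix, fragment geometry,
poly-A partition."""

import numpy as np
import pytest
from scipy import stats as sps

from circkit.simulate import (
    ConfigError,
    SimConfig,
    _trapezoid_sampler,
    polya_partition,
    simulate,
    simulate_transcriptome,
    write_outputs,
)


def small(seed=1, **kw):
    kw.setdefault("n_genes", 6)
    kw.setdefault("coverage", 10.0)
    return SimConfig(seed=seed, **kw)


class TestConfig:
    def test_fractions_must_fit(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, circular_fraction=0.7, tandem_fraction=0.5)

    def test_infeasible_exon_range(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, exon_count_range=(5, 3))

    def test_insert_model_must_cover_read(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, insert_core=(100, 200), insert_tail=50)


class TestTranscriptomePool:
    def test_all_linear_when_no_structures(self):
        sim = simulate_transcriptome(small(circular_fraction=0.0, tandem_fraction=0.0))
        assert {i.structure for i in sim.isoforms} == {"linear"}

    def test_pure_circular_pool_two_exon_genes(self):
        sim = simulate_transcriptome(
            small(circular_fraction=1.0, exon_count_range=(2, 2))
        )
        assert {i.structure for i in sim.isoforms} == {"circular"}
        # with two exons, the only eligible splice acceptor is exon 2 (1-based)
        assert all(i.acceptor_index == 2 for i in sim.isoforms)
        assert all(not i.polyadenylated for i in sim.isoforms)

    def test_polyadenylation_follows_structure(self):
        sim = simulate_transcriptome(small(circular_fraction=0.4, tandem_fraction=0.3))
        for iso in sim.isoforms:
            assert iso.polyadenylated == (iso.structure != "circular")

    def test_tandem_sequence_duplicates_block(self):
        sim = simulate_transcriptome(small(circular_fraction=0.0, tandem_fraction=0.5))
        linear = {i.gene_id: i for i in sim.isoforms if i.structure == "linear"}
        for iso in sim.isoforms:
            if iso.structure != "tandem_dup":
                continue
            gene = next(g for g in sim.genes if g.gene_id == iso.gene_id)
            block = sum(gene.exon_lengths[iso.acceptor_index - 1 : iso.donor_index])
            assert iso.length == linear[iso.gene_id].length + block

    def test_same_seed_bit_identical(self, tmp_path):
        out1 = write_outputs(simulate(small(seed=9)), tmp_path / "a")
        out2 = write_outputs(simulate(small(seed=9)), tmp_path / "b")
        for key in ("annotation", "genome", "reads1", "reads2"):
            assert out1[key].read_bytes() == out2[key].read_bytes()

    def test_different_seed_differs(self):
        a = simulate(small(seed=9))
        b = simulate(small(seed=10))
        assert a.chromosomes != b.chromosomes


class TestFragmentGeometry:
    def test_linear_reads_are_exact_substrings_without_errors(self):
        sim = simulate(small(circular_fraction=0.0, error_rate=0.0))
        by_iso = {i.isoform_id: i for i in sim.isoforms}
        from circkit.genome_model import reverse_complement

        for rp in sim.read_pairs[:50]:
            tx = by_iso[rp.isoform_id].sequence
            assert rp.mate1 in tx or reverse_complement(rp.mate1) in tx

    def test_full_length_circle_fragment_wraps_once(self):
        # force the insert draw to 400; two-exon circles (span 2, 200-bp
        # exons) are then sequenced as exactly one full turn of the circle
        cfg = SimConfig(
            seed=4, n_genes=8, coverage=15.0, circular_fraction=1.0,
            exon_count_range=(3, 3), exon_length_range=(200, 200),
            circle_span_range=(2, 2),
            insert_core=(400, 400), insert_tail=0, error_rate=0.0,
        )
        sim = simulate(cfg)
        full_turn = {i.isoform_id for i in sim.isoforms if i.length == 400}
        assert full_turn
        rows = [r for r in sim.read_pairs if r.isoform_id in full_turn]
        assert rows
        for rp in rows:
            assert rp.frag_len == 400
            assert rp.crosses_backsplice == (rp.frag_start > 0)

    def test_backsplice_crossing_fraction_matches_closed_form(self):
        cfg = SimConfig(seed=8, n_genes=12, coverage=40.0, circular_fraction=1.0,
                        error_rate=0.0)
        sim = simulate(cfg)
        sampler_dist = sps.trapezoid(0.25, 0.75, loc=200, scale=400)
        truth = sim.read_truth
        for iso in sim.isoforms:
            rows = truth[truth.isoform_id == iso.isoform_id]
            if len(rows) < 50:
                continue
            L = iso.length
            expect = sampler_dist.expect(lambda x: min(round(x), L) - 1) / L
            obs = rows.crosses_backsplice.mean()
            se = np.sqrt(expect * (1 - expect) / len(rows))
            assert abs(obs - expect) <= 3 * se + 1 / len(rows)

    def test_trapezoid_sampler_range_and_median(self):
        cfg = SimConfig(seed=1)
        sample_fn = _trapezoid_sampler(cfg)
        rng = np.random.default_rng(0)
        draws = np.array([sample_fn(rng) for _ in range(4000)])
        assert draws.min() >= 200 and draws.max() <= 600
        assert abs(np.median(draws) - 400) < 10


class TestPolyAPartition:
    def test_perfect_selection(self):
        cfg = small(circular_fraction=0.5, polya_retention=1.0, polya_leakage=0.0)
        sim = simulate(cfg)
        sel, dep = polya_partition(sim)
        assert all(r.polyadenylated for r in sel)
        assert all(not r.polyadenylated for r in dep)

    def test_null_partition_independent_of_structure(self):
        cfg = small(
            n_genes=12, coverage=25.0, circular_fraction=0.5,
            polya_retention=0.5, polya_leakage=0.5,
        )
        sim = simulate(cfg)
        sel, dep = polya_partition(sim)
        frac = {}
        for flag in (True, False):
            n_sel = sum(1 for r in sel if r.polyadenylated is flag)
            n_dep = sum(1 for r in dep if r.polyadenylated is flag)
            frac[flag] = n_sel / (n_sel + n_dep)
        assert abs(frac[True] - frac[False]) < 0.1

    def test_leaky_defaults_concentrate_circles_in_depleted(self):
        cfg = small(n_genes=12, coverage=25.0, circular_fraction=0.5)
        sim = simulate(cfg)
        sel, dep = polya_partition(sim)
        dep_circ = sum(1 for r in dep if not r.polyadenylated)
        sel_circ = sum(1 for r in sel if not r.polyadenylated)
        assert dep_circ > 5 * sel_circ


def test_template_switch_chimeras_present_when_enabled():
    cfg = small(circular_fraction=0.0, template_switch_rate=0.3, error_rate=0.0)
    sim = simulate(cfg)
    structures = {r.structure for r in sim.read_pairs}
    assert "template_switch" in structures
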