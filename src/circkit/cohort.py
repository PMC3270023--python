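"""Cohort-level analyses over a curated set of scrambled junctions.

Four independent analyses:

* poly-A enrichment — circles lack poly-A tails, so junctional reads from
  true circles should concentrate in the poly-A *depleted* (flow-through)
  fraction of a poly-A selection, while tandem-duplication junctions on
  linear transcripts show the opposite sign;
* complementary alternative-splice search — if circles were byproducts of
  exon-skipping events, the complementary skip junction (Y-1)->(X+1)
  should be seen in the linear transcript pool;
* acceptor-position enrichment — a permutation test for over-use of a
  particular exon (exon 2 in practice) as the circle acceptor;
* intron-length quantiles — where the median intron length of
  circle-producing genes sits within the all-gene intron length
  distribution, stratified by donor/acceptor exon index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import Aligner, align_to_junctions, is_junctional
from .genome_model import ExonJunction, GeneModel

PSEUDOCOUNT = 1.0


@dataclass
class PolyAEnrichment:
    junction: ExonJunction
    count_selected: int
    count_depleted: int

    @property
    def enrichment(self) -> float:
        """Depleted/selected read-count ratio with pseudocount 1 on both."""
        return (self.count_depleted + PSEUDOCOUNT) / (self.count_selected + PSEUDOCOUNT)


def _unique_junctional_counts(
    reads: Iterable[tuple[str, str]],
    junctions: Sequence[ExonJunction],
    read_length: int,
    min_flank: int,
    max_mismatches: int,
    aligner: Aligner | None = None,
) -> dict[str, int]:
    if aligner is None:
        aligner = Aligner({j.record_id: j.junction_seq for j in junctions})
    by_record = {j.record_id: j for j in junctions}
    counts = {j.record_id: 0 for j in junctions}
    hits = align_to_junctions(reads, junctions, max_mismatches, aligner=aligner)
    for alns in hits.values():
        for a in alns:
            if not a.unique or a.target_id not in by_record:
                continue
            j = by_record[a.target_id]
            if is_junctional(
                a, j.breakpoint_offset, min_flank,
                read_length=a.read_length if a.read_length is not None else read_length,
            ):
                counts[a.target_id] += 1
    return counts


def polya_enrichment(
    junctions: Sequence[ExonJunction],
    selected_reads: Iterable[tuple[str, str]],
    depleted_reads: Iterable[tuple[str, str]],
    read_length: int = 80,
    min_flank: int = 11,
    max_mismatches: int = 3,
) -> tuple[list[PolyAEnrichment], float]:
    """Per-junction and aggregate depleted/selected junctional-read ratios.

    Reads are single-end; each fraction's reads are aligned directly to the
    junction database and counted when uniquely, junctionally aligned.
    The aggregate is (total depleted + 1) / (total selected + 1).
    """
    selected_reads = list(selected_reads)
    depleted_reads = list(depleted_reads)
    if not selected_reads or not depleted_reads:
        raise ValueError("empty read set for a poly-A fraction")
    aligner = Aligner({j.record_id: j.junction_seq for j in junctions})
    sel = _unique_junctional_counts(
        selected_reads, junctions, read_length, min_flank, max_mismatches, aligner
    )
    dep = _unique_junctional_counts(
        depleted_reads, junctions, read_length, min_flank, max_mismatches, aligner
    )
    per_junction = [
        PolyAEnrichment(j, sel[j.record_id], dep[j.record_id]) for j in junctions
    ]
    aggregate = (sum(dep.values()) + PSEUDOCOUNT) / (sum(sel.values()) + PSEUDOCOUNT)
    return per_junction, aggregate


@dataclass
class ComplementEvidence:
    gene_id: str
    donor_index: int  # X of the circle
    acceptor_index: int  # Y of the circle
    complement_defined: bool
    complement_donor: int | None  # Y-1
    complement_acceptor: int | None  # X+1
    support: int
    frame_preserving: bool | None

    @property
    def supported(self) -> bool:
        """Supported per the more-than-one-read rule."""
        return self.complement_defined and self.support > 1


def complementary_splice_search(
    gene: GeneModel,
    donor_index: int,
    acceptor_index: int,
    junction_read_counts: Mapping[tuple[str, int, int], int],
) -> ComplementEvidence:
    """Evidence for the forward skip junction (Y-1)->(X+1) complementary to
    a circle of exons Y..X.

    ``junction_read_counts`` maps (gene_id, donor, acceptor) to junctional
    read counts in the linear transcript pool.  The complement is undefined
    when the circle touches the first or last exon.  ``frame_preserving``
    is whether the skipped block length is a multiple of 3 (a proxy for the
    skip product escaping nonsense-mediated decay).
    """
    if donor_index < acceptor_index:
        raise ValueError("not a scrambled junction")
    defined = acceptor_index >= 2 and donor_index < gene.n_exons
    block_len = sum(gene.exon_lengths[acceptor_index - 1 : donor_index])
    if not defined:
        return ComplementEvidence(
            gene.gene_id, donor_index, acceptor_index, False, None, None, 0, None
        )
    cd, ca = acceptor_index - 1, donor_index + 1
    support = junction_read_counts.get((gene.gene_id, cd, ca), 0)
    return ComplementEvidence(
        gene.gene_id,
        donor_index,
        acceptor_index,
        True,
        cd,
        ca,
        support,
        block_len % 3 == 0,
    )


def supported_percent(n_supported: int, n_total: int) -> float:
    """Percentage of scrambled isoforms with a supported complement,
    truncated (not rounded) to one decimal place."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(100.0 * n_supported / n_total * 10) / 10


def acceptor_position_enrichment(
    junctions: Sequence[tuple[str, int]],
    genes: Iterable[GeneModel],
    n_permutations: int = 10000,
    seed: int = 0,
    target_acceptor: int = 2,
) -> tuple[float, float]:
    """Permutation test for enrichment of ``target_acceptor`` as the circle
    acceptor exon.

    ``junctions`` is a list of (gene_id, acceptor_index Y) for observed
    scrambled junctions.  The null redraws each junction's Y uniformly from
    its gene's eligible acceptor positions (2..exon count), preserving the
    junction count per gene.  Returns (observed fraction with
    Y == target_acceptor, permutation p-value with +1 correction).
    """
    if n_permutations < 1000:
        raise ValueError("n_permutations must be >= 1000")
    if not junctions:
        raise ValueError("no scrambled junctions")
    by_id = {g.gene_id: g for g in genes}
    k = np.array([by_id[g].n_exons for g, _ in junctions])
    if np.any(k < 2):
        raise ValueError("genes must have at least 2 exons for an eligible acceptor")
    y_obs = np.array([y for _, y in junctions])
    observed = float(np.mean(y_obs == target_acceptor))
    # P(draw == target) per junction under uniform 2..k
    eligible = k - 1
    p_target = np.where(
        (2 <= target_acceptor) & (target_acceptor <= k), 1.0 / eligible, 0.0
    )
    rng = np.random.default_rng(seed)
    draws = rng.random((n_permutations, len(junctions))) < p_target
    perm_stats = draws.mean(axis=1)
    p_value = (1.0 + np.sum(perm_stats >= observed)) / (n_permutations + 1.0)
    return observed, float(p_value)


def intron_length_quantiles(
    circle_junctions: Sequence[tuple[str, int, int]],
    genes: Iterable[GeneModel],
    max_index: int = 9,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Quantile of circle-gene median intron length in the all-gene
    distribution, per (stratum, exon index, intron index).

    ``circle_junctions`` holds (gene_id, donor X, acceptor Y).  For the
    donor stratum, junctions are grouped by X; for the acceptor stratum by
    Y.  For each group and each intron index i <= max_index, the median of
    intron i among the group's genes is ranked (mean-rank quantile, in
    [0, 1]) within intron i's length distribution over all genes.  Strata
    with fewer than ``min_genes`` genes are emitted with a missing
    quantile.
    """
    genes = list(genes)
    by_id = {g.gene_id: g for g in genes}
    all_introns: dict[int, np.ndarray] = {}
    for i in range(1, max_index + 1):
        vals = [g.intron_lengths[i - 1] for g in genes if g.n_exons > i]
        all_introns[i] = np.asarray(vals, dtype=float)

    rows = []
    for stratum, pick in (("donor", 0), ("acceptor", 1)):
        groups: dict[int, set[str]] = {}
        for gene_id, x, y in circle_junctions:
            idx = (x, y)[pick]
            if idx <= max_index:
                groups.setdefault(idx, set()).add(gene_id)
        for exon_index in sorted(groups):
            gene_ids = groups[exon_index]
            for intron_index in range(1, max_index + 1):
                lengths = [
                    by_id[g].intron_lengths[intron_index - 1]
                    for g in gene_ids
                    if by_id[g].n_exons > intron_index
                ]
                if len(lengths) < min_genes or all_introns[intron_index].size == 0:
                    quantile = np.nan
                else:
                    med = float(np.median(lengths))
                    quantile = (
                        stats.percentileofscore(
                            all_introns[intron_index], med, kind="mean"
                        )
                        / 100.0
                    )
                rows.append(
                    {
                        "stratum": stratum,
                        "exon_index": exon_index,
                        "intron_index": intron_index,
                        "n_genes": len(lengths),
                        "quantile": quantile,
                    }
                )
    return pd.DataFrame(rows)


def write_polya_tsv(
    per_junction: Sequence[PolyAEnrichment], aggregate: float, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# aggregate_enrichment (pseudocount 1): %.6g\n" % aggregate)
        fh.write("record_id\tcount_selected\tcount_depleted\tenrichment\n")
        for p in per_junction:
            fh.write(
                f"{p.junction.record_id}\t{p.count_selected}\t{p.count_depleted}\t"
                f"{p.enrichment:.6g}\n"
            )
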