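"""Relative abundance of scrambled vs canonical isoforms.

Two estimators are emitted side by side:

* the junctional-rate ratio j/e, where j is the per-nucleotide rate of
  deduplicated junctional reads and e the per-nucleotide gene expression
  rate (unique reads / mature gene length); and
* "method 1", the fraction n_scr / (n_scr + canonical), comparing
  circle-consistent scrambled pairs against read pairs supporting the
  canonical-order splice junctions between exons Y and X — the junctions
  adjacent to the scramble inside the interval (X-1 -> X and Y -> Y+1).
  Because a circle of exons Y..X itself contains those canonical
  junctions, circular molecules inflate the denominator, which is why
  method 1 systematically underestimates the scrambled fraction.  A
  self-junction (X == Y) has no internal canonical junction and falls
  back to the flanking junctions (X -> X+1 and Y-1 -> Y).

j's per-nucleotide denominator is W = read_length - 2*min_flank + 1, the
number of read offsets that satisfy the junctional criterion; this makes j
commensurate with e.  W scales every j/e output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

ABUNDANCE_BINS = ("0-25%", "25-50%", "50-75%", "75+%")


class UndefinedFractionError(ValueError):
    """All counts zero: no reads to form a fraction from."""


@dataclass
class AbundanceEstimate:
    gene_id: str
    donor_index: int
    acceptor_index: int
    j: float
    e: float
    ratio_je: float | None  # None when e == 0
    fraction_method1: float | None
    abundance_bin: str | None

    @property
    def testable_ratio(self) -> bool:
        return self.ratio_je is not None


def junction_width(read_length: int = 80, min_flank: int = 11) -> int:
    """Number of read offsets that cross the junction with full flanks."""
    w = read_length - 2 * min_flank + 1
    if w < 1:
        raise ValueError("read_length too short for min_flank")
    return w


def estimate_rates(
    n_distinct: int,
    unique_gene_reads: int,
    gene_length: int,
    read_length: int = 80,
    min_flank: int = 11,
) -> tuple[float, float, float | None]:
    """Per-nucleotide junctional rate j, expression rate e, and j/e.

    j/e is None (undefined) when e == 0; the record is kept.
    """
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    w = junction_width(read_length, min_flank)
    j = n_distinct / w
    e = unique_gene_reads / gene_length
    ratio = j / e if e > 0 else None
    return j, e, ratio


def method1_fraction(
    n_scrambled_pairs: int,
    n_canonical_pairs_donor: int | None,
    n_canonical_pairs_acceptor: int | None,
) -> float:
    """Scrambled fraction n_scr / (n_scr + mean canonical support).

    The canonical support is the mean of the pair counts at the canonical
    junctions adjacent to the scramble on the donor and acceptor sides;
    a side with no such junction (None) falls back to the single
    available count.
    """
    counts = [c for c in (n_canonical_pairs_donor, n_canonical_pairs_acceptor) if c is not None]
    if any(c < 0 for c in counts) or n_scrambled_pairs < 0:
        raise ValueError("counts must be nonnegative")
    if not counts:
        canonical = 0.0
    else:
        canonical = sum(counts) / len(counts)
    if n_scrambled_pairs == 0 and canonical == 0:
        raise UndefinedFractionError("no scrambled or canonical pairs")
    return n_scrambled_pairs / (n_scrambled_pairs + canonical)


def assign_bin(fraction: float) -> str:
    """Fig-2-style abundance bin; right-open except the last."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction < 0.25:
        return ABUNDANCE_BINS[0]
    if fraction < 0.50:
        return ABUNDANCE_BINS[1]
    if fraction < 0.75:
        return ABUNDANCE_BINS[2]
    return ABUNDANCE_BINS[3]


def abundance_histogram(estimates: Iterable[AbundanceEstimate]) -> dict[str, int]:
    hist = {b: 0 for b in ABUNDANCE_BINS}
    for est in estimates:
        if est.fraction_method1 is not None:
            hist[assign_bin(est.fraction_method1)] += 1
    return hist


def detection_probability(e: float, w: int, threshold: int = 1) -> float:
    """P(at least ``threshold`` junctional reads) under a Poisson(e*w) model.

    e is the per-nucleotide expression rate of the (hypothetical) scrambled
    isoform and w the junction width, so e*w is the expected junctional
    read count.
    """
    if e < 0:
        raise ValueError("e must be nonnegative")
    if w < 1 or threshold < 1:
        raise ValueError("w and threshold must be >= 1")
    return float(stats.poisson.sf(threshold - 1, e * w))


def write_abundance_tsv(
    estimates: Sequence[AbundanceEstimate], path: str | Path, exon_base: int = 1
) -> None:
    shift = exon_base - 1
    with open(path, "w") as fh:
        fh.write("gene_id\tdonor_exon\tacceptor_exon\tj\te\tratio_je\tfraction_method1\tabundance_bin\n")
        for est in estimates:
            ratio = "NA" if est.ratio_je is None else f"{est.ratio_je:.6g}"
            frac = "NA" if est.fraction_method1 is None else f"{est.fraction_method1:.6g}"
            abin = est.abundance_bin or "NA"
            fh.write(
                f"{est.gene_id}\t{est.donor_index + shift}\t{est.acceptor_index + shift}\t"
                f"{est.j:.6g}\t{est.e:.6g}\t{ratio}\t{frac}\t{abin}\n"
            )


def write_histogram_tsv(hist: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("abundance_bin\tcount\n")
        for b in ABUNDANCE_BINS:
            fh.write(f"{b}\t{hist.get(b, 0)}\n")
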