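# Methods

`circkit` detects and quantifies scrambled-exon (circular) RNA isoforms
from paired-end RNA-seq, and ships a ground-truthed read simulator so the
whole pipeline can be exercised end to end without external data.

## The detection model

A *scrambled* junction joins a splice donor of exon X to the splice
acceptor of an upstream exon Y (X ≥ Y, indices 1-based in transcription
order).  Such junctions arise from two structures with distinct paired-end
signatures:

* **circular RNA** — exons Y..X covalently closed by a backsplice.  The
  mate of any read crossing the X→Y junction must come from inside the
  exon block Y..X.
* **tandem duplication on a linear transcript** — exons Y..X duplicated in
  canonical order.  The mate of a junction-crossing read may then fall
  upstream of Y or downstream of X whenever the fragment is longer than
  the duplicated block.

The pipeline stages are:

1. **Junction database.**  For every gene (one representative exon chain;
   see "Annotation handling"), all k² ordered exon pairs are enumerated,
   k(k+1)/2 of them scrambled (including self-joins X = Y).  Each junction
   record carries the last `read_length − min_flank` nt of the donor exon
   followed by the first `read_length − min_flank` nt of the acceptor exon
   (a shorter exon contributes its full length only, so junction sequences
   stay intragenic).
2. **Alignment.**  Mates are aligned independently to the spliced
   transcriptome allowing up to `max_mismatches` substitutions (default
   3), both orientations, all alignments reported.  Only mates that fail
   there are aligned to the junction database — this ordering is
   mandatory, since any read that fits a transcript contiguously is not
   junction-spanning evidence.  A read is *junctional* when it covers at
   least `min_flank` mismatch-free bases on each side of the breakpoint;
   `min_flank = 11` implements a strictly-more-than-10 rule.
3. **Mate classification and deduplication.**  For each unique junctional
   alignment to a scrambled record, the mate's unique transcript position
   classifies the pair: fully inside the block Y..X → circle-consistent;
   extending outside the block with ≥ `min_flank` mismatch-free bases
   beyond the boundary → linear evidence; otherwise ambiguous.  The
   mismatch-free requirement on the extension mirrors the junctional
   criterion and exists because a mate that itself crosses the backsplice
   by a few bases gets absorbed into the reference with terminal
   mismatches and would otherwise masquerade as linear evidence.  Support
   is counted as distinct (junction offset, mate offset, mismatch
   profiles) tuples, so PCR duplicates count once.
4. **Quantification.**  Two relative-abundance estimators are emitted side
   by side, since the analysis they implement is determinate only up to
   this choice:
   * **j/e** — the per-nucleotide junctional rate j = n_distinct / W
     against the per-nucleotide expression rate e = unique reads / mature
     gene length.  W = `read_length − 2·min_flank + 1` (59 for 80-bp
     reads) is the number of read offsets that can satisfy the junctional
     criterion; it is the denominator that makes j commensurate with e
     and scales all j/e output.
   * **method 1** — n_scr / (n_scr + canonical), where n_scr counts
     circle-consistent pairs and the canonical support is the mean pair
     count of the canonical junctions adjacent to the scramble *inside*
     the interval (X−1→X and Y→Y+1; flanking junctions for self-joins).
     Because the circle itself contains those canonical junctions, its
     reads inflate the denominator: method 1 is a documented
     underestimate.  Fractions are histogrammed into 0–25 / 25–50 /
     50–75 / 75+ % bins (right-open except the last).
   * A Poisson detection model P(≥ t junctional reads) = 1 − CDF(t−1; e·W)
     expresses how detectability falls with expression.
5. **Circularity statistic.**  From uniquely aligned, properly oriented
   pairs the empirical fragment-length CDF F is stored on a 0..100
   integer percentile grid and evaluated as a right-continuous step
   function at percentile resolution (no interpolation — the grid is the
   stored object, and smoothing would invent data).  For a junction with
   circle length L (sum of exon lengths Y..X) and n distinct junctional
   reads, the probability of seeing zero linear-evidence reads under the
   tandem hypothesis is p₀ = F(L)ⁿ.  Junctions with F(L) = 1 (circle
   beyond the sampled insert range) are reported untestable.  Genome-wide,
   the expected number of junctions with ≥ 1 linear-evidence read under
   universal linearity is reported both as the quantile-binned sum
   Σ_bins count·(1 − mean p₀) and the direct Σ(1 − p₀); the aggregation
   granularity is a free choice, so both are labeled and emitted.

   **Known approximation.**  p = 1 − F(L) treats the mate as the far
   endpoint of the fragment and ignores the junction's alignment offset
   within the read (0..W−1).  The plain p₀ is therefore conservative: the
   observed zero-evidence fraction sits at or above mean p₀.  An optional
   offset-averaged mode replaces F(L) with mean over offsets of F(L + o);
   it is off by default (the plain form is the standard statistic) but is
   the better-calibrated choice when comparing against simulation truth,
   and the calibration tests use it for the equality check while
   asserting the plain form's conservative direction.
6. **Window scan** (annotation-free cross-check).  Uniquely mapped pairs
   are binned by transcript position (200-bp bins).  Pairs whose
   forward-oriented mate lies downstream of the reverse-oriented mate
   (category 1) are geometrically impossible on a linear transcript and
   flag scrambling without any junction database; canonical inward-facing
   pairs are category 2.  Same-orientation pairs are discarded — an
   unstranded library gives no principled way to orient them.  The scan
   runs in transcript (spliced) coordinates: introns would dilute
   fixed-width bins.

## Cohort analyses

* **Poly-A enrichment.**  Circles lack poly-A tails.  Single-end reads
  from matched poly-A selected and depleted fractions are aligned directly
  to the junction database; unique junctional counts per fraction give a
  depleted/selected enrichment with pseudocount 1 on both counts (the
  pseudocount keeps zero-count junctions defined and is logged in the
  output).  Circle junctions are expected > 1, tandem junctions < 1.
* **Complementary splice search.**  If circles were by-products of exon
  skipping, the complementary forward junction (Y−1)→(X+1) should appear
  in the linear pool.  A complement is "supported" only above one read
  (strictly more than 1).  Frame preservation of the skipped block
  (length mod 3 = 0) is used as a proxy for the skip product escaping
  nonsense-mediated decay; full stop-codon/50-nt-rule modeling is out of
  scope.
* **Acceptor-position enrichment.**  Over-use of exon 2 as the circle
  acceptor is tested by permutation: each observed junction's acceptor is
  redrawn uniformly from its gene's eligible acceptor positions (2..k —
  exon 1 has no 3′ splice site), preserving per-gene junction counts;
  the p-value uses the +1 correction, so it lives in [1/(B+1), 1].  The
  uniform null is a modeling choice made here; no canonical null exists
  for this statistic.
* **Intron-length quantiles.**  For junction groups stratified by donor
  or acceptor exon index (≤ 9), the median length of each intron index
  among circle-producing genes is ranked (mean-rank quantile) within that
  intron's all-gene length distribution; strata under 3 genes are emitted
  as missing.

## The simulator

The generator emulates the study conditions the pipeline targets:
ribosomal-RNA-depleted, random-primed (unstranded), 80-bp paired-end
sequencing of fragmented RNA.

* Genes: by default 4–8 exons of 100–250 bp (typical human exons are
  ~150 bp) with 200–800 bp introns, random uniform base composition, one
  gene per synthetic chromosome, random strand.
* Isoform mixture per gene: linear at 1−φ−τ, circular at φ, tandem at τ
  (molecule fractions).  Circle/tandem spans draw the acceptor uniformly
  from eligible positions 2..k (optionally biased to exon 2 for
  enrichment fixtures) and the donor uniformly from Y..k (optionally
  bounded by `circle_span_range`).  Circular isoforms are never
  polyadenylated; linear and tandem always are.
* Fragments: trapezoidal length distribution — uniform 300–500 bp core
  with 100-bp linear ramps (support 200–600) — as a concrete reading of
  inserts of "roughly 300–500 bp" with "tails extending roughly 100 bp".
  Circular molecules are fragmented uniformly around the circle with
  length truncated at the circle length (a draw beyond L yields the
  full-length, single-cut molecule), so backsplice-crossing read pairs
  reproduce the circular paired-end geometry including wrap-around.
* Errors: i.i.d. substitutions at rate ε (default 0.001); constant
  Phred-40 qualities (quality-aware behavior is out of scope).
* Poly-A selection: fragments from polyadenylated molecules enter the
  selected fraction with probability s⁺ = 0.95 and otherwise flow
  through; non-polyadenylated fragments leak in with s⁻ = 0.05 — a leaky
  double selection.
* An off-by-default template-switch mode converts a configurable fraction
  of linear fragments into intra-transcript chimeras with uniformly
  random breakpoints, the artifact class whose exon-boundary coincidence
  rate is 1/len² (1/22500 for 150-bp exons).

What the simulator does **not** model: indels, GC or positional coverage
bias, PCR duplicates, paralogous gene families, alternative splicing
within a gene, expression heterogeneity between genes, and intron-derived
reads.  Passing tests therefore demonstrate the correctness of the
pipeline's logic and statistics under the stated generative model, not
robustness to every artifact of real libraries; in particular uniqueness
filtering is exercised only lightly because random sequences rarely
multi-map.

## Numerical and design choices

* Coordinates are 0-based half-open internally; exon indices are 1-based
  in transcription order in every report (a `--exon-base 0` flag shifts
  reported numbering for comparison with 0-based exon tables).
* Multi-transcript genes use one representative chain: most exons, ties
  by longest mature length, then lexicographic transcript id.  This is
  deterministic but blind to isoform-specific exons (a known limitation:
  scrambles involving exons absent from the representative chain are
  invisible).
* Uniqueness: an alignment is unique only if it is the strictly best
  scorer across all targets and offsets; ties at distinct offsets of one
  target also void uniqueness.  Only unique alignments contribute to
  expression, inserts, or junction evidence — conservative against
  paralog inflation.
* N bases never match.  Reads with characters outside ACGTN are rejected
  with a warning.
* The aligner is exact within its contract (all ungapped alignments with
  ≤ max_mismatches): seeds of k = 16 guarantee a clean seed for reads of
  length ≥ (max_mismatches+1)·k by pigeonhole; shorter reads fall back to
  a brute-force scan.  Gapped and spliced alignment are non-goals.
* Simulation sizes in the test suite (15–40 genes, 30–50× coverage) are
  chosen so each calibration has enough junctions for a 3-standard-error
  comparison while the whole suite stays fast enough to run routinely.

## Known limitations

* The p₀ statistic inherits the offset approximation described above;
  with the default plain mode it overstates the probability of linear
  evidence for circles near the upper edge of the insert distribution.
* Method-1 fractions are biased downward by construction and additionally
  lose numerator support for circles much smaller than the insert length
  (both reads of a fragment then cross the backsplice and the mate is
  unmappable).
* Trans-gene (fusion) junctions, de-novo exon discovery, and gapped
  alignment are out of scope; the junction database is strictly
  intragenic.
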