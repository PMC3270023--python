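"""Mismatch-tolerant ungapped short-read alignment.

Reads are mapped first to the spliced transcriptome; reads that fail there
are mapped to the exon-exon junction database.  The aligner is a
seed-and-extend scan over exact k-mer seeds (k=16, both strands) with full
Hamming verification: a read with at most ``max_mismatches`` substitutions
is guaranteed a clean seed whenever ``len(read) >= (max_mismatches+1)*k``
(pigeonhole); shorter reads fall back to a brute-force scan over all
offsets.  No gaps, no quality weighting — the contract is "all ungapped
alignments with at most N mismatches, on either strand".

An alignment is *unique* when it is the single best-scoring alignment of
its read across all targets and offsets.  N bases never match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .genome_model import reverse_complement

logger = logging.getLogger(__name__)

FORWARD = "F"
REVERSE = "R"

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class Alignment:
    read_id: str
    target_id: str
    offset: int
    orientation: str  # F: read as given; R: reverse-complement aligned
    mismatch_profile: tuple[tuple[int, str], ...]  # (position on oriented read, observed base)
    n_mismatches: int
    unique: bool = False
    read_length: int | None = None

    def with_unique(self, unique: bool) -> "Alignment":
        return Alignment(
            self.read_id,
            self.target_id,
            self.offset,
            self.orientation,
            self.mismatch_profile,
            self.n_mismatches,
            unique,
            self.read_length,
        )


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    mate1: str
    mate2: str

    def __post_init__(self) -> None:
        if not self.mate1 or not self.mate2:
            raise ValueError(f"read {self.read_id}: empty mate sequence")


def _mismatches(
    read: str, target: str, offset: int, max_mm: int
) -> tuple[tuple[int, str], ...] | None:
    """Mismatch profile of ``read`` vs ``target[offset:]`` or None if > max_mm.

    An N on either side counts as a mismatch.
    """
    profile: list[tuple[int, str]] = []
    segment = target[offset : offset + len(read)]
    if segment == read and "N" not in read:
        return ()
    for i, (r, t) in enumerate(zip(read, segment)):
        if r != t or r == "N":
            profile.append((i, r))
            if len(profile) > max_mm:
                return None
    return tuple(profile)


class Aligner:
    """Exact-seed index over a set of named target sequences."""

    def __init__(self, targets: Mapping[str, str], k: int = 16):
        self.targets = {name: seq.upper() for name, seq in targets.items()}
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.targets.items():
            for pos in range(0, len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((name, pos))
        self._index = index

    def _candidate_offsets(self, seq: str) -> set[tuple[str, int]]:
        k = self.k
        n = len(seq)
        seed_starts = list(range(0, n - k + 1, k))
        if seed_starts and seed_starts[-1] != n - k:
            seed_starts.append(n - k)
        candidates: set[tuple[str, int]] = set()
        for s in seed_starts:
            for name, pos in self._index.get(seq[s : s + k], ()):
                offset = pos - s
                if 0 <= offset <= len(self.targets[name]) - n:
                    candidates.add((name, offset))
        return candidates

    def align_read(self, read_id: str, seq: str, max_mismatches: int = 3) -> list[Alignment]:
        """All ungapped alignments of ``seq`` with <= max_mismatches.

        Returns an empty list for unalignable or invalid reads.  The
        ``unique`` flag is set on the single best alignment when it is
        strictly best.
        """
        seq = seq.upper()
        if not seq or set(seq) - _VALID:
            logger.warning("read %s contains non-ACGTN characters; rejected", read_id)
            return []
        out: list[Alignment] = []
        for orientation, oriented in ((FORWARD, seq), (REVERSE, reverse_complement(seq))):
            if len(oriented) < (max_mismatches + 1) * self.k:
                candidates = {
                    (name, off)
                    for name, target in self.targets.items()
                    for off in range(0, len(target) - len(oriented) + 1)
                }
            else:
                candidates = self._candidate_offsets(oriented)
            for name, offset in sorted(candidates):
                profile = _mismatches(oriented, self.targets[name], offset, max_mismatches)
                if profile is not None:
                    out.append(
                        Alignment(
                            read_id, name, offset, orientation, profile,
                            len(profile), read_length=len(oriented),
                        )
                    )
        if out:
            best = min(a.n_mismatches for a in out)
            best_hits = [i for i, a in enumerate(out) if a.n_mismatches == best]
            if len(best_hits) == 1:
                out[best_hits[0]] = out[best_hits[0]].with_unique(True)
        return out


def align_to_transcriptome(
    reads: Iterable[tuple[str, str]],
    targets: Mapping[str, str] | Aligner,
    max_mismatches: int = 3,
) -> tuple[dict[str, list[Alignment]], list[tuple[str, str]]]:
    """Align single reads to the transcriptome.

    Returns (alignments keyed by read id, unaligned (read_id, seq) list).
    """
    aligner = targets if isinstance(targets, Aligner) else Aligner(targets)
    aligned: dict[str, list[Alignment]] = {}
    unaligned: list[tuple[str, str]] = []
    for read_id, seq in reads:
        hits = aligner.align_read(read_id, seq, max_mismatches)
        if hits:
            aligned[read_id] = hits
        else:
            unaligned.append((read_id, seq))
    return aligned, unaligned


def align_to_junctions(
    unaligned: Iterable[tuple[str, str]],
    junctions,
    max_mismatches: int = 3,
    aligner: Aligner | None = None,
) -> dict[str, list[Alignment]]:
    """Align transcriptome-unaligned reads to the junction database.

    ``junctions`` is a collection of ExonJunction (or any objects with
    ``record_id``/``junction_seq``).  Reads longer than a junction sequence
    simply cannot align to that record.
    """
    if aligner is None:
        aligner = Aligner({j.record_id: j.junction_seq for j in junctions})
    aligned: dict[str, list[Alignment]] = {}
    max_target = max((len(t) for t in aligner.targets.values()), default=0)
    for read_id, seq in unaligned:
        if len(seq) > max_target:
            logger.warning(
                "read %s longer than every junction sequence; skipped", read_id
            )
            continue
        hits = aligner.align_read(read_id, seq, max_mismatches)
        if hits:
            aligned[read_id] = hits
    return aligned


def is_junctional(
    alignment: Alignment,
    breakpoint_offset: int,
    min_flank: int = 11,
    read_length: int | None = None,
) -> bool:
    """True iff the read crosses the junction with ``min_flank`` mismatch-free
    bases on each side of the breakpoint.

    ``read_length`` defaults to the length recorded on the alignment.
    """
    if read_length is None:
        read_length = alignment.read_length
    if read_length is None:
        raise ValueError("read_length is required")
    start = alignment.offset
    end = alignment.offset + read_length
    if breakpoint_offset - start < min_flank or end - breakpoint_offset < min_flank:
        return False
    lo = breakpoint_offset - min_flank
    hi = breakpoint_offset + min_flank
    for pos, _base in alignment.mismatch_profile:
        tpos = start + pos
        if lo <= tpos < hi:
            return False
    return True


# ---------------------------------------------------------------------------
# FASTQ I/O and TSV serialization
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    for (id1, seq1), (id2, seq2) in zip(read_fastq(path1), read_fastq(path2), strict=True):
        base1 = id1.rsplit("/", 1)[0]
        base2 = id2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"mate id mismatch: {id1} vs {id2}")
        yield ReadPair(base1, seq1, seq2)


def write_alignments_tsv(alignments: Iterable[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttarget_id\toffset\torientation\tn_mismatches\tmismatch_profile\tunique\n")
        for a in alignments:
            profile = ",".join(f"{p}:{b}" for p, b in a.mismatch_profile)
            fh.write(
                f"{a.read_id}\t{a.target_id}\t{a.offset}\t{a.orientation}\t"
                f"{a.n_mismatches}\t{profile}\t{int(a.unique)}\n"
            )
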