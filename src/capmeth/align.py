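"""Three-letter bisulfite read alignment on a desk-scale reference.

Reads are searched against two in-silico converted reference spaces — C->T
(the original-top / Watson-informative molecule) and G->A (the Crick
molecule, expressed on forward coordinates) — with a seeded exact-candidate
stage and full bisulfite-aware verification in the original base space.
Mismatch budgets follow short-read bisulfite practice: up to 2 mismatches in
the 30 bp seed and 5 in the whole read, where read-T over reference-C (CT
space) and read-A over reference-G (GA space) are conversion-consistent and
never counted. Candidate generation is exact for these budgets: the seed is
split into seed_max_mismatches + 1 chunks, one of which must match the
reduced-alphabet reference exactly (pigeonhole).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sequence import C, G, T, A, ct_convert, encode, ga_convert, revcomp
from .simulate import ReadPair, SimulatedLibrary, parse_read_name, ReferenceGenome

CT, GA = "CT", "GA"

logger = logging.getLogger(__name__)


@dataclass
class AlignerParams:
    seed_length: int = 30
    seed_max_mismatches: int = 2
    total_max_mismatches: int = 5
    max_gaps: int = 0  # gapped alignment disabled; gaps only rank ties
    max_insert: int = 1000

    def __post_init__(self) -> None:
        if self.seed_max_mismatches > self.total_max_mismatches:
            raise ValueError("seed_max_mismatches > total_max_mismatches")
        if self.seed_length < self.seed_max_mismatches + 1:
            raise ValueError("seed too short for its mismatch budget")
        if self.max_gaps != 0:
            raise NotImplementedError("gapped alignment is not supported")


@dataclass(frozen=True)
class Hit:
    """One candidate placement of a read."""

    chrom: str
    start: int
    strand: str  # orientation of the read on the forward reference
    space: str  # CT or GA
    mismatches: int
    gaps: int = 0


@dataclass
class AlignmentRecord:
    """A mate placed on the reference (forward coordinates)."""

    read_id: str
    chrom: str
    start: int
    strand: str
    space: str
    mismatches: int
    gaps: int
    mate: int  # 1 or 2
    seq: str  # as sequenced (read orientation)
    qual: str
    uniqueness: str = "unique"
    duplicate: bool = False
    dup_group: int = -1

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    @property
    def fragment_strand(self) -> str:
        """Source-molecule strand: CT space reads come from Watson."""
        return "+" if self.space == CT else "-"


@dataclass
class AlignedPair:
    """Joint placement decision for a read pair."""

    name: str
    r1: AlignmentRecord | None
    r2: AlignmentRecord | None
    paired: bool
    uniqueness: str  # unique | multi | unmapped
    duplicate: bool = False
    dup_group: int = -1

    @property
    def records(self) -> list[AlignmentRecord]:
        return [r for r in (self.r1, self.r2) if r is not None]

    @property
    def outer_span(self) -> tuple[str, int, int, str, str]:
        recs = self.records
        chrom = recs[0].chrom
        start = min(r.start for r in recs)
        end = max(r.end for r in recs)
        return chrom, start, end, recs[0].space, recs[0].fragment_strand


class ConvertedIndex:
    """Exact k-mer indexes of the two converted reference texts.

    Chunk length is seed_length // (seed_max_mismatches + 1); with the
    default 30/2 budget that is 10. The original sequence is retained for
    bisulfite-aware mismatch re-evaluation.
    """

    def __init__(self, genome: ReferenceGenome,
                 params: AlignerParams | None = None) -> None:
        if not genome.sequences:
            raise ValueError("empty genome")
        params = params or AlignerParams()
        self.params = params
        self.k = params.seed_length // (params.seed_max_mismatches + 1)
        self.genome = genome
        self.orig: dict[str, np.ndarray] = {}
        self.converted_text: dict[str, dict[str, str]] = {CT: {}, GA: {}}
        self._kmers: dict[str, dict[str, list[tuple[str, int]]]] = {
            CT: {}, GA: {}}
        for chrom, seq in genome.sequences.items():
            self.orig[chrom] = genome.codes(chrom)
            for space, text in ((CT, ct_convert(seq)), (GA, ga_convert(seq))):
                self.converted_text[space][chrom] = text
                table = self._kmers[space]
                k = self.k
                for i in range(len(text) - k + 1):
                    table.setdefault(text[i:i + k], []).append((chrom, i))

    def candidate_starts(self, space: str, chunk: str,
                         offset: int, read_len: int):
        """Read-start candidates implied by an exact chunk match."""
        for chrom, pos in self._kmers[space].get(chunk, ()):
            start = pos - offset
            if 0 <= start and start + read_len <= len(self.orig[chrom]):
                yield chrom, start


def _mismatch_profile(ref: np.ndarray, read: np.ndarray, space: str) -> np.ndarray:
    """Boolean per-base mismatch vector, bisulfite-aware in original space."""
    mm = ref != read
    if space == CT:
        mm &= ~((ref == C) & (read == T))
    else:
        mm &= ~((ref == G) & (read == A))
    return mm


def align_read(seq: str, index: ConvertedIndex,
               params: AlignerParams) -> list[Hit]:
    """All placements of one read satisfying the seed/total budgets."""
    L = len(seq)
    if L < params.seed_length:
        return []
    hits: dict[tuple, Hit] = {}
    rc = revcomp(seq)
    for space in (CT, GA):
        convert = ct_convert if space == CT else ga_convert
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else rc
            reduced = convert(oriented)
            codes = encode(oriented)
            # the seed is the first 30 bp of the READ; in reverse orientation
            # that is the trailing window of the oriented sequence
            seed_lo = 0 if strand == "+" else L - params.seed_length
            seed_hi = seed_lo + params.seed_length
            k = index.k
            n_chunks = params.seed_max_mismatches + 1
            seen: set[tuple[str, int]] = set()
            for ci in range(n_chunks):
                off = seed_lo + ci * k
                chunk = reduced[off:off + k]
                for chrom, start in index.candidate_starts(space, chunk, off, L):
                    if (chrom, start) in seen:
                        continue
                    seen.add((chrom, start))
                    ref = index.orig[chrom][start:start + L]
                    mm = _mismatch_profile(ref, codes, space)
                    total = int(mm.sum())
                    if total > params.total_max_mismatches:
                        continue
                    if int(mm[seed_lo:seed_hi].sum()) > params.seed_max_mismatches:
                        continue
                    key = (chrom, start, strand, space)
                    hits[key] = Hit(chrom, start, strand, space, total)
    return list(hits.values())


def align_pair(pair: ReadPair, index: ConvertedIndex,
               params: AlignerParams) -> tuple[list[Hit], list[Hit]]:
    """Candidate hit lists for both mates."""
    return (align_read(pair.seq1, index, params),
            align_read(pair.seq2, index, params))


def _record(pair: ReadPair, hit: Hit, mate: int,
            uniqueness: str) -> AlignmentRecord:
    seq = pair.seq1 if mate == 1 else pair.seq2
    qual = pair.qual1 if mate == 1 else pair.qual2
    return AlignmentRecord(f"{pair.name}/{mate}", hit.chrom, hit.start,
                           hit.strand, hit.space, hit.mismatches, hit.gaps,
                           mate, seq, qual, uniqueness)


def select_unique_best(pair: ReadPair, hits1: list[Hit], hits2: list[Hit],
                       params: AlignerParams) -> AlignedPair:
    """Rank joint placements: properly paired beats single-end, then fewer
    gaps+mismatches; 'unique' iff exactly one top-ranked location survives.

    A proper pair shares chromosome and conversion space, has opposite
    orientations with the '+' mate leftmost, and an outer span within
    max_insert. Mates pairing with inconsistent spaces are improper (a
    physical molecule has one informative space).
    """
    len1 = len(pair.seq1)
    proper: list[tuple[int, Hit, Hit]] = []
    for h1 in hits1:
        for h2 in hits2:
            if h1.chrom != h2.chrom or h1.space != h2.space:
                continue
            if h1.strand == h2.strand:
                continue
            plus, minus = (h1, h2) if h1.strand == "+" else (h2, h1)
            plus_len = len1 if plus is h1 else len(pair.seq2)
            minus_len = len1 if minus is h1 else len(pair.seq2)
            outer_start = min(plus.start, minus.start)
            outer_end = max(plus.start + plus_len, minus.start + minus_len)
            if plus.start > minus.start or outer_end - outer_start > params.max_insert:
                continue
            proper.append((h1.mismatches + h1.gaps + h2.mismatches + h2.gaps,
                           h1, h2))
    if proper:
        best = min(s for s, _, _ in proper)
        top = [(h1, h2) for s, h1, h2 in proper if s == best]
        if len(top) == 1:
            h1, h2 = top[0]
            return AlignedPair(pair.name, _record(pair, h1, 1, "unique"),
                               _record(pair, h2, 2, "unique"), True, "unique")
        h1, h2 = top[0]
        return AlignedPair(pair.name, _record(pair, h1, 1, "multi"),
                           _record(pair, h2, 2, "multi"), True, "multi")

    # single-end fallback: each mate on its own
    recs: list[AlignmentRecord | None] = [None, None]
    statuses = []
    for mate, hits in ((1, hits1), (2, hits2)):
        if not hits:
            statuses.append("unmapped")
            continue
        best = min(h.mismatches + h.gaps for h in hits)
        top = [h for h in hits if h.mismatches + h.gaps == best]
        status = "unique" if len(top) == 1 else "multi"
        recs[mate - 1] = _record(pair, top[0], mate, status)
        statuses.append(status)
    if all(s == "unmapped" for s in statuses):
        return AlignedPair(pair.name, None, None, False, "unmapped")
    # a pair is usable downstream only if every aligned mate is unique
    status = "multi" if "multi" in statuses else "unique"
    return AlignedPair(pair.name, recs[0], recs[1], False, status)


def align_library(pairs: list[ReadPair], index: ConvertedIndex,
                  params: AlignerParams | None = None) -> list[AlignedPair]:
    """Align and select every pair of a library."""
    params = params or index.params
    out = []
    n_short = 0
    for pair in pairs:
        if (len(pair.seq1) < params.seed_length
                or len(pair.seq2) < params.seed_length):
            n_short += 1
        h1, h2 = align_pair(pair, index, params)
        out.append(select_unique_best(pair, h1, h2, params))
    counts = {s: sum(p.uniqueness == s for p in out)
              for s in ("unique", "multi", "unmapped")}
    logger.info("aligned %d pairs: %d unique, %d multi, %d unmapped "
                "(%d with a mate shorter than the %d bp seed)", len(pairs),
                counts["unique"], counts["multi"], counts["unmapped"],
                n_short, params.seed_length)
    return out


@dataclass
class DedupResult:
    kept: list[AlignedPair]
    removed: int
    n_unique: int

    @property
    def duplication_rate(self) -> float:
        """Removed / uniquely aligned pairs, in [0, 1]."""
        return self.removed / self.n_unique if self.n_unique else 0.0


def deduplicate(aligned: list[AlignedPair]) -> DedupResult:
    """Collapse PCR duplicates among unique alignments.

    Group key: (chromosome, pair outer start, pair outer end, conversion
    space, fragment strand). Within a group the member with the fewest
    gaps+mismatches is kept; ties break by highest summed base quality, then
    lexicographically smallest read name (deterministic).
    """
    unique = [p for p in aligned if p.uniqueness == "unique"]
    groups: dict[tuple, list[AlignedPair]] = {}
    for p in unique:
        groups.setdefault(p.outer_span, []).append(p)
    kept: list[AlignedPair] = []
    for gid, (key, members) in enumerate(sorted(groups.items())):
        def rank(p: AlignedPair):
            mm = sum(r.mismatches + r.gaps for r in p.records)
            q = sum(ord(c) - 33 for r in p.records for c in r.qual)
            return (mm, -q, p.name)

        members.sort(key=rank)
        winner = members[0]
        winner.dup_group = gid
        winner.duplicate = False
        for r in winner.records:
            r.dup_group = gid
        kept.append(winner)
        for loser in members[1:]:
            loser.duplicate = True
            loser.dup_group = gid
            for r in loser.records:
                r.duplicate = True
                r.dup_group = gid
    kept.sort(key=lambda p: p.outer_span)
    return DedupResult(kept, removed=len(unique) - len(groups),
                       n_unique=len(unique))


def records_from_truth(library: SimulatedLibrary,
                       genome: ReferenceGenome) -> list[AlignedPair]:
    """Perfect alignments reconstructed from simulated read names.

    Used as the truth-placement oracle when testing downstream arithmetic
    independently of the aligner.
    """
    out = []
    for pair in library.pairs:
        chrom, start, end, strand, _frag, _copy = parse_read_name(pair.name)
        len1, len2 = len(pair.seq1), len(pair.seq2)
        if strand == "+":
            space = CT
            h1 = Hit(chrom, start, "+", space, 0)
            h2 = Hit(chrom, end - len2, "-", space, 0)
        else:
            space = GA
            h1 = Hit(chrom, end - len1, "-", space, 0)
            h2 = Hit(chrom, start, "+", space, 0)
        out.append(AlignedPair(pair.name, _record(pair, h1, 1, "unique"),
                               _record(pair, h2, 2, "unique"), True, "unique"))
    return out
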