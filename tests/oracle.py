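"""Independent brute-force oracles used by the test suite.

These deliberately share no code path with the package implementation: the
aligner oracle scans every reference position in both conversion spaces and
orientations with numpy sliding windows, and pair selection re-implements
the ranking rules from scratch.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from capmeth.sequence import encode, revcomp

A, C, G, T = 0, 1, 2, 3


def brute_force_hits(seq, genome, seed_length=30, seed_max_mismatches=2,
                     total_max_mismatches=5):
    """Every placement of a read satisfying the budgets, by exhaustive scan."""
    L = len(seq)
    if L < seed_length:
        return []
    hits = []
    for chrom, ref_seq in genome.sequences.items():
        ref = encode(ref_seq)
        if len(ref) < L:
            continue
        win = sliding_window_view(ref, L)
        for space in ("CT", "GA"):
            for strand in ("+", "-"):
                oriented = encode(seq if strand == "+" else revcomp(seq))
                mm = win != oriented[None, :]
                if space == "CT":
                    mm &= ~((win == C) & (oriented[None, :] == T))
                else:
                    mm &= ~((win == G) & (oriented[None, :] == A))
                seed_lo = 0 if strand == "+" else L - seed_length
                total = mm.sum(axis=1)
                seed_mm = mm[:, seed_lo:seed_lo + seed_length].sum(axis=1)
                ok = (total <= total_max_mismatches) & (
                    seed_mm <= seed_max_mismatches)
                for start in np.flatnonzero(ok):
                    hits.append((chrom, int(start), strand, space,
                                 int(total[start])))
    return hits


def brute_force_select(len1, len2, hits1, hits2, max_insert=1000):
    """Re-implementation of unique-best pair selection from scratch.

    Returns (status, placement) where placement is
    ((chrom, start1, strand1, mm1), (chrom, start2, strand2, mm2), space)
    for a unique proper pair, or per-mate tuples for single-end placements.
    """
    proper = []
    for h1 in hits1:
        for h2 in hits2:
            c1, s1, st1, sp1, m1 = h1
            c2, s2, st2, sp2, m2 = h2
            if c1 != c2 or sp1 != sp2 or st1 == st2:
                continue
            if st1 == "+":
                plus_start, minus_start = s1, s2
                ends = (s1 + len1, s2 + len2)
            else:
                plus_start, minus_start = s2, s1
                ends = (s2 + len2, s1 + len1)
            if plus_start > minus_start:
                continue
            outer = max(ends) - min(plus_start, minus_start)
            if outer > max_insert:
                continue
            proper.append((m1 + m2, h1, h2))
    if proper:
        best = min(p[0] for p in proper)
        top = [p for p in proper if p[0] == best]
        if len(top) == 1:
            _, h1, h2 = top[0]
            return "unique", (h1, h2)
        return "multi", None
    placements = []
    for hits in (hits1, hits2):
        if not hits:
            placements.append(("unmapped", None))
            continue
        best = min(h[4] for h in hits)
        top = [h for h in hits if h[4] == best]
        placements.append(("unique", top[0]) if len(top) == 1
                          else ("multi", None))
    statuses = [s for s, _ in placements]
    if all(s == "unmapped" for s in statuses):
        return "unmapped", None
    if "multi" in statuses:
        return "multi", None
    return "unique-single", tuple(placements)


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by direct enumeration with scipy's hypergeometric
    pmf (float path, independent of the package's rational arithmetic)."""
    from scipy.stats import hypergeom

    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())
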