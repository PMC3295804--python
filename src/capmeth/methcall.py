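"""Per-cytosine methylation calling with conversion-failure correction.

CT-space alignments inform Watson-strand cytosines (read C = methylated,
read T over a reference C = unmethylated); GA-space alignments symmetrically
inform Crick cytosines at forward-strand G positions (read G = methylated,
read A = unmethylated). The raw level is mC reads / (C reads + mC reads) in
percent. Because bisulfite conversion is incomplete, a single library-wide
non-conversion rate e is estimated from non-CpG cytosines — essentially
unmethylated in human somatic cells — and CpG levels are corrected by
background subtraction with renormalization:

    corrected = max(0, (raw - e) / (1 - e))

which leaves a truly-unmethylated site at 0 and is invertible for e < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignedPair, AlignmentRecord, CT
from .sequence import A as SEQ_A, C as SEQ_C, G as SEQ_G, T as SEQ_T
from .sequence import classify_context, encode, revcomp
from .simulate import ReferenceGenome

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated",
                "count_unmethylated", "depth", "raw_level", "corrected_level"]


class EstimationError(ValueError):
    """Raised when the non-conversion rate cannot be estimated."""


@dataclass(frozen=True)
class ConversionEstimate:
    """Pooled library-wide bisulfite non-conversion rate."""

    nonconversion_rate: float
    n_noncpg_sites: int
    n_noncpg_calls: int


def _flat_records(aligned) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    for item in aligned:
        if isinstance(item, AlignedPair):
            if item.uniqueness != "unique" or item.duplicate:
                continue
            records.extend(item.records)
        else:
            records.append(item)
    return records


def pileup(aligned, genome: ReferenceGenome,
           min_base_quality: int = 0) -> pd.DataFrame:
    """Strand-aware cytosine counts from unique, deduplicated alignments.

    Accepts AlignedPair or AlignmentRecord sequences; pairs that are
    non-unique or flagged duplicate are ignored. Read bases that are neither
    the methylated nor the converted letter at a reference cytosine, and
    bases below min_base_quality, do not contribute.
    """
    counts: dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        counts[chrom] = np.zeros((4, len(seq)), dtype=np.int64)
    for rec in _flat_records(aligned):
        seq = rec.seq if rec.strand == "+" else revcomp(rec.seq)
        qual = rec.qual if rec.strand == "+" else rec.qual[::-1]
        if rec.start < 0 or rec.end > len(genome.sequences[rec.chrom]):
            raise ValueError(
                f"alignment {rec.read_id} overhangs {rec.chrom}: "
                f"[{rec.start}, {rec.end})")
        table = counts[rec.chrom]
        ref = genome.codes(rec.chrom)[rec.start:rec.end]
        read = encode(seq)
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
        ok = q >= min_base_quality
        if rec.space == CT:
            site = (ref == SEQ_C) & ok
            meth_row, meth_code, unmeth_row, unmeth_code = 0, SEQ_C, 1, SEQ_T
        else:
            site = (ref == SEQ_G) & ok
            meth_row, meth_code, unmeth_row, unmeth_code = 2, SEQ_G, 3, SEQ_A
        # positions are unique within one read, so plain fancy indexing is safe
        table[meth_row, rec.start + np.flatnonzero(site & (read == meth_code))] += 1
        table[unmeth_row, rec.start + np.flatnonzero(site & (read == unmeth_code))] += 1
    rows_out = []
    for chrom, seq in genome.sequences.items():
        table = counts[chrom]
        for strand, (mi, ui) in (("+", (0, 1)), ("-", (2, 3))):
            covered = np.flatnonzero(table[mi] + table[ui])
            for p in covered:
                m, u = int(table[mi, p]), int(table[ui, p])
                rows_out.append((chrom, int(p), strand,
                                 classify_context(seq, int(p), strand),
                                 m, u, m + u, 100.0 * m / (m + u), np.nan))
    df = pd.DataFrame(rows_out, columns=CALL_COLUMNS)
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def estimate_nonconversion(calls: pd.DataFrame) -> ConversionEstimate:
    """Pooled non-conversion rate e from non-CpG cytosines (both strands)."""
    noncpg = calls[calls["context"] != "CpG"]
    depth = int(noncpg["depth"].sum())
    if depth == 0:
        raise EstimationError("no non-CpG coverage: cannot estimate the "
                              "non-conversion rate")
    meth = int(noncpg["count_methylated"].sum())
    return ConversionEstimate(meth / depth, len(noncpg), depth)


def estimate_nonconversion_spikein(calls: pd.DataFrame,
                                   carrier_chroms: set[str]) -> ConversionEstimate:
    """Alternative estimator from unmethylated carrier DNA (lambda spike-in):
    pooled over every cytosine on the carrier sequences."""
    carrier = calls[calls["chrom"].isin(carrier_chroms)]
    depth = int(carrier["depth"].sum())
    if depth == 0:
        raise EstimationError("no carrier coverage: cannot estimate the "
                              "non-conversion rate")
    meth = int(carrier["count_methylated"].sum())
    return ConversionEstimate(meth / depth, len(carrier), depth)


def correct_levels(calls: pd.DataFrame,
                   estimate: ConversionEstimate) -> pd.DataFrame:
    """Apply the non-conversion correction to CpG calls (non-CpG calls keep
    their raw levels). Returns a new frame; raw levels are retained."""
    e = estimate.nonconversion_rate
    if e >= 1.0:
        raise EstimationError("non-conversion rate is 1: degenerate library")
    out = calls.copy()
    raw = out["raw_level"] / 100.0
    corrected = np.maximum(0.0, (raw - e) / (1.0 - e)) * 100.0
    out["corrected_level"] = np.where(out["context"] == "CpG",
                                      corrected, out["raw_level"])
    return out
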