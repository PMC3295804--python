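"""Capture QC: mapping, enrichment, coverage, duplication, allele dropout.

On-target status for a pair is judged on its outer span (the sequenced
fragment), with >= 1 bp overlap against any capture target. Allele dropout
is assessed at planted heterozygous sites: conversion-confounded pairs
(C/T, A/G) are excluded, and a base observation only counts as allele
evidence when its identity is conversion-safe in the read's space — an
observed T in CT space may be a converted C and an observed A in GA space a
converted Crick-C, so those letters are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import CT, GA, AlignedPair, DedupResult
from .simulate import HetSite, ReferenceGenome, TargetSet, overlaps_target


@dataclass
class CaptureQcReport:
    raw_read_pairs: int
    unique_pairs: int
    unique_map_rate: float  # %
    duplication_rate: float  # %
    mean_target_depth: float  # x
    fraction_targets_covered: float  # % regions with >= 1 unique read
    fraction_targets_ge10: float  # % regions with >= min_region_reads reads
    on_target_rate: float  # % of unique pairs overlapping targets
    min_region_reads: int
    per_chromosome_strand_depth: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "raw_read_pairs": self.raw_read_pairs,
            "unique_pairs": self.unique_pairs,
            "unique_map_rate": self.unique_map_rate,
            "duplication_rate": self.duplication_rate,
            "mean_target_depth": self.mean_target_depth,
            "fraction_targets_covered": self.fraction_targets_covered,
            "fraction_targets_ge10": self.fraction_targets_ge10,
            "on_target_rate": self.on_target_rate,
            "min_region_reads": self.min_region_reads,
        }

    def to_text(self) -> str:
        lines = [
            f"raw read pairs            {self.raw_read_pairs}",
            f"uniquely aligned pairs    {self.unique_pairs}",
            f"unique map rate           {self.unique_map_rate:.2f}%",
            f"duplication rate          {self.duplication_rate:.2f}%",
            f"mean target depth         {self.mean_target_depth:.2f}x",
            f"targets covered (>=1)     {self.fraction_targets_covered:.2f}%",
            f"targets >= {self.min_region_reads} reads       "
            f"{self.fraction_targets_ge10:.2f}%",
            f"on-target rate            {self.on_target_rate:.2f}%",
        ]
        return "\n".join(lines) + "\n"


@dataclass
class DropoutReport:
    """Heterozygote recovery summary.

    dropout_rate = 100 * (n_truth_het - n_recovered_het) / n_truth_het;
    conversion-ambiguous sites are excluded before the denominator.
    """

    n_truth_het: int
    n_recovered_het: int
    excluded_ambiguous: int = 0

    @property
    def dropout_rate(self) -> float:
        if self.n_truth_het == 0:
            raise ValueError("no qualifying heterozygous truth sites")
        return 100.0 * (self.n_truth_het - self.n_recovered_het) / self.n_truth_het


def compute_capture_qc(dedup: DedupResult, targets: TargetSet,
                       raw_read_pairs: int, genome: ReferenceGenome,
                       min_region_reads: int = 10) -> CaptureQcReport:
    """QC statistics from deduplicated unique alignments.

    Depth is per-base unique-read depth over target bases; a region counts
    as covered when >= 1 unique read overlaps it by >= 1 bp.
    """
    if len(targets) == 0:
        raise ValueError("empty target set")
    index = targets.overlap_index()
    depth = {c: np.zeros((2, len(s)), dtype=np.int64)
             for c, s in genome.sequences.items()}
    region_reads = np.zeros(len(targets), dtype=np.int64)
    regions = targets.regions
    rstarts = {c: sub["start"].to_numpy()
               for c, sub in regions.groupby("chrom")}
    ridx = {c: sub.index.to_numpy() for c, sub in regions.groupby("chrom")}
    rends = {c: sub["end"].to_numpy() for c, sub in regions.groupby("chrom")}

    n_on_target = 0
    for pair in dedup.kept:
        chrom, ostart, oend, space, _strand = pair.outer_span
        if overlaps_target(index, chrom, ostart, oend):
            n_on_target += 1
        row = 0 if space == CT else 1
        for rec in pair.records:
            depth[rec.chrom][row, rec.start:rec.end] += 1
            if rec.chrom in rstarts:
                s, e = rstarts[rec.chrom], rends[rec.chrom]
                hit = (s < rec.end) & (e > rec.start)
                region_reads[ridx[rec.chrom][hit]] += 1

    span = targets.total_span
    total_depth = 0
    chrom_rows = []
    for chrom in genome.chrom_names:
        mask = np.zeros(len(genome.sequences[chrom]), dtype=bool)
        sub = regions[regions["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            mask[s:e] = True
        chrom_span = int(mask.sum())
        w = int(depth[chrom][0, mask].sum())
        c = int(depth[chrom][1, mask].sum())
        total_depth += w + c
        if chrom_span:
            chrom_rows.append((chrom, chrom_span, w / chrom_span,
                               c / chrom_span))
    per_chrom = pd.DataFrame(chrom_rows, columns=["chrom", "target_span",
                                                  "watson_depth",
                                                  "crick_depth"])
    n_unique = dedup.n_unique
    n_kept = len(dedup.kept)
    return CaptureQcReport(
        raw_read_pairs=raw_read_pairs,
        unique_pairs=n_unique,
        unique_map_rate=100.0 * n_unique / raw_read_pairs if raw_read_pairs else 0.0,
        duplication_rate=100.0 * dedup.duplication_rate,
        mean_target_depth=total_depth / span,
        fraction_targets_covered=100.0 * float((region_reads >= 1).mean()),
        fraction_targets_ge10=100.0 * float(
            (region_reads >= min_region_reads).mean()),
        on_target_rate=100.0 * n_on_target / n_kept if n_kept else 0.0,
        min_region_reads=min_region_reads,
        per_chromosome_strand_depth=per_chrom,
    )


def _conversion_safe(base: str, space: str) -> bool:
    if space == CT:
        return base != "T"
    return base != "A"


def assess_allele_dropout(het_sites: list[HetSite], kept: list[AlignedPair],
                          genome: ReferenceGenome, min_depth: int = 10,
                          min_allele_reads: int = 2,
                          min_base_quality: int = 0) -> DropoutReport:
    """Allele-dropout rate from deduplicated alignments at known het sites.

    A truth site qualifies when it is conversion-unambiguous and its total
    read depth is strictly greater than min_depth (depths "of more than"
    the threshold). It is recovered when both alleles are seen with at least
    min_allele_reads conversion-safe observations each.
    """
    from .sequence import revcomp

    informative = [h for h in het_sites if not h.bisulfite_ambiguous]
    excluded = len(het_sites) - len(informative)
    positions: dict[str, np.ndarray] = {}
    site_of: dict[tuple[str, int], int] = {}
    for i, h in enumerate(informative):
        site_of[(h.chrom, h.pos)] = i
    for chrom in genome.chrom_names:
        positions[chrom] = np.array(sorted(
            p for (c, p) in site_of if c == chrom), dtype=np.int64)

    depth = np.zeros(len(informative), dtype=np.int64)
    evidence: list[dict[str, int]] = [dict() for _ in informative]
    for pair in kept:
        for rec in pair.records:
            pos_arr = positions.get(rec.chrom)
            if pos_arr is None or len(pos_arr) == 0:
                continue
            lo = np.searchsorted(pos_arr, rec.start)
            hi = np.searchsorted(pos_arr, rec.end)
            if lo == hi:
                continue
            seq = rec.seq if rec.strand == "+" else revcomp(rec.seq)
            qual = rec.qual if rec.strand == "+" else rec.qual[::-1]
            for p in pos_arr[lo:hi]:
                off = int(p) - rec.start
                if ord(qual[off]) - 33 < min_base_quality:
                    continue
                i = site_of[(rec.chrom, int(p))]
                depth[i] += 1
                base = seq[off]
                if _conversion_safe(base, rec.space):
                    evidence[i][base] = evidence[i].get(base, 0) + 1

    qualifying = [i for i in range(len(informative)) if depth[i] > min_depth]
    if not qualifying:
        raise ValueError("no qualifying heterozygous truth sites "
                         f"(depth > {min_depth})")
    recovered = 0
    for i in qualifying:
        h = informative[i]
        if (evidence[i].get(h.ref, 0) >= min_allele_reads
                and evidence[i].get(h.alt, 0) >= min_allele_reads):
            recovered += 1
    return DropoutReport(len(qualifying), recovered, excluded)
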