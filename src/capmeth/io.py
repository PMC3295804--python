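"""File-format dialects: FASTA, FASTQ, BED, SAM-subset, TSV reports.

Coordinates are 0-based half-open in every tab-separated dialect; SAM POS is
1-based per the SAM convention. Every writer's output is accepted by its
reader (round-trip property) and writers are byte-stable for fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import CT, AlignedPair, AlignmentRecord
from .sequence import revcomp
from .simulate import (GeneModel, HetSite, ReadPair, ReferenceGenome,
                       TargetSet)


class ParseError(ValueError):
    """Malformed record, with the offending line number in the message."""


# --------------------------------------------------------------------- FASTA

def write_fasta(genome: ReferenceGenome, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> ReferenceGenome:
    sequences = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(str(path), "fasta")}
    if not sequences:
        raise ParseError(f"{path}: no FASTA records")
    return ReferenceGenome(sequences)


# --------------------------------------------------------------------- FASTQ

def write_fastq_pairs(pairs: list[ReadPair], path1, path2) -> None:
    """Paired FASTQ, phred+33; mate suffixes /1 and /2."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    out = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2, strict=True):
        name = r1.id.removesuffix("/1")
        if r2.id.removesuffix("/2") != name:
            raise ParseError(f"mate names disagree: {r1.id} vs {r2.id}")
        q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        out.append(ReadPair(name, str(r1.seq), str(r2.seq), q1, q2))
    return out


# ----------------------------------------------------------------------- BED

def write_bed(targets: TargetSet, path) -> None:
    targets.regions.to_csv(path, sep="\t", header=False, index=False,
                           columns=["chrom", "start", "end", "region_id"])


def read_bed(path) -> TargetSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else f"region_{len(rows):05d}"
            rows.append((fields[0], start, end, name))
    if not rows:
        raise ParseError(f"{path}: no BED intervals")
    return TargetSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                 "region_id"]))


# ----------------------------------------------------------------- het sites

def write_het_tsv(sites: list[HetSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n")


def read_het_tsv(path) -> list[HetSite]:
    df = pd.read_csv(path, sep="\t")
    return [HetSite(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df.itertuples()]


# --------------------------------------------------------------- gene models

def write_genes_tsv(genes: list[GeneModel], path) -> None:
    """Minimal gene-model dialect: name, chrom, strand, comma-joined exon
    starts and ends (0-based half-open, genomic order)."""
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstrand\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{starts}\t{ends}\n")


def read_genes_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for r in df.itertuples():
        starts = [int(x) for x in r.exon_starts.split(",")]
        ends = [int(x) for x in r.exon_ends.split(",")]
        genes.append(GeneModel(r.name, r.chrom, r.strand,
                               tuple(zip(starts, ends))))
    return genes


# ------------------------------------------------------------ cytosine calls

def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(calls: pd.DataFrame, path) -> None:
    """Corrected CpG levels as bedGraph (one 1 bp interval per cytosine)."""
    cpg = calls[calls["context"] == "CpG"]
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="corrected_cpg_methylation"\n')
        for r in cpg.itertuples():
            level = r.corrected_level
            if level is None or (isinstance(level, float) and np.isnan(level)):
                level = r.raw_level
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{level:.6g}\n")


# --------------------------------------------------------------- alignments

_ALN_COLUMNS = ["name", "mate", "chrom", "start", "strand", "space",
                "mismatches", "gaps", "paired", "uniqueness", "duplicate",
                "dup_group", "seq", "qual"]


def write_alignments_tsv(aligned: list[AlignedPair], path) -> None:
    rows = []
    for p in aligned:
        for rec in p.records:
            rows.append((p.name, rec.mate, rec.chrom, rec.start, rec.strand,
                         rec.space, rec.mismatches, rec.gaps, int(p.paired),
                         p.uniqueness, int(p.duplicate), p.dup_group,
                         rec.seq, rec.qual))
    pd.DataFrame(rows, columns=_ALN_COLUMNS).to_csv(path, sep="\t",
                                                    index=False)


def read_alignments_tsv(path) -> list[AlignedPair]:
    df = pd.read_csv(path, sep="\t")
    pairs: dict[str, AlignedPair] = {}
    for r in df.itertuples():
        rec = AlignmentRecord(f"{r.name}/{r.mate}", r.chrom, int(r.start),
                              r.strand, r.space, int(r.mismatches),
                              int(r.gaps), int(r.mate), r.seq, r.qual,
                              r.uniqueness, bool(r.duplicate),
                              int(r.dup_group))
        if r.name not in pairs:
            pairs[r.name] = AlignedPair(r.name, None, None, bool(r.paired),
                                        r.uniqueness, bool(r.duplicate),
                                        int(r.dup_group))
        pair = pairs[r.name]
        if rec.mate == 1:
            pair.r1 = rec
        else:
            pair.r2 = rec
    return list(pairs.values())


def write_sam(aligned: list[AlignedPair], genome: ReferenceGenome,
              path) -> None:
    """Minimal SAM: mapped records only, with ZS (conversion space), NM
    (bisulfite-aware mismatches) and ZD (duplicate group) tags."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in genome.sequences.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for p in aligned:
            recs = p.records
            if not recs:
                continue
            for rec in recs:
                other = next((r for r in recs if r is not rec), None)
                flag = 0x1
                if p.paired:
                    flag |= 0x2
                if rec.strand == "-":
                    flag |= 0x10
                if other is not None and other.strand == "-":
                    flag |= 0x20
                flag |= 0x40 if rec.mate == 1 else 0x80
                if p.duplicate:
                    flag |= 0x400
                seq = rec.seq if rec.strand == "+" else revcomp(rec.seq)
                qual = rec.qual if rec.strand == "+" else rec.qual[::-1]
                rnext = "=" if other is not None else "*"
                pnext = other.start + 1 if other is not None else 0
                if p.paired and other is not None:
                    ostart = min(rec.start, other.start)
                    oend = max(rec.end, other.end)
                    tlen = oend - ostart
                    if rec.start > other.start or (
                            rec.start == other.start and rec.strand == "-"):
                        tlen = -tlen
                else:
                    tlen = 0
                mapq = 30 if p.uniqueness == "unique" else 0
                fh.write(f"{p.name}\t{flag}\t{rec.chrom}\t{rec.start + 1}\t"
                         f"{mapq}\t{len(rec.seq)}M\t{rnext}\t{pnext}\t{tlen}\t"
                         f"{seq}\t{qual}\tZS:Z:{rec.space}\t"
                         f"NM:i:{rec.mismatches}\tZD:i:{rec.dup_group}\n")


# ------------------------------------------------------------------- reports

def write_keyvalue(data: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in data.items():
            fh.write(f"{k}\t{v}\n")


def write_json(data: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
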