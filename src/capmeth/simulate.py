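"""Synthetic data for a hybrid-capture bisulfite sequencing experiment.

The generator emulates the statistical structure of a captured bisulfite
library: a small reference with CpG-dense islands, a bimodal CpG truth
methylome with symmetric Watson/Crick levels, capture-target regions,
planted heterozygous SNPs, and paired-end reads that pass through fragment
capture, per-molecule bisulfite conversion, PCR duplication and sequencing
error. Every read name carries its truth origin
(``sim:<chrom>:<start>:<end>:<strand>:<fragment>:<copy>``) so downstream
tests can join calls back to the truth without side files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence import classify_context, encode, revcomp

_BASES = np.array(list("ACGT"))

# Allele pairs indistinguishable from bisulfite conversion itself.
_AMBIGUOUS_PAIRS = frozenset({frozenset("CT"), frozenset("AG")})


class PlacementError(ValueError):
    """Raised when disjoint intervals cannot be placed on the genome."""


@dataclass
class ReferenceGenome:
    """Named chromosomes plus a precomputed CpG-position index.

    ``cpg_positions[chrom]`` lists forward-strand positions p with C at p and
    G at p+1; the Crick member of the pair sits at p+1.
    """

    sequences: dict[str, str]
    cpg_positions: dict[str, np.ndarray] = field(init=False)
    _codes: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.cpg_positions = {}
        self._codes = {}
        for name, seq in self.sequences.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_c = arr == ord("C")
            is_g = arr == ord("G")
            self.cpg_positions[name] = np.flatnonzero(is_c[:-1] & is_g[1:])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def codes(self, chrom: str) -> np.ndarray:
        """uint8 encoding of a chromosome, cached."""
        if chrom not in self._codes:
            self._codes[chrom] = encode(self.sequences[chrom])
        return self._codes[chrom]


@dataclass
class TrueMethylome:
    """Per-cytosine true methylation probabilities on both strands.

    ``watson_levels[chrom][p]`` is the true level of the forward-strand C at
    p (NaN where there is no C); ``crick_levels`` likewise for reverse-strand
    cytosines (forward-strand G positions). CpG pairs share one level on both
    strands (symmetric CpG methylation assumed).
    """

    watson_levels: dict[str, np.ndarray]
    crick_levels: dict[str, np.ndarray]

    def level(self, chrom: str, pos: int, strand: str) -> float:
        arr = self.watson_levels if strand == "+" else self.crick_levels
        return float(arr[chrom][pos])

    def to_table(self, genome: ReferenceGenome) -> pd.DataFrame:
        """Long-format truth table: chrom, pos, strand, context, true_level."""
        rows = []
        for chrom, seq in genome.sequences.items():
            for strand, levels in (("+", self.watson_levels[chrom]),
                                   ("-", self.crick_levels[chrom])):
                positions = np.flatnonzero(~np.isnan(levels))
                for p in positions:
                    rows.append((chrom, int(p), strand,
                                 classify_context(seq, int(p), strand),
                                 float(levels[p])))
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                           "true_level"])


@dataclass
class TargetSet:
    """Sorted, non-overlapping capture-target regions (0-based half-open)."""

    regions: pd.DataFrame  # chrom, start, end, region_id

    def __post_init__(self) -> None:
        df = self.regions.sort_values(["chrom", "start"]).reset_index(drop=True)
        for _, sub in df.groupby("chrom"):
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValueError("target regions overlap within a chromosome")
        if (df["end"] <= df["start"]).any():
            raise ValueError("every region must have length >= 1")
        self.regions = df

    @property
    def total_span(self) -> int:
        return int((self.regions["end"] - self.regions["start"]).sum())

    def __len__(self) -> int:
        return len(self.regions)

    def overlap_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per chromosome: (region starts, running max of region ends)."""
        out = {}
        for chrom, sub in self.regions.groupby("chrom"):
            starts = sub["start"].to_numpy()
            out[chrom] = (starts, np.maximum.accumulate(sub["end"].to_numpy()))
        return out


def overlaps_target(index, chrom: str, start: int, end: int) -> bool:
    """>=1 bp overlap between [start, end) and any region of the index."""
    if chrom not in index:
        return False
    starts, cummax_ends = index[chrom]
    i = np.searchsorted(starts, end)  # regions starting before `end`
    return i > 0 and cummax_ends[i - 1] > start


@dataclass(frozen=True)
class HetSite:
    """A planted heterozygous SNP; ref/alt are forward-strand alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def bisulfite_ambiguous(self) -> bool:
        """True iff the allele pair is confounded with bisulfite conversion
        (C/T or A/G in either order)."""
        return frozenset((self.ref, self.alt)) in _AMBIGUOUS_PAIRS


@dataclass
class SimParams:
    """Library-simulation parameters.

    conversion_rate is the probability an unmethylated cytosine reads as T;
    inappropriate_conversion_rate the probability a methylated cytosine does.
    pcr_duplicate_mean is the mean number of sequenced copies per captured
    molecule (>= 1); copies are 1 + Poisson(mean - 1).
    strand_mode "both" samples the source strand 50/50;
    "watson-informative-only" emits only original-top-strand molecules.
    """

    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    read_length: int = 90
    n_fragments: int = 20000
    conversion_rate: float = 0.99
    inappropriate_conversion_rate: float = 0.0
    sequencing_error_rate: float = 0.001
    on_target_capture_prob: float = 0.8
    off_target_capture_prob: float = 0.08
    pcr_duplicate_mean: float = 1.67
    base_quality: int = 40
    strand_mode: str = "both"
    record_conversion_events: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "inappropriate_conversion_rate",
                     "sequencing_error_rate", "on_target_capture_prob",
                     "off_target_capture_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pcr_duplicate_mean < 1.0:
            raise ValueError("pcr_duplicate_mean must be >= 1")
        if self.read_length < 1 or self.n_fragments < 0:
            raise ValueError("read_length >= 1 and n_fragments >= 0 required")
        if self.strand_mode not in ("both", "watson-informative-only"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str


@dataclass
class SimulatedLibrary:
    """Reads plus the truth tables the simulator guarantees about them."""

    pairs: list[ReadPair]
    fragments: pd.DataFrame  # fragment_id chrom start end strand on_target n_copies
    conversion_events: pd.DataFrame | None
    params: SimParams
    n_attempted: int


def parse_read_name(name: str) -> tuple[str, int, int, str, int, int]:
    """Decode a simulated read name into (chrom, start, end, strand,
    fragment_id, copy)."""
    tag, chrom, start, end, strand, frag, copy = name.split(":")
    if tag != "sim":
        raise ValueError(f"not a simulated read name: {name!r}")
    return chrom, int(start), int(end), strand, int(frag), int(copy)


# ---------------------------------------------------------------------------
# generators


def generate_genome(n_chroms: int, chrom_length: int, gc_fraction: float,
                    cpg_island_spec: dict | None = None,
                    seed: int = 0) -> ReferenceGenome:
    """Random reference with optional CpG-dense islands.

    Background bases are i.i.d. with P(C)=P(G)=gc_fraction/2. Islands, given
    as ``{"n_per_chrom": int, "length": int, "cpg_fraction": float}``, are
    rewritten by a process that emits the dinucleotide CG with probability
    cpg_fraction per step, which concentrates CpGs far above background.
    """
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    sequences: dict[str, str] = {}
    for i in range(n_chroms):
        bases = rng.choice(_BASES, size=chrom_length, p=p)
        if cpg_island_spec:
            n_isl = int(cpg_island_spec["n_per_chrom"])
            isl_len = int(cpg_island_spec["length"])
            cpg_fr = float(cpg_island_spec["cpg_fraction"])
            for _ in range(n_isl):
                s = int(rng.integers(0, chrom_length - isl_len))
                island = []
                while len(island) < isl_len:
                    if rng.random() < cpg_fr:
                        island.extend("CG")
                    else:
                        island.append(str(rng.choice(_BASES, p=p)))
                bases[s:s + isl_len] = island[:isl_len]
        sequences[f"chr{i + 1}"] = "".join(bases)
    return ReferenceGenome(sequences)


def generate_methylome(genome: ReferenceGenome,
                       cpg_beta_high: tuple[float, float] = (10.0, 1.0),
                       cpg_beta_low: tuple[float, float] = (1.0, 20.0),
                       p_high: float = 0.7,
                       noncpg_level: float = 0.0,
                       seed: int = 0) -> TrueMethylome:
    """Bimodal CpG truth levels; constant (near-zero) non-CpG levels.

    Each CpG pair draws one level from the two-component Beta mixture and
    both strand cytosines of the pair carry it (symmetric methylation). All
    non-CpG cytosines get exactly ``noncpg_level``.
    """
    if not 0.0 <= p_high <= 1.0:
        raise ValueError("p_high must be in [0, 1]")
    if not 0.0 <= noncpg_level <= 1.0:
        raise ValueError("noncpg_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    watson: dict[str, np.ndarray] = {}
    crick: dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        w = np.full(len(seq), np.nan)
        c = np.full(len(seq), np.nan)
        w[arr == ord("C")] = noncpg_level
        c[arr == ord("G")] = noncpg_level
        cpg = genome.cpg_positions[chrom]
        if len(cpg):
            hi = rng.random(len(cpg)) < p_high
            levels = np.where(hi,
                              rng.beta(*cpg_beta_high, size=len(cpg)),
                              rng.beta(*cpg_beta_low, size=len(cpg)))
            w[cpg] = levels
            c[cpg + 1] = levels
        watson[chrom] = w
        crick[chrom] = c
    return TrueMethylome(watson, crick)


def define_targets(genome: ReferenceGenome, n_regions: int,
                   min_len: int, max_len: int, seed: int = 0) -> TargetSet:
    """Uniformly placed disjoint capture targets."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if max_len < min_len or min_len < 1:
        raise ValueError("need 1 <= min_len <= max_len")
    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    attempts = 0
    while len(rows) < n_regions:
        attempts += 1
        if attempts > 200 * n_regions:
            raise PlacementError(
                f"could not place {n_regions} disjoint regions "
                f"({len(rows)} placed after {attempts} attempts)")
        chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        length = int(rng.integers(min_len, max_len + 1))
        cl = len(genome.sequences[chrom])
        if length > cl:
            continue
        s = int(rng.integers(0, cl - length + 1))
        e = s + length
        if any(s < pe and e > ps for ps, pe in placed[chrom]):
            continue
        placed[chrom].append((s, e))
        rows.append((chrom, s, e))
    rows.sort()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["region_id"] = [f"region_{i:05d}" for i in range(len(df))]
    return TargetSet(df)


def plant_het_sites(genome: ReferenceGenome, density: float,
                    include_ambiguous: bool = True,
                    seed: int = 0) -> list[HetSite]:
    """Plant heterozygous SNPs at Bernoulli(density) per reference base.

    The alternate allele is drawn uniformly from the three non-reference
    bases (restricted to conversion-unambiguous pairs when
    include_ambiguous is False).
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sites: list[HetSite] = []
    for chrom, seq in genome.sequences.items():
        hits = np.flatnonzero(rng.random(len(seq)) < density)
        for pos in hits:
            ref = seq[pos]
            if ref not in "ACGT":
                continue
            alts = [b for b in "ACGT" if b != ref]
            if not include_ambiguous:
                alts = [b for b in alts
                        if frozenset((ref, b)) not in _AMBIGUOUS_PAIRS]
            alt = alts[int(rng.integers(len(alts)))]
            sites.append(HetSite(chrom, int(pos), ref, alt))
    return sites


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model for metagene profiling: ordered genomic exons."""

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by genomic start

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tts(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]


def define_genes(genome: ReferenceGenome, n_genes: int,
                 n_exons: tuple[int, int] = (3, 6),
                 exon_len: tuple[int, int] = (150, 400),
                 intron_len: tuple[int, int] = (200, 800),
                 flank: int = 2000, seed: int = 0) -> list[GeneModel]:
    """Toy gene models with disjoint footprints, 2 kb clear of chrom ends."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    chroms = genome.chrom_names
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 500 * n_genes:
            raise PlacementError(f"could not place {n_genes} disjoint genes")
        chrom = chroms[int(rng.integers(len(chroms)))]
        k = int(rng.integers(n_exons[0], n_exons[1] + 1))
        exlens = rng.integers(exon_len[0], exon_len[1] + 1, size=k)
        inlens = rng.integers(intron_len[0], intron_len[1] + 1, size=k - 1)
        span = int(exlens.sum() + inlens.sum())
        cl = len(genome.sequences[chrom])
        if cl < span + 2 * flank + 2:
            continue
        s = int(rng.integers(flank, cl - span - flank))
        e = s + span
        if any(s - flank < pe and e + flank > ps for ps, pe in occupied[chrom]):
            continue
        exons = []
        pos = s
        for i in range(k):
            exons.append((pos, pos + int(exlens[i])))
            pos += int(exlens[i]) + (int(inlens[i]) if i < k - 1 else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        occupied[chrom].append((s, e))
        genes.append(GeneModel(f"gene_{len(genes):04d}", chrom, strand,
                               tuple(exons)))
    return genes


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(seq: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[int(rng.integers(3))]
    return seq


def simulate_reads(genome: ReferenceGenome, methylome: TrueMethylome,
                   targets: TargetSet, het_sites: list[HetSite],
                   params: SimParams) -> SimulatedLibrary:
    """Simulate a captured bisulfite paired-end library.

    Per attempted fragment: (1) draw a Normal(fragment_mean, fragment_sd)
    length (redrawn until >= 1) and a uniform placement; (2) retain with
    on_target_capture_prob if it overlaps a target by >= 1 bp, else
    off_target_capture_prob; (3) pick a source strand; (4) convert each
    source-strand cytosine independently — the molecule's methylation state
    is Bernoulli(true_level), unmethylated Cs read T with conversion_rate,
    methylated Cs with inappropriate_conversion_rate; the read base arising
    from the opposite strand's C (a G on this strand) is untouched;
    (5) sequence 1 + Poisson(pcr_duplicate_mean - 1) copies; (6) emit
    read_length-bp mates (mate 2 is the reverse complement of the fragment
    end) with per-base substitution errors per copy.
    """
    rng = np.random.default_rng(params.seed)
    index = targets.overlap_index()
    chroms = genome.chrom_names
    clens = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    het_by_chrom: dict[str, dict[int, tuple[str, str]]] = {}
    for h in het_sites:
        het_by_chrom.setdefault(h.chrom, {})[h.pos] = (h.ref, h.alt)

    qual_char = chr(params.base_quality + 33)
    pairs: list[ReadPair] = []
    frag_rows = []
    event_rows = [] if params.record_conversion_events else None
    rl = params.read_length

    for frag_id in range(params.n_fragments):
        # fragment length and placement
        while True:
            flen = int(round(rng.normal(params.fragment_mean, params.fragment_sd)))
            if flen >= 1:
                break
        chrom = chroms[int(rng.choice(len(chroms), p=clens / clens.sum()))]
        cl = len(genome.sequences[chrom])
        if flen > cl:
            flen = cl
        start = int(rng.integers(0, cl - flen + 1))
        end = start + flen

        on_target = overlaps_target(index, chrom, start, end)
        keep_p = (params.on_target_capture_prob if on_target
                  else params.off_target_capture_prob)
        if rng.random() >= keep_p:
            continue

        if params.strand_mode == "watson-informative-only":
            strand = "+"
        else:
            strand = "+" if rng.random() < 0.5 else "-"

        frag = np.array(list(genome.sequences[chrom][start:end]))
        # heterozygous sites: one allele per molecule
        chrom_hets = het_by_chrom.get(chrom)
        if chrom_hets:
            for pos in range(start, end):
                if pos in chrom_hets:
                    ref, alt = chrom_hets[pos]
                    frag[pos - start] = ref if rng.random() < 0.5 else alt

        # orient to the source strand
        if strand == "-":
            mol = np.array(list(revcomp("".join(frag))))
        else:
            mol = frag

        # bisulfite conversion of the source strand's cytosines
        c_idx = np.flatnonzero(mol == "C")
        if len(c_idx):
            if strand == "+":
                gpos = start + c_idx
                levels = methylome.watson_levels[chrom][gpos]
            else:
                gpos = end - 1 - c_idx
                levels = methylome.crick_levels[chrom][gpos]
            levels = np.nan_to_num(levels, nan=0.0)  # allele-created C: unmethylated
            methylated = rng.random(len(c_idx)) < levels
            conv_p = np.where(methylated, params.inappropriate_conversion_rate,
                              params.conversion_rate)
            converted = rng.random(len(c_idx)) < conv_p
            mol[c_idx[converted]] = "T"
            if event_rows is not None:
                seq = genome.sequences[chrom]
                for j, gi in enumerate(gpos):
                    base_ok = (seq[gi] == ("C" if strand == "+" else "G"))
                    event_rows.append((frag_id, chrom, int(gi), strand,
                                       classify_context(seq, int(gi), strand)
                                       if base_ok else "het",
                                       bool(methylated[j]), bool(converted[j])))

        n_copies = 1 + int(rng.poisson(params.pcr_duplicate_mean - 1.0))
        mol_rc = np.array(list(revcomp("".join(mol))))
        for copy in range(n_copies):
            r1 = _apply_errors(mol[:rl].copy(), params.sequencing_error_rate, rng)
            r2 = _apply_errors(mol_rc[:rl].copy(), params.sequencing_error_rate, rng)
            name = f"sim:{chrom}:{start}:{end}:{strand}:{frag_id}:{copy}"
            pairs.append(ReadPair(name, "".join(r1), "".join(r2),
                                  qual_char * len(r1), qual_char * len(r2)))
        frag_rows.append((frag_id, chrom, start, end, strand, on_target,
                          n_copies))

    if not pairs:
        warnings.warn("no fragments were retained: empty library",
                      stacklevel=2)
    fragments = pd.DataFrame(frag_rows, columns=["fragment_id", "chrom",
                                                 "start", "end", "strand",
                                                 "on_target", "n_copies"])
    events = None
    if event_rows is not None:
        events = pd.DataFrame(event_rows,
                              columns=["fragment_id", "chrom", "pos", "strand",
                                       "context", "methylated", "read_as_t"])
    return SimulatedLibrary(pairs, fragments, events, params,
                            params.n_fragments)
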