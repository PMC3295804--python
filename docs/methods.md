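# Methods

## The assay being modelled

Hybrid-capture bisulfite sequencing enriches a target subset of the genome
(here, a toy stand-in for an exome) with hybridization probes, converts the
captured library with sodium bisulfite, and sequences it as short paired-end
reads. Unmethylated cytosines deaminate to uracil and read as T after PCR;
5-methylcytosine is protected and reads as C. Comparing each read base
against the reference therefore reveals, per cytosine and per strand, how
many sampled molecules were methylated. `capmeth` implements the
computational half of this assay and a generative model of its data.

## Simulator

The generator is the package's definition of the study conditions, not a
tuning dial; its defaults describe one fixed, documented experiment.

**Reference genome.** I.i.d. bases at a configurable GC fraction (default
0.45, human-like), with CpG islands injected by a process that emits the CG
dinucleotide with probability `cpg_fraction` per step inside island
intervals. Islands concentrate CpGs the way capture panels concentrate them
around promoters/exons; the background supplies CpG-poor sequence and the
non-CpG cytosines needed by the conversion estimator.

**Truth methylome.** Each CpG pair draws one level from a two-component
Beta mixture (defaults: 70% from Beta(10, 1), 30% from Beta(1, 20)),
reproducing the strongly bimodal CpG landscape of somatic methylomes. Both
strand cytosines of a pair carry the identical level — symmetric CpG
methylation is assumed throughout, so the package makes no hemimethylation
inference. Non-CpG cytosines carry a constant level (default 0), matching
the assumption — also used by the non-conversion estimator — that non-CpG
methylation is negligible in human somatic cells.

**Library.** Per attempted fragment: a Normal(250, 25) bp length (redrawn
until ≥ 1; the protocol's sonication mean), uniform placement, Bernoulli
capture with `on_target_capture_prob` (default 0.8) if the fragment
overlaps any target by ≥ 1 bp else `off_target_capture_prob` (default
0.08) — a two-probability retention model is sufficient to reproduce
aggregate enrichment in the 72–76% range and deliberately avoids probe
thermodynamics — a 50/50 source strand (a `watson-informative-only` mode
exists for probes designed on one strand), per-molecule methylation states
drawn Bernoulli(true level) and converted C→T with `conversion_rate`
(default 0.99) when unmethylated or `inappropriate_conversion_rate`
(default 0, no over-conversion) when methylated, heterozygous sites
resolved to one allele per molecule, 1 + Poisson(mean − 1) sequenced copies
(default mean 1.67 ⇒ ~40% duplication), and 90 bp mates (mate 2 is the
reverse complement of the fragment end) with per-base substitution errors
(default 0.001). Read names encode chrom:start:end:strand:fragment:copy so
tests and QC oracles can join any read back to its truth row without side
files.

What the simulator does **not** model: probe sequence design and bait
thermodynamics, GC-dependent capture bias, insert-size/quality-score
heterogeneity, adapter read-through, indels, and carrier-DNA handling.
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and inference under the stated generative model, not robustness
to every artifact of real libraries.

## Aligner

Reads are aligned in the two reduced-alphabet spaces of bisulfite data: the
reference with C→T applied (original-top-strand molecules) and with G→A
applied (bottom-strand molecules on forward coordinates). Candidate
placements come from exact k-mer matches: the 30 bp seed is split into
3 chunks of 10 (seed budget 2 mismatches + 1), and the pigeonhole principle
makes candidate generation exact — every placement within the seed budget
shares at least one exact chunk in the reduced alphabet, because
bisulfite-consistent substitutions are invisible there. Candidates are then
verified in the original base space: read-T over reference-C (CT space) and
read-A over reference-G (GA space) are conversion-consistent and never
counted; every other substitution is. Budgets: ≤ 2 seed mismatches
(conversion-consistent substitutions do not count toward the seed budget —
a deliberate interpretation, since the reduced-alphabet search cannot see
them), ≤ 5 per read. Gapped alignment is disabled; gap counts participate
only in ranking, which keeps the aligner exact and directly comparable to a
position-exhaustive oracle.

Pair selection ranks properly-paired placements (same chromosome and
conversion space, opposite orientations, plus-strand mate leftmost, outer
span ≤ 1000 bp) above single-end ones, then by total mismatches+gaps; a
read pair is *unique* iff exactly one top-ranked location survives, and
only unique pairs feed any downstream counting. Mates whose best placements
disagree on conversion space are treated as improper: a physical molecule
has one informative space.

PCR duplicates are collapsed by (chromosome, pair outer start, outer end,
conversion space, molecule strand), keeping the member with fewest
mismatches, breaking ties by summed base quality then lexicographic read
name so the result is deterministic. The duplication rate's denominator is
uniquely-aligned pairs before collapse.

## Methylation calling and conversion correction

CT-space alignments inform forward-strand cytosines (read C ⇒ methylated,
read T ⇒ unmethylated), GA-space alignments inform reverse-strand cytosines
symmetrically; any other letter at a cytosine is ignored, as are bases
below the quality threshold (default 0 — the simulator emits constant
qualities). Overlapping mates of one pair both count; they are the same
molecule, so this inflates effective depth slightly without biasing levels.
Contexts follow the standard trinucleotide rule (CpG/CHG/CHH) on the
informative strand; cytosines too close to a chromosome end to classify are
CHH by convention.

Because a fraction *e* of unmethylated cytosines fails to convert, raw
levels are biased upward by ≈ e·(1 − m). The package estimates one pooled
*e* per library from non-CpG calls (`e = Σ methylated / Σ depth`) — a
single global rate, matching how the assay reports conversion — and
corrects CpG fractions by background subtraction with renormalization,
`corrected = max(0, (raw − e)/(1 − e))`, reported in percent alongside the
retained raw level. This correction is exact in expectation (a site with
true level m has raw expectation m + (1 − m)·e), monotone in the raw level
and invertible for e < 1. A spike-in variant estimates *e* from
unmethylated carrier sequences when such chromosomes are present. Sites
with zero depth are absent rather than zero; e = 1 is refused as a
degenerate library.

## Capture QC and allele dropout

On-target status is judged on the pair's outer span (the sequenced
fragment) with ≥ 1 bp overlap; judging the fragment rather than individual
mates makes the statistic identical to the simulator's fragment-level truth
and avoids double-counting mates. "Covered" for a region means ≥ 1 unique
deduplicated read overlapping ≥ 1 bp (the most permissive reading); the
≥ 10-read fraction uses the same overlap rule. Mean target depth is
per-base unique-read depth summed over target bases divided by the target
span.

Allele dropout is measured at known heterozygous sites. Pairs confounded
with conversion (C/T, A/G) are excluded outright. A site qualifies when its
total read depth is strictly greater than 10 (depths "of more than 10×");
it is recovered when both alleles are seen at least twice (a knob — the
recovery criterion is not standardised) in conversion-safe observations. An
observed base counts as allele evidence only when it cannot be a conversion
product in that read's space: observed T in CT space may be a converted C
and observed A in GA space a converted bottom-strand C, so those letters
never count. For an unmethylated allele pair this gives each allele an
evidence probability of 1/4 per covering read (allele × informative
strand), which is what the exact trinomial oracle in the test suite checks.

## Region analysis

**Fisher exact test.** Authored as full hypergeometric enumeration in
exact integer arithmetic (math.comb / Fraction): the two-sided p sums all
tables with the observed margins whose probability does not exceed the
observed table's, with a 1e-7 relative tie tolerance (applied as an exact
rational comparison) so analytically tied tables are never dropped to
floating-point noise. The all-zero table yields p = 1 by convention.

**DMR calling.** Region counts pool both strands' CpG calls lying inside
the region. Between two samples, three conjunctive gates: Fisher p < 0.01
(raw — no multiple-testing correction, matching the assay's stated
procedure; Bonferroni/BH are available behind a flag that defaults off),
fold change > 2 where fold = max/min of the two levels (symmetric, since
"over two-fold between samples" has no direction; min = 0 with max > 0
passes), and absolute difference > 20 points. Every result row carries all
three booleans plus the raw statistics, so a call is auditable. Regions
uncovered in either sample are excluded from testing.

**Metagene profile.** 70 sections: upstream 2 kb (20), first exon (10),
internal exons concatenated in transcript order (10), terminal exon (10),
downstream 2 kb (20). Coordinates are flipped for minus-strand genes;
each feature is divided into equal base-pair sections and each covered CpG
assigned to exactly one. Section means are unweighted over CpG levels
pooled across genes (not per-gene means of means — pooled is stable for
sparsely covered genes). Genes with fewer than three exons contribute no
internal-exon observations.

**Concordance and validation.** Pearson r over per-cytosine levels at
sites with depth ≥ 9 in both call sets ("at least nine reads" adopted over
the ambiguous "nine-fold"), with a 95% CI from Fisher's variance-
stabilizing transform. Per-CpG validation against clone sequencing uses a
2×2 chi-square with continuity correction when all expected counts are ≥ 5
and the exact test otherwise (the switch rule is a documented choice; both
tests are named by the assay without one).

## Pipeline, seeding, determinism

`run_pipeline` executes simulate → align → dedup → call → qc → dmr →
metagene → concordance for two samples sharing one truth methylome; a
configurable fraction of target regions (default 10%) carries planted
differences in sample B, moved in one direction per region (opposite
per-CpG moves would cancel in the regional aggregate) by at least the
configured shift (default 0.4) and at least three-fold, the contrast
profile the three gates detect with margin at desk-scale depth. All
randomness fans out from one global seed through stable stage labels
(SeedSequence spawn keys), so a stage rerun standalone reproduces its
in-pipeline output and two runs with one seed are byte-identical; the
manifest records a SHA-256 digest per artifact. A stage failure aborts
with the stage name (exit code 3 from the CLI; 2 for config errors).
Configuration is one strict YAML file: unknown keys are rejected, and the
file round-trips losslessly.

When a desk-scale run leaves no heterozygous site above the dropout depth
threshold, or fewer than three sites above the concordance depth filter,
the pipeline writes an explicit NA report for that statistic rather than
aborting; the underlying library functions still raise, as their contracts
specify.

## Problem sizes

Defaults and test scales were chosen so the full suite and the acceptance
script each run in a few minutes on one CPU while keeping every statistical
check well-powered: a 100 kb single-chromosome genome with 8 CpG islands,
50 targets of 100–300 bp, 2×10⁴ attempted fragments per sample (≈ 7–8 k
retained pairs, ≈ 29× mean target depth, ≈ 15× per strand). The
conversion-recovery experiment uses 95% conversion and ≈ 55× per-strand
depth over > 4,000 CpG strand calls with sequencing error set to zero, so
the non-conversion estimator is measured against its own target rather
than against error-plus-non-conversion jointly. DMR operating
characteristics use count-level simulation (450 null regions, 50 planted
40-point shifts at depth 200 per sample), which isolates the decision rule
from read-level noise already tested elsewhere.

## Known limitations

- The aligner is exact but desk-scale: a hash of reduced-alphabet k-mers,
  not an FM-index; no gapped alignment, no quality-aware scoring.
- Overlapping mates double-count the same molecule at covered cytosines
  (unbiased for levels, slightly anti-conservative for depth filters).
- One global non-conversion rate; no per-site or per-read filtering of
  incompletely converted molecules.
- The capture model has no GC or probe-affinity bias, so enrichment
  uniformity is optimistic relative to real panels.
- Multi-mapped reads are recorded but never counted; on a repeat-free
  random reference they are rare, so the unique-map-rate statistic is near
  100% rather than the 80–85% typical of a real genome with repeats.
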