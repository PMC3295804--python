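"""End-to-end driver: simulate two samples, align, call, QC, DMR, metagene,
concordance. Every artifact is written under one output directory and listed
with its SHA-256 digest in ``manifest.json``; runs are byte-reproducible for
a fixed config.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from . import __version__, align, analysis, io, methcall, qc, simulate
from .config import PipelineConfig, stage_seed

logger = logging.getLogger(__name__)

STAGES = ["simulate", "align", "dedup", "call", "qc", "dmr", "metagene",
          "concordance"]
SAMPLES = ("A", "B")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sim_params(cfg: PipelineConfig, seed: int) -> simulate.SimParams:
    lib = cfg.library
    return simulate.SimParams(
        fragment_mean=lib.fragment_mean, fragment_sd=lib.fragment_sd,
        read_length=lib.read_length, n_fragments=lib.n_fragments,
        conversion_rate=lib.conversion_rate,
        inappropriate_conversion_rate=lib.inappropriate_conversion_rate,
        sequencing_error_rate=lib.sequencing_error_rate,
        on_target_capture_prob=lib.on_target_capture_prob,
        off_target_capture_prob=lib.off_target_capture_prob,
        pcr_duplicate_mean=lib.pcr_duplicate_mean,
        base_quality=lib.base_quality, strand_mode=lib.strand_mode,
        record_conversion_events=False, seed=seed)


def _aligner_params(cfg: PipelineConfig) -> align.AlignerParams:
    a = cfg.aligner
    return align.AlignerParams(a.seed_length, a.seed_max_mismatches,
                               a.total_max_mismatches, a.max_gaps,
                               a.max_insert)


def plant_dmr_methylome(methylome: simulate.TrueMethylome,
                        genome: simulate.ReferenceGenome,
                        targets: simulate.TargetSet,
                        fraction: float, shift: float,
                        seed: int) -> tuple[simulate.TrueMethylome, list[str]]:
    """Shift CpG truth levels in a random fraction of target regions.

    Planted levels differ from the originals by at least ``shift`` (as a
    fraction) and by more than three-fold, the contrast profile the three-gate
    DMR rule detects: hypomethylated CpGs move up, hypermethylated CpGs move
    down. Returns the modified methylome and the planted region ids.
    """
    rng = np.random.default_rng(seed)
    watson = {c: a.copy() for c, a in methylome.watson_levels.items()}
    crick = {c: a.copy() for c, a in methylome.crick_levels.items()}
    regions = targets.regions
    n_plant = int(round(fraction * len(regions)))
    chosen = sorted(rng.choice(len(regions), size=n_plant, replace=False))
    planted = []
    for i in chosen:
        reg = regions.iloc[i]
        cpg = genome.cpg_positions[reg["chrom"]]
        inside = cpg[(cpg >= reg["start"]) & (cpg < reg["end"])]
        w = watson[reg["chrom"]]
        c = crick[reg["chrom"]]
        if len(inside) == 0:
            continue
        # one direction per region, or opposite per-CpG moves cancel in the
        # regional aggregate
        go_up = float(np.mean(w[inside])) <= 0.5
        for p in inside:
            level = w[p]
            if go_up:
                new = min(1.0, max(level + shift, 3.0 * level))
            else:
                new = max(0.0, min(level - shift, level / 3.0))
            w[p] = new
            c[p + 1] = new
        planted.append(reg["region_id"])
    return simulate.TrueMethylome(watson, crick), planted


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages and return the artifact directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(writer, obj, relpath: str):
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(obj, path)
        written.append(path)
        return path

    stage = "simulate"
    try:
        g = config.genome
        genome = simulate.generate_genome(
            g.n_chroms, g.chrom_length, g.gc_fraction, g.island_spec,
            seed=stage_seed(config.seed, "genome"))
        m = config.methylome
        methylome = simulate.generate_methylome(
            genome, (m.beta_high_a, m.beta_high_b),
            (m.beta_low_a, m.beta_low_b), m.p_high, m.noncpg_level,
            seed=stage_seed(config.seed, "methylome"))
        targets = simulate.define_targets(
            genome, config.targets.n_regions, config.targets.min_len,
            config.targets.max_len, seed=stage_seed(config.seed, "targets"))
        hets = simulate.plant_het_sites(
            genome, config.hets.density, config.hets.include_ambiguous,
            seed=stage_seed(config.seed, "hets"))
        genes = simulate.define_genes(
            genome, config.n_genes, seed=stage_seed(config.seed, "genes"))
        methylome_b, planted = plant_dmr_methylome(
            methylome, genome, targets, config.planted_dmr.fraction,
            config.planted_dmr.shift, seed=stage_seed(config.seed, "plant"))

        emit(io.write_fasta, genome, "reference.fa")
        emit(io.write_bed, targets, "targets.bed")
        emit(io.write_het_tsv, hets, "het_sites.tsv")
        emit(io.write_genes_tsv, genes, "genes.tsv")
        emit(io.write_table, methylome.to_table(genome), "truth_methylome_A.tsv")
        emit(io.write_table, methylome_b.to_table(genome), "truth_methylome_B.tsv")
        with open(out / "planted_dmrs.txt", "w") as fh:
            fh.writelines(f"{rid}\n" for rid in planted)
        written.append(out / "planted_dmrs.txt")

        libraries = {}
        for sample, meth in (("A", methylome), ("B", methylome_b)):
            params = _sim_params(config,
                                 stage_seed(config.seed, f"reads:{sample}"))
            lib = simulate.simulate_reads(genome, meth, targets, hets, params)
            libraries[sample] = lib
            p1 = out / sample / "reads_1.fq"
            p2 = out / sample / "reads_2.fq"
            p1.parent.mkdir(parents=True, exist_ok=True)
            io.write_fastq_pairs(lib.pairs, p1, p2)
            written.extend([p1, p2])
            emit(io.write_table, lib.fragments, f"{sample}/truth_fragments.tsv")
            logger.info("sample %s: %d fragments retained of %d attempted, "
                        "%d read pairs", sample, len(lib.fragments),
                        lib.n_attempted, len(lib.pairs))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    stage = "align"
    try:
        aparams = _aligner_params(config)
        index = align.ConvertedIndex(genome, aparams)
        aligned = {s: align.align_library(libraries[s].pairs, index, aparams)
                   for s in SAMPLES}
        for s in SAMPLES:
            emit(io.write_alignments_tsv, aligned[s], f"{s}/alignments.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "dedup"
    try:
        dedup = {s: align.deduplicate(aligned[s]) for s in SAMPLES}
        for s in SAMPLES:
            emit(lambda pairs, p: io.write_sam(pairs, genome, p),
                 dedup[s].kept, f"{s}/alignments.dedup.sam")
            logger.info("sample %s: %d unique pairs, %d duplicates removed",
                        s, dedup[s].n_unique, dedup[s].removed)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "call"
    calls = {}
    try:
        for s in SAMPLES:
            raw = methcall.pileup(dedup[s].kept, genome,
                                  config.thresholds.min_base_quality)
            est = methcall.estimate_nonconversion(raw)
            corrected = methcall.correct_levels(raw, est)
            calls[s] = corrected
            emit(io.write_calls_tsv, corrected, f"{s}/cytosine_report.tsv")
            emit(io.write_bedgraph, corrected, f"{s}/corrected.bedGraph")
            emit(io.write_keyvalue,
                 {"nonconversion_rate": est.nonconversion_rate,
                  "n_noncpg_sites": est.n_noncpg_sites,
                  "n_noncpg_calls": est.n_noncpg_calls},
                 f"{s}/nonconversion.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "qc"
    try:
        for s in SAMPLES:
            report = qc.compute_capture_qc(
                dedup[s], targets, len(libraries[s].pairs), genome,
                config.thresholds.region_min_reads)
            emit(io.write_json, report.to_dict(), f"{s}/qc.json")
            with open(out / f"{s}/qc.txt", "w") as fh:
                fh.write(report.to_text())
            written.append(out / f"{s}/qc.txt")
            emit(io.write_table, report.per_chromosome_strand_depth,
                 f"{s}/per_chromosome_depth.tsv")
            try:
                dropout = qc.assess_allele_dropout(
                    hets, dedup[s].kept, genome,
                    config.thresholds.dropout_min_depth,
                    config.thresholds.min_allele_reads,
                    config.thresholds.min_base_quality)
                row = {"n_truth_het": dropout.n_truth_het,
                       "n_recovered_het": dropout.n_recovered_het,
                       "excluded_ambiguous": dropout.excluded_ambiguous,
                       "dropout_rate": dropout.dropout_rate}
            except ValueError:
                # small libraries may leave no het site above the depth
                # threshold; report that rather than aborting the run
                logger.warning("sample %s: no qualifying het sites for the "
                               "dropout assessment", s)
                row = {"n_truth_het": 0, "n_recovered_het": 0,
                       "excluded_ambiguous": 0, "dropout_rate": "NA"}
            emit(io.write_keyvalue, row, f"{s}/dropout.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "dmr"
    try:
        agg = {s: analysis.aggregate_regions(calls[s], targets)
               for s in SAMPLES}
        dmrs = analysis.call_dmrs(agg["A"], agg["B"],
                                  config.thresholds.alpha,
                                  config.thresholds.fold,
                                  config.thresholds.diff)
        emit(io.write_table, dmrs, "dmr.tsv")
        logger.info("%d of %d tested regions are DMRs",
                    int(dmrs["is_dmr"].sum()), len(dmrs))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "metagene"
    try:
        for s in SAMPLES:
            profile = analysis.metagene_profile(calls[s], genes)
            emit(io.write_table, profile, f"{s}/metagene.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "concordance"
    try:
        try:
            conc = analysis.pearson_concordance(
                calls["A"], calls["B"],
                config.thresholds.concordance_min_depth)
            row = {"pearson_r": conc.r, "ci_low": conc.ci_low,
                   "ci_high": conc.ci_high, "n_sites": conc.n_sites}
        except ValueError:
            # shallow libraries can leave < 3 sites above the depth filter
            logger.warning("too few sites above depth %d for concordance",
                           config.thresholds.concordance_min_depth)
            row = {"pearson_r": "NA", "ci_low": "NA", "ci_high": "NA",
                   "n_sites": 0}
        emit(io.write_keyvalue, row, "concordance.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    digests = {}
    for path in sorted(written):
        rel = str(path.relative_to(out))
        digests[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    io.write_json({"version": __version__, "seed": config.seed,
                   "stages": STAGES, "files": digests}, out / "manifest.json")
    return out
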