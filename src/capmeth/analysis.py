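"""Region-level methylation, DMR calling, metagene profiles, concordance.

DMR calling follows a three-gate rule between two samples: a two-sided
Fisher exact test on the pooled CpG counts of a region (p < 0.01), an over
two-fold difference between the two region levels, and an absolute level
difference of more than 20 percentage points. The gates are conjunctive and
no multiple-testing correction is applied by default; every result carries
the three booleans and the raw statistics so decisions are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GeneModel, TargetSet

logger = logging.getLogger(__name__)

# Tables whose probability exceeds the observed one by less than this
# relative tolerance still count as "at least as extreme" (guards against
# analytically-tied tables; applied in exact rational arithmetic).
_TIE_RTOL = Fraction(1, 10**7)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Full hypergeometric enumeration in exact integer arithmetic: the p-value
    sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's. An all-zero table
    yields p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    obs = comb(r1, a) * comb(n - r1, c1 - a)
    gate = obs + obs * _TIE_RTOL  # Fraction; exact comparison
    total = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(n - r1, c1 - x)
        if w <= gate:
            total += w
    return float(Fraction(total, comb(n, c1)))


@dataclass(frozen=True)
class RegionMethylation:
    region_id: str
    sum_methylated: int
    sum_unmethylated: int

    @property
    def level(self) -> float:
        total = self.sum_methylated + self.sum_unmethylated
        if total == 0:
            raise ValueError(f"region {self.region_id} has no CpG coverage")
        return 100.0 * self.sum_methylated / total


def aggregate_regions(calls: pd.DataFrame, targets: TargetSet) -> pd.DataFrame:
    """Sum methylated/unmethylated CpG counts per target region.

    Both strands contribute; a cytosine belongs to the region containing its
    position. Returns columns region_id, sum_methylated, sum_unmethylated,
    level (% — NaN where the region has no covered CpG).
    """
    cpg = calls[calls["context"] == "CpG"]
    rows = []
    for _, reg in targets.regions.iterrows():
        sub = cpg[(cpg["chrom"] == reg["chrom"])
                  & (cpg["pos"] >= reg["start"]) & (cpg["pos"] < reg["end"])]
        m = int(sub["count_methylated"].sum())
        u = int(sub["count_unmethylated"].sum())
        rows.append((reg["region_id"], m, u,
                     100.0 * m / (m + u) if m + u else np.nan))
    return pd.DataFrame(rows, columns=["region_id", "sum_methylated",
                                       "sum_unmethylated", "level"])


def call_dmrs(regions_a: pd.DataFrame, regions_b: pd.DataFrame,
              alpha: float = 0.01, fold: float = 2.0, diff: float = 20.0,
              correction: str | None = None) -> pd.DataFrame:
    """Three-gate differential methylation between two samples.

    Inputs are aggregate_regions frames over the same region universe;
    regions without coverage in either sample are excluded. The fold gate
    compares max/min of the two levels (min = 0 with max > 0 passes).
    correction: None (default, raw p), "bonferroni" or "bh".
    """
    if list(regions_a["region_id"]) != list(regions_b["region_id"]):
        raise ValueError("region universes differ between samples")
    merged = regions_a.merge(regions_b, on="region_id",
                             suffixes=("_a", "_b"))
    tot_a = merged["sum_methylated_a"] + merged["sum_unmethylated_a"]
    tot_b = merged["sum_methylated_b"] + merged["sum_unmethylated_b"]
    tested = merged[(tot_a > 0) & (tot_b > 0)].reset_index(drop=True)
    p = np.array([fisher_exact_two_sided(r.sum_methylated_a,
                                         r.sum_unmethylated_a,
                                         r.sum_methylated_b,
                                         r.sum_unmethylated_b)
                  for r in tested.itertuples()])
    if correction == "bonferroni":
        p_adj = np.minimum(1.0, p * len(p))
    elif correction == "bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        p_adj = np.empty_like(p)
        p_adj[order] = np.minimum(1.0, ranked)
    elif correction is None:
        p_adj = p
    else:
        raise ValueError(f"unknown correction {correction!r}")

    lev_a = tested["level_a"].to_numpy()
    lev_b = tested["level_b"].to_numpy()
    lo = np.minimum(lev_a, lev_b)
    hi = np.maximum(lev_a, lev_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_change = np.where(lo > 0, hi / lo,
                               np.where(hi > 0, np.inf, 1.0))
    abs_diff = np.abs(lev_a - lev_b)
    out = pd.DataFrame({
        "region_id": tested["region_id"],
        "sum_methylated_a": tested["sum_methylated_a"],
        "sum_unmethylated_a": tested["sum_unmethylated_a"],
        "sum_methylated_b": tested["sum_methylated_b"],
        "sum_unmethylated_b": tested["sum_unmethylated_b"],
        "level_a": lev_a,
        "level_b": lev_b,
        "p_value": p_adj,
        "fold_change": fold_change,
        "abs_diff": abs_diff,
        "passes_p": p_adj < alpha,
        "passes_fold": fold_change > fold,
        "passes_diff": abs_diff > diff,
    })
    out["is_dmr"] = out["passes_p"] & out["passes_fold"] & out["passes_diff"]
    return out


# ---------------------------------------------------------------------------
# metagene profile

FEATURE_SECTIONS = (("upstream", 20), ("first_exon", 10),
                    ("internal_exons", 10), ("terminal_exon", 10),
                    ("downstream", 20))
N_SECTIONS = sum(n for _, n in FEATURE_SECTIONS)


def _section_of(offset: int, length: int, n_sections: int) -> int:
    return min(n_sections - 1, offset * n_sections // length)


def metagene_profile(calls: pd.DataFrame, genes: list[GeneModel],
                     flank: int = 2000) -> pd.DataFrame:
    """Mean CpG methylation across 70 gene-anatomy sections.

    The 2 kb upstream of the TSS and 2 kb downstream of the TTS are divided
    equally into 20 sections each; the first, internal (concatenated in
    transcript order) and terminal exons into 10 sections each. Coordinates
    are flipped for minus-strand genes so sections follow transcription.
    Section means are unweighted over CpG levels pooled across genes. Genes
    with fewer than three exons contribute no internal-exon observations.
    """
    cpg = calls[calls["context"] == "CpG"].copy()
    level = np.where(cpg["corrected_level"].notna(), cpg["corrected_level"],
                     cpg["raw_level"])
    cpg["_level"] = level
    by_chrom = {c: sub.sort_values("pos") for c, sub in cpg.groupby("chrom")}

    sums = np.zeros(N_SECTIONS)
    counts = np.zeros(N_SECTIONS, dtype=np.int64)

    def add(feature_base: int, n_sec: int, interval: tuple[int, int],
            strand: str, chrom: str, feat_len: int, offset0: int) -> None:
        sub = by_chrom.get(chrom)
        if sub is None:
            return
        s, e = interval
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, (s, e))
        for p, lv in zip(pos[lo:hi], sub["_level"].to_numpy()[lo:hi]):
            off = (p - s) if strand == "+" else (e - 1 - p)
            sec = feature_base + _section_of(offset0 + off, feat_len, n_sec)
            sums[sec] += lv
            counts[sec] += 1

    for gene in genes:
        fwd = gene.strand == "+"
        exons_tx = list(gene.exons) if fwd else list(gene.exons)[::-1]
        tss, tts = gene.tss, gene.tts
        up = (tss - flank, tss) if fwd else (tss, tss + flank)
        down = (tts, tts + flank) if fwd else (tts - flank, tts)
        base = 0
        add(base, 20, up, gene.strand, gene.chrom, flank, 0)
        base += 20
        first = exons_tx[0]
        add(base, 10, first, gene.strand, gene.chrom, first[1] - first[0], 0)
        base += 10
        internal = exons_tx[1:-1]
        if internal:
            total = sum(e - s for s, e in internal)
            run = 0
            for s, e in internal:
                add(base, 10, (s, e), gene.strand, gene.chrom, total, run)
                run += e - s
        base += 10
        term = exons_tx[-1]
        add(base, 10, term, gene.strand, gene.chrom, term[1] - term[0], 0)
        base += 10
        add(base, 20, down, gene.strand, gene.chrom, flank, 0)

    labels = []
    for name, n in FEATURE_SECTIONS:
        labels.extend([(name, i) for i in range(n)])
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "section": np.arange(N_SECTIONS),
        "feature": [f for f, _ in labels],
        "feature_section": [i for _, i in labels],
        "mean_level": means,
        "n_cpg": counts,
    })


# ---------------------------------------------------------------------------
# concordance and per-site validation


@dataclass(frozen=True)
class ConcordanceResult:
    r: float
    ci_low: float
    ci_high: float
    n_sites: int


def pearson_concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                        min_depth: int = 9) -> ConcordanceResult:
    """Pearson r over per-cytosine levels at sites with depth >= min_depth
    in both samples; 95% CI via Fisher's variance-stabilizing transform."""
    cols = ["chrom", "pos", "strand"]
    a = calls_a[calls_a["depth"] >= min_depth]
    b = calls_b[calls_b["depth"] >= min_depth]
    merged = a.merge(b, on=cols, suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared qualifying sites")

    def levels(suffix: str) -> np.ndarray:
        corr = merged[f"corrected_level{suffix}"]
        raw = merged[f"raw_level{suffix}"]
        return np.where(corr.notna(), corr, raw).astype(float)

    x, y = levels("_a"), levels("_b")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant levels in one sample: r undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(merged)
    z = np.arctanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return ConcordanceResult(r, float(np.tanh(z - half)),
                             float(np.tanh(z + half)), n)


def site_validation_test(capture_counts: pd.DataFrame,
                         clone_counts: pd.DataFrame,
                         alpha: float = 0.01) -> pd.DataFrame:
    """Per-CpG 2x2 comparison of capture-sequencing counts against clone
    (BS-PCR) counts: chi-square with continuity correction when every
    expected count is >= 5, otherwise the exact test.

    Both inputs need columns site_id, methylated, unmethylated; zero-depth
    sites are skipped with a log entry.
    """
    merged = capture_counts.merge(clone_counts, on="site_id",
                                  suffixes=("_cap", "_clone"))
    rows = []
    for r in merged.itertuples():
        table = np.array([[r.methylated_cap, r.unmethylated_cap],
                          [r.methylated_clone, r.unmethylated_clone]])
        if table[0].sum() == 0 or table[1].sum() == 0:
            logger.info("site %s skipped: zero depth", r.site_id)
            continue
        expected = stats.contingency.expected_freq(table)
        if (expected >= 5).all():
            _, p, _, _ = stats.chi2_contingency(table, correction=True)
            used = "chi2"
        else:
            p = fisher_exact_two_sided(*table.ravel())
            used = "fisher"
        rows.append((r.site_id, float(p), used, p < alpha))
    return pd.DataFrame(rows, columns=["site_id", "p_value", "test",
                                       "significant"])
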