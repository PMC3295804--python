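"""Region aggregation, Fisher exactness, DMR gates, metagene, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from capmeth.analysis import (aggregate_regions, call_dmrs,
                              fisher_exact_two_sided, metagene_profile,
                              pearson_concordance, site_validation_test)
from capmeth.simulate import GeneModel, TargetSet


def _calls(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "count_methylated",
                                     "count_unmethylated"])
    df["depth"] = df.count_methylated + df.count_unmethylated
    df["raw_level"] = 100.0 * df.count_methylated / df.depth
    df["corrected_level"] = df.raw_level
    return df


def _targets(rows):
    return TargetSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                 "region_id"]))


class TestFisher:
    def test_diagonal_table(self):
        # support {0..3}: P(0) + P(3) = 2/20
        assert fisher_exact_two_sided(3, 0, 0, 3) == pytest.approx(0.1)

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(5, 5, 5, 5) == 1.0

    def test_all_zero_convention(self):
        assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    def test_matches_enumeration_oracle_on_random_tables(self):
        from oracle import fisher_enumeration
        rng = np.random.default_rng(1234)
        for _ in range(250):
            a, b, c, d = rng.integers(0, 16, size=4)
            while a + b + c + d == 0 or a + b + c + d > 60:
                a, b, c, d = rng.integers(0, 16, size=4)
            mine = fisher_exact_two_sided(a, b, c, d)
            assert mine == pytest.approx(fisher_enumeration(a, b, c, d),
                                         abs=1e-12)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_matches_scipy_property(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        mine = fisher_exact_two_sided(a, b, c, d)
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, abs=1e-10)


class TestAggregateRegions:
    def test_pooled_ratio(self):
        calls = _calls([("chr1", 10, "+", "CpG", 5, 5),
                        ("chr1", 20, "+", "CpG", 0, 10)])
        agg = aggregate_regions(calls, _targets([("chr1", 0, 100, "r0")]))
        assert agg.level.iloc[0] == pytest.approx(25.0)

    def test_uncovered_region_is_nan(self):
        calls = _calls([("chr1", 10, "+", "CpG", 5, 5)])
        agg = aggregate_regions(calls, _targets([("chr1", 0, 100, "r0"),
                                                 ("chr1", 200, 300, "r1")]))
        assert np.isnan(agg.level.iloc[1])

    def test_non_cpg_contexts_excluded(self):
        calls = _calls([("chr1", 10, "+", "CHH", 5, 5)])
        agg = aggregate_regions(calls, _targets([("chr1", 0, 100, "r0")]))
        assert agg.sum_methylated.iloc[0] == 0

    def test_split_additivity(self):
        rng = np.random.default_rng(7)
        rows = [("chr1", int(p), "+", "CpG", int(rng.integers(0, 9)),
                 int(rng.integers(0, 9))) for p in range(0, 200, 3)]
        calls = _calls(rows)
        whole = aggregate_regions(calls, _targets([("chr1", 0, 200, "r")]))
        split = aggregate_regions(calls, _targets([("chr1", 0, 97, "ra"),
                                                   ("chr1", 97, 200, "rb")]))
        assert (split.sum_methylated.sum()
                == whole.sum_methylated.iloc[0])
        assert (split.sum_unmethylated.sum()
                == whole.sum_unmethylated.iloc[0])


class TestCallDmrs:
    def _regions(self, counts):
        return pd.DataFrame(
            [(f"r{i}", m, u, 100.0 * m / (m + u) if m + u else np.nan)
             for i, (m, u) in enumerate(counts)],
            columns=["region_id", "sum_methylated", "sum_unmethylated",
                     "level"])

    def test_zero_versus_moderate_level_is_dmr(self):
        # mirrors the hypomethylated-in-one-sample pattern: 0% vs 22.222%
        a = self._regions([(0, 40)])
        b = self._regions([(6, 21)])
        out = call_dmrs(a, b)
        row = out.iloc[0]
        assert row.p_value < 0.01 and np.isinf(row.fold_change)
        assert row.abs_diff == pytest.approx(22.222, abs=1e-3)
        assert bool(row.is_dmr)

    def test_identical_counts_not_dmr(self):
        a = self._regions([(30, 70)])
        out = call_dmrs(a, a.copy())
        row = out.iloc[0]
        assert row.p_value == 1.0 and row.abs_diff == 0.0
        assert not row.is_dmr

    def test_fold_gate_blocks_high_level_shift(self):
        # 50% vs 90%: significant and >20 points apart but only 1.8-fold
        a = self._regions([(100, 100)])
        b = self._regions([(180, 20)])
        row = call_dmrs(a, b).iloc[0]
        assert row.passes_p and row.passes_diff and not row.passes_fold
        assert not row.is_dmr

    def test_uncovered_regions_excluded(self):
        a = self._regions([(10, 10), (0, 0)])
        b = self._regions([(10, 10), (5, 5)])
        assert len(call_dmrs(a, b)) == 1

    def test_mismatched_universes_rejected(self):
        a = self._regions([(1, 1)])
        b = self._regions([(1, 1), (2, 2)])
        with pytest.raises(ValueError):
            call_dmrs(a, b)

    def test_degenerate_gates_flag_everything(self):
        rng = np.random.default_rng(3)
        counts = [(int(rng.integers(0, 30)) + 1, int(rng.integers(0, 30)) + 1)
                  for _ in range(20)]
        a = self._regions(counts)
        b = self._regions(counts[::-1])
        out = call_dmrs(a, b, alpha=1.01, fold=0.99, diff=-1.0)
        assert out.is_dmr.all()

    def test_operating_characteristics_on_planted_counts(self):
        # 450 null regions + 50 planted 40-point shifts at depth 200/sample
        rng = np.random.default_rng(42)
        depth = 200
        rows_a, rows_b, truth = [], [], []
        for i in range(450):
            level = rng.beta(2, 2)
            rows_a.append((rng.binomial(depth, level), depth))
            rows_b.append((rng.binomial(depth, level), depth))
            truth.append(False)
        for i in range(50):
            low = rng.uniform(0.02, 0.25)
            ma = rng.binomial(depth, low)
            mb = rng.binomial(depth, low + 0.40)
            rows_a.append((ma, depth))
            rows_b.append((mb, depth))
            truth.append(True)
        a = self._regions([(m, d - m) for m, d in rows_a])
        b = self._regions([(m, d - m) for m, d in rows_b])
        out = call_dmrs(a, b)
        truth = np.array(truth)
        recall = out.is_dmr.to_numpy()[truth].mean()
        assert recall >= 0.9
        null_sig = (out.p_value.to_numpy()[~truth] < 0.01).mean()
        band = 3 * np.sqrt(0.01 * 0.99 / 450)
        assert null_sig <= 0.01 + band


class TestMetagene:
    GENE = GeneModel("g", "chr1", "+",
                     ((3000, 3400), (4000, 4200), (4800, 5000),
                      (5600, 6000)))

    def test_profile_shape_and_upstream_width(self):
        calls = _calls([("chr1", 1000 + 100 * i, "+", "CpG", 1, 1)
                        for i in range(20)])
        prof = metagene_profile(calls, [self.GENE])
        assert len(prof) == 70
        assert (prof.feature.value_counts()["upstream"] == 20)
        # CpGs every 100 bp across [1000, 3000) land one per 100 bp section
        up = prof[prof.feature == "upstream"]
        assert (up.n_cpg == 1).all()

    def test_constant_field_gives_constant_sections(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(800, 8200), 400, replace=False))
        calls = _calls([("chr1", int(p), "+", "CpG", 3, 97) for p in pos])
        prof = metagene_profile(calls, [self.GENE])
        covered = prof[prof.n_cpg > 0]
        assert covered.mean_level.to_numpy() == pytest.approx(
            np.full(len(covered), 3.0))

    def test_hand_worked_assignment(self):
        # minus-strand gene: exons [(100,200),(300,400),(500,600)]; TSS=600
        gene = GeneModel("g", "chr1", "-",
                         ((100, 200), (300, 400), (500, 600)))
        calls = _calls([
            # upstream spans [600, 2600); transcription runs high-to-low, so
            # position 700 sits 2599-700 = 1899 bp into the feature -> sec 18
            ("chr1", 700, "+", "CpG", 1, 0),
            # first exon (tx order) is (500,600); 599-595 = 4 bp in -> sec 0
            ("chr1", 595, "+", "CpG", 1, 0),
            # internal exon (300,400); 399-310 = 89 of 100 bp -> sec 8
            ("chr1", 310, "+", "CpG", 1, 0),
            # terminal exon (100,200); 199-199 = 0 bp in -> sec 0
            ("chr1", 199, "+", "CpG", 1, 0),
            # downstream: TTS=100; 99-50 = 49 bp of 2000 -> sec 0
            ("chr1", 50, "+", "CpG", 1, 0),
        ])
        prof = metagene_profile(calls, [gene])
        hit = prof[prof.n_cpg > 0][["feature", "feature_section"]]
        assert set(map(tuple, hit.to_numpy())) == {
            ("upstream", 18), ("first_exon", 0), ("internal_exons", 8),
            ("terminal_exon", 0), ("downstream", 0)}

    def test_two_exon_gene_skips_internal(self):
        gene = GeneModel("g", "chr1", "+", ((3000, 3200), (4000, 4200)))
        calls = _calls([("chr1", 3100, "+", "CpG", 1, 0),
                        ("chr1", 4100, "+", "CpG", 1, 0)])
        prof = metagene_profile(calls, [gene])
        assert prof[prof.feature == "internal_exons"].n_cpg.sum() == 0
        assert prof[prof.feature == "first_exon"].n_cpg.sum() == 1
        assert prof[prof.feature == "terminal_exon"].n_cpg.sum() == 1


class TestConcordance:
    def _df(self, levels, depth=20):
        return _calls([("chr1", i, "+", "CpG",
                        int(round(depth * lv / 100)),
                        depth - int(round(depth * lv / 100)))
                       for i, lv in enumerate(levels)])

    def test_identical_sets_give_r_one(self):
        df = self._df([10, 50, 90, 30, 70])
        res = pearson_concordance(df, df.copy())
        assert res.r == pytest.approx(1.0)

    def test_anticorrelated_sets_give_minus_one(self):
        levels = [10.0, 50.0, 90.0, 30.0, 70.0]
        res = pearson_concordance(self._df(levels),
                                  self._df([100 - lv for lv in levels]))
        assert res.r == pytest.approx(-1.0)

    def test_depth_filter_applies_to_both(self):
        a = self._df([10, 50, 90, 30], depth=20)
        b = self._df([10, 50, 90, 30], depth=5)
        with pytest.raises(ValueError, match="fewer than 3"):
            pearson_concordance(a, b, min_depth=9)

    def test_constant_vector_rejected(self):
        df = self._df([50, 50, 50, 50])
        with pytest.raises(ValueError, match="constant"):
            pearson_concordance(df, df.copy())

    def test_ci_brackets_r(self):
        rng = np.random.default_rng(9)
        lv = rng.uniform(0, 100, 50)
        noisy = np.clip(lv + rng.normal(0, 8, 50), 0, 100)
        res = pearson_concordance(self._df(list(lv), 50),
                                  self._df(list(noisy), 50))
        assert res.ci_low < res.r < res.ci_high


class TestSiteValidation:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "methylated",
                                           "unmethylated"])

    def test_similar_proportions_concordant(self):
        out = site_validation_test(self._counts([("s", 10, 90)]),
                                   self._counts([("s", 1, 9)]))
        assert out.p_value.iloc[0] > 0.01 and not out.significant.iloc[0]

    def test_identical_proportions_never_significant(self):
        lhc = self._counts([(f"s{i}", 10 * i, 100 - 10 * i)
                            for i in range(1, 10)])
        clone = self._counts([(f"s{i}", i, 10 - i) for i in range(1, 10)])
        out = site_validation_test(lhc, clone)
        assert not out.significant.any()

    def test_small_expected_counts_use_exact_test(self):
        out = site_validation_test(self._counts([("s", 1, 5)]),
                                   self._counts([("s", 4, 2)]))
        assert out.test.iloc[0] == "fisher"
        big = site_validation_test(self._counts([("s", 40, 60)]),
                                   self._counts([("s", 35, 65)]))
        assert big.test.iloc[0] == "chi2"

    def test_zero_depth_site_skipped(self):
        out = site_validation_test(self._counts([("s", 0, 0), ("t", 5, 5)]),
                                   self._counts([("s", 3, 3), ("t", 5, 5)]))
        assert list(out.site_id) == ["t"]

    def test_matched_panel_has_no_significant_sites(self):
        # 27 CpGs with matched proportions in both assays
        rng = np.random.default_rng(27)
        lhc_rows, clone_rows = [], []
        for i in range(27):
            p = rng.uniform(0.05, 0.95)
            m = rng.binomial(100, p)
            lhc_rows.append((f"s{i}", m, 100 - m))
            mc = rng.binomial(12, p)
            clone_rows.append((f"s{i}", mc, 12 - mc))
        out = site_validation_test(self._counts(lhc_rows),
                                   self._counts(clone_rows))
        # expected significant count is Binomial(27, 0.01); > 2 would be
        # far outside its 3-sigma band
        assert out.significant.sum() <= 2
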