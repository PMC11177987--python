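"""Methylation quantitation: weighting, tiling, pooling, QC, bimodality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gvoomics import synthetic_data as sd
from gvoomics.genomic_io import GenomicInterval, MethylomeSample
from gvoomics.methylome_quant import (bimodality_summary, build_cpg_tiles,
                                      build_genome_tiles, global_methylation,
                                      informative_tiles, pool_by_genotype,
                                      qc_sample, weighted_methylation)


def sample_from(rows, sample_id="S", genotype="NA", reads=0):
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                        "n_meth", "n_unmeth"])
    return MethylomeSample(sample_id=sample_id, genotype=genotype, calls=calls,
                           mapped_read_count=reads)


class TestGlobalMethylation:
    def test_weighted_ratio(self):
        s = sample_from([("chr1", 10, "+", "CpG", 3, 1),
                         ("chr1", 20, "+", "CpG", 1, 5)])
        assert global_methylation(s, "CpG") == pytest.approx(40.0)

    def test_all_unmethylated(self):
        s = sample_from([("chr1", 10, "+", "CpG", 0, 7)])
        assert global_methylation(s, "CpG") == 0.0

    def test_no_covered_calls_raises(self):
        s = sample_from([("chr1", 10, "+", "CpG", 0, 0)])
        with pytest.raises(ValueError, match="undefined"):
            global_methylation(s, "CpG")

    def test_generator_hits_oocyte_target(self, oocyte_samples, oocyte_plan):
        samples, _ = oocyte_samples
        value = global_methylation(samples["WT#1"], "CpG")
        assert value == pytest.approx(oocyte_plan.expected_global_cpg(), abs=2.0)


class TestWeightedMethylation:
    IV = [GenomicInterval("chr1", 1, 100, name="r")]

    def test_coverage_weighted_value(self):
        s = sample_from([("chr1", 10, "+", "CpG", 3, 0),
                         ("chr1", 20, "+", "CpG", 0, 3),
                         ("chr1", 30, "+", "CpG", 2, 2)])
        (f,) = weighted_methylation(s, self.IV, cov_min=3)
        assert f.methylation == pytest.approx(50.0)
        assert f.n_cpgs_used == 3

    def test_low_coverage_cpgs_filtered(self):
        s = sample_from([("chr1", 10, "+", "CpG", 3, 0),
                         ("chr1", 20, "+", "CpG", 1, 0)])
        (f,) = weighted_methylation(s, self.IV, cov_min=3)
        assert f.methylation == pytest.approx(100.0)
        assert f.n_cpgs_used == 1

    def test_uncovered_interval_undefined(self):
        s = sample_from([("chr1", 500, "+", "CpG", 5, 5)])
        (f,) = weighted_methylation(s, self.IV, cov_min=3)
        assert f.methylation is None and f.n_cpgs_used == 0

    def test_cov_min_validated(self):
        s = sample_from([("chr1", 10, "+", "CpG", 1, 1)])
        with pytest.raises(ValueError):
            weighted_methylation(s, self.IV, cov_min=0)


class TestTiles:
    def test_cpg_tiles_drop_remainder(self):
        tiles = build_cpg_tiles({"chr1": np.arange(1, 2501, 10)}, 100)
        assert len(tiles) == 2
        assert (tiles[0].start, tiles[0].end) == (1, 991)
        assert (tiles[1].start, tiles[1].end) == (1001, 1991)

    def test_too_few_cpgs_no_tiles(self):
        assert build_cpg_tiles({"chr1": np.arange(1, 100)}, 100) == []

    def test_no_cross_chromosome_tiles(self):
        tiles = build_cpg_tiles({"chr1": np.arange(1, 151),
                                 "chr2": np.arange(1, 121)}, 100)
        assert [t.chrom for t in tiles] == ["chr1", "chr2"]

    @pytest.mark.parametrize("length, n, last", [
        (25_000, 3, (20_001, 25_000)),
        (10_000, 1, (1, 10_000)),
        (9_999, 1, (1, 9_999)),
    ])
    def test_genome_tiles_partition(self, length, n, last):
        tiles = build_genome_tiles({"chr1": length}, 10_000)
        assert len(tiles) == n
        assert (tiles[-1].start, tiles[-1].end) == last
        # exact partition: adjacent, non-overlapping, covering 1..length
        assert tiles[0].start == 1 and tiles[-1].end == length
        for a, b in zip(tiles, tiles[1:]):
            assert b.start == a.end + 1

    def test_cpg_tiles_never_share_a_cpg(self):
        pos = np.sort(np.random.default_rng(0).choice(10 ** 6, 450,
                                                      replace=False)) + 1
        tiles = build_cpg_tiles({"chr1": pos}, 100)
        claimed = [((pos >= t.start) & (pos <= t.end)).sum() for t in tiles]
        assert claimed == [100] * len(tiles)
        for a, b in zip(tiles, tiles[1:]):
            assert b.start > a.end


class TestInformativeTiles:
    TILES = [GenomicInterval("chr1", 1, 100, name="t0")]

    def _sample(self, n_cov, cov, sid):
        rows = [("chr1", 10 + i, "+", "CpG", cov, 0) for i in range(n_cov)]
        return sample_from(rows, sample_id=sid)

    def test_tile_kept_when_all_samples_covered(self):
        samples = [self._sample(5, 3, "a"), self._sample(5, 4, "b")]
        assert informative_tiles(samples, self.TILES) == self.TILES

    def test_tile_dropped_when_one_sample_uncovered(self):
        samples = [self._sample(5, 3, "a"), self._sample(5, 0, "b")]
        assert informative_tiles(samples, self.TILES) == []

    def test_min_cpgs_boundary(self):
        samples = [self._sample(1, 3, "a")]
        assert informative_tiles(samples, self.TILES, min_cpgs=1) == self.TILES
        assert informative_tiles(samples, self.TILES, min_cpgs=2) == []


class TestPooling:
    def test_position_wise_sum(self):
        a = sample_from([("chr1", 10, "+", "CpG", 2, 1)], "a", "WT")
        b = sample_from([("chr1", 10, "+", "CpG", 1, 3)], "b", "WT")
        pool = pool_by_genotype([a, b])["WT"]
        row = pool.calls.iloc[0]
        assert (row.n_meth, row.n_unmeth) == (3, 4)
        assert pool.member_ids == ["a", "b"]

    def test_single_sample_pool_is_identity(self):
        a = sample_from([("chr1", 10, "+", "CpG", 2, 1),
                         ("chr2", 5, "+", "CHH", 0, 4)], "a", "WT")
        pool = pool_by_genotype([a])["WT"]
        assert pool.calls[["n_meth", "n_unmeth"]].sum().tolist() == [2, 5]

    def test_disjoint_positions_union(self):
        a = sample_from([("chr1", 10, "+", "CpG", 2, 1)], "a", "WT")
        b = sample_from([("chr1", 20, "+", "CpG", 1, 3)], "b", "WT")
        pool = pool_by_genotype([a, b])["WT"]
        assert sorted(pool.calls["pos"]) == [10, 20]

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30),
                              st.integers(0, 30), st.integers(0, 30)),
                    min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_pool_value_is_coverage_weighted_combination(self, counts):
        # pooled weighted methylation == ratio of summed member counts
        rows_a = [("chr1", 10 * (i + 1), "+", "CpG", m, u)
                  for i, (m, u, _, _) in enumerate(counts)]
        rows_b = [("chr1", 10 * (i + 1), "+", "CpG", m, u)
                  for i, (_, _, m, u) in enumerate(counts)]
        a = sample_from(rows_a, "a", "WT")
        b = sample_from(rows_b, "b", "WT")
        pool = pool_by_genotype([a, b])["WT"]
        iv = [GenomicInterval("chr1", 1, 10 * (len(counts) + 1))]
        (f,) = weighted_methylation(pool, iv, cov_min=1)
        tot_m = sum(m1 + m2 for m1, _, m2, _ in counts)
        tot = sum(sum(c) for c in counts)
        if f.methylation is None:
            assert tot == 0 or all(sum(c) == 0 for c in
                                   ((m1 + m2, u1 + u2) for m1, u1, m2, u2 in counts))
        else:
            assert f.methylation == pytest.approx(100.0 * tot_m / tot)


X_CGIS = [GenomicInterval("chrX", 1, 100, name="x0"),
          GenomicInterval("chrX", 200, 300, name="x1")]


def _x_sample(level, reads, n=5, cov=20):
    rows = [("chrX", 10 + i, "+", "CpG", int(cov * level),
             cov - int(cov * level)) for i in range(n)]
    rows += [("chrX", 210 + i, "+", "CpG", int(cov * level),
              cov - int(cov * level)) for i in range(n)]
    return sample_from(rows, "s", reads=reads)


class TestQC:
    def test_clean_deep_sample_included(self):
        rep = qc_sample(_x_sample(0.05, 6_000_000), X_CGIS)
        assert rep.included and rep.x_cgi_methylation == pytest.approx(5.0)

    def test_contaminated_sample_excluded(self):
        rep = qc_sample(_x_sample(0.20, 6_000_000), X_CGIS)
        assert not rep.pass_contamination and not rep.included

    def test_shallow_sample_excluded(self):
        rep = qc_sample(_x_sample(0.05, 4_000_000), X_CGIS)
        assert rep.pass_contamination and not rep.pass_depth and not rep.included

    def test_uncovered_xcgis_excluded_with_reason(self):
        s = sample_from([("chr1", 10, "+", "CpG", 5, 5)], reads=6_000_000)
        rep = qc_sample(s, X_CGIS)
        assert not rep.included and "undefined" in rep.reason

    def test_synthetic_contamination_detected(self, oocyte_plan):
        samples, truth = sd.gen_methylomes(
            plan=oocyte_plan, n_per_genotype={"WT": 1},
            contamination={"WT#1": 0.25}, seed=21)
        x_cgis = [iv for iv, k in oocyte_plan.cgis if k == "x_cgi"]
        rep = qc_sample(samples["WT#1"], x_cgis)
        # mixture arithmetic: 0.75*~2% oocyte + 0.25*70% somatic ~ 19%
        assert rep.x_cgi_methylation == pytest.approx(19.0, abs=2.5)
        assert not rep.included


class TestBimodality:
    def test_polar_values_flagged(self):
        s = bimodality_summary([2, 3, 95, 96])
        assert (s.frac_low, s.frac_mid, s.frac_high) == (0.5, 0.0, 0.5)
        assert s.bimodal

    def test_midrange_values_not_flagged(self):
        s = bimodality_summary([50.0] * 10)
        assert s.frac_low == 0 and s.frac_high == 0 and not s.bimodal

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bimodality_summary([])

    def test_oocyte_plan_bimodal_somatic_not(self, oocyte_samples, oocyte_plan):
        samples, _ = oocyte_samples
        tiles = build_cpg_tiles(oocyte_plan.cpg_positions(), 100)
        pools = pool_by_genotype([samples["WT#1"], samples["WT#2"]])
        vals = [f.methylation for f in weighted_methylation(pools["WT"], tiles)]
        assert bimodality_summary(vals).bimodal
        # fully contaminated sample == pure somatic-like profile
        somatic, _ = sd.gen_methylomes(plan=oocyte_plan,
                                       n_per_genotype={"WT": 1},
                                       contamination={"WT#1": 1.0}, seed=22)
        svals = [f.methylation for f in
                 weighted_methylation(somatic["WT#1"], tiles)]
        assert not bimodality_summary(svals).bimodal

    def test_maternal_paternal_gdmr_contract(self, oocyte_samples, oocyte_plan):
        samples, _ = oocyte_samples
        pools = pool_by_genotype(list(samples.values()))
        mat = [iv for iv, k in oocyte_plan.gdmrs if k == "maternal_gdmr"]
        pat = [iv for iv, k in oocyte_plan.gdmrs if k == "paternal_gdmr"]
        for pool in pools.values():
            assert all(f.methylation >= 85 for f in
                       weighted_methylation(pool, mat))
            assert all(f.methylation <= 10 for f in
                       weighted_methylation(pool, pat))
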