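"""Differential methylation calling and HyperD/HypoD classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gvoomics import synthetic_data as sd
from gvoomics.dmr_domains import (DMRecord, annotate_context, call_dmrs,
                                  classify_domains, diff_meth_test,
                                  intersect_dmrs, qvalue_adjust, _test_table)
from gvoomics.genomic_io import GeneModel, GenomicInterval, MethylomeSample
from gvoomics.methylome_quant import build_genome_tiles, informative_tiles
from gvoomics.splice_counter import build_intron_catalog  # noqa: F401 (sanity)


def pool_from(rows, genotype="WT"):
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                        "n_meth", "n_unmeth"])
    return MethylomeSample(sample_id=f"pool:{genotype}", genotype=genotype,
                           calls=calls)


REGION = GenomicInterval("chr1", 1, 1000, name="r0")


def counts_pool(m, u, genotype="WT", chrom="chr1", start=10, per_cpg=10):
    """Spread (m, u) counts over CpGs of coverage per_cpg."""
    rows = []
    pos = start
    while m + u > 0:
        mm = min(m, per_cpg)
        uu = min(u, per_cpg - mm)
        rows.append((chrom, pos, "+", "CpG", mm, uu))
        m, u = m - mm, u - uu
        pos += 10
    return pool_from(rows, genotype)


class TestDiffMethTest:
    def test_large_difference_significant(self):
        # chi-square on [[80,20],[30,70]] ~ 50.5 -> p << 1e-10
        p, delta = _test_table(80, 100, 30, 100)
        assert delta == pytest.approx(-50.0)
        assert p < 1e-10

    def test_identical_pools_null(self):
        p, delta = _test_table(40, 100, 40, 100)
        assert delta == 0.0
        assert p > 0.99

    def test_sparse_table_takes_fisher_path(self):
        p, delta = _test_table(1, 2, 1, 2)
        assert p == pytest.approx(1.0)

    def test_uncovered_region_undefined(self):
        ref = counts_pool(5, 5)
        empty = pool_from([("chr2", 10, "+", "CpG", 3, 3)], "Het")
        assert diff_meth_test(ref, empty, REGION) is None

    @given(st.integers(0, 200), st.integers(1, 200),
           st.integers(0, 200), st.integers(1, 200))
    @settings(derandomize=True, max_examples=80)
    def test_symmetry_under_group_swap(self, m1, u1, m2, u2):
        p_ab, d_ab = _test_table(m1, m1 + u1, m2, m2 + u2)
        p_ba, d_ba = _test_table(m2, m2 + u2, m1, m1 + u1)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab == pytest.approx(p_ba, rel=1e-9)


class TestQvalueAdjust:
    def test_uniform_nulls_rarely_called(self):
        rng = np.random.default_rng(1)
        called = [(qvalue_adjust(rng.uniform(size=10_000)) < 0.01).sum()
                  for _ in range(20)]
        assert np.mean([c == 0 for c in called]) >= 0.95

    def test_strong_signal_among_nulls_called(self):
        rng = np.random.default_rng(2)
        p = np.append(rng.uniform(size=10_000), 1e-8)
        assert qvalue_adjust(p)[-1] < 0.01


def _cal_pools(planted_delta=None, n_planted=0, coverage=30, seed=7,
               n_tiles=1200):
    plan = sd.tiling_methylome_plan(n_tiles)
    tiles = build_genome_tiles(plan.chrom_lengths, 10_000)
    planted = []
    if n_planted:
        hypod = [iv for iv, cls in plan.domains if cls == "HypoD"]
        planted = [sd.PlantedDMR(hypod[i], planted_delta, ("Het",))
                   for i in range(n_planted)]
    samples, _ = sd.gen_methylomes(plan=plan,
                                   n_per_genotype={"WT": 1, "Het": 1},
                                   coverage_mean=coverage,
                                   planted_dmrs=planted,
                                   include_noncpg=False, seed=seed)
    planted_ids = {t.name for t in tiles
                   for d in planted if t.chrom == d.interval.chrom
                   and t.start == d.interval.start}
    return samples["WT#1"], samples["Het#1"], tiles, planted_ids


class TestCallDmrs:
    def test_planted_recovered_nulls_quiet(self):
        ref, test, tiles, planted_ids = _cal_pools(+30.0, n_planted=40)
        inform = informative_tiles([ref, test], tiles)
        res = call_dmrs(inform, ref, test)
        called = {r.region_id for r in res.records}
        assert len(called & planted_ids) >= 36      # >= 90% recovery
        assert len(called - planted_ids) <= 2       # sparse false calls

    def test_null_run_makes_no_calls(self):
        ref, test, tiles, _ = _cal_pools(seed=8)
        res = call_dmrs(informative_tiles([ref, test], tiles), ref, test)
        assert len(res.records) == 0

    def test_subthreshold_delta_never_called(self):
        # a planted +15 shift cannot pass delta_min=20 however significant
        ref, test, tiles, planted_ids = _cal_pools(+15.0, n_planted=20,
                                                   coverage=60, seed=9)
        res = call_dmrs(informative_tiles([ref, test], tiles), ref, test,
                        delta_min=20.0)
        called = {r.region_id for r in res.records}
        assert called & planted_ids == set()

    def test_power_monotone_in_coverage(self):
        rec = {}
        for cov in (10, 30):
            ref, test, tiles, planted_ids = _cal_pools(+30.0, n_planted=40,
                                                       coverage=cov, seed=10)
            res = call_dmrs(informative_tiles([ref, test], tiles), ref, test)
            called = {r.region_id for r in res.records}
            rec[cov] = len(called & planted_ids)
        assert rec[30] >= rec[10]

    def test_empty_universe(self):
        ref = counts_pool(5, 5)
        test = counts_pool(5, 5, "Het")
        res = call_dmrs([], ref, test)
        assert res.records == [] and len(res.table) == 0


def make_gene(gene_id, chrom, exon_pairs, strand="+"):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs]
    return GeneModel(gene_id, chrom, strand, {f"{gene_id}.T": exons})


def dmr_at(chrom, start, end, delta=25.0, rid=None):
    return DMRecord(rid or f"{chrom}:{start}", GenomicInterval(chrom, start, end),
                    30.0, 30.0 + delta, delta, 1e-6, 1e-5,
                    "hyper" if delta > 0 else "hypo")


class TestAnnotateContext:
    GENES = [make_gene("G1", "chr1", [(5000, 5500), (7000, 7500)])]

    def test_intronic_dmr(self):
        (d,) = [dmr_at("chr1", 5800, 6200)]
        counts = annotate_context([d], self.GENES)
        assert d.context == "intron" and counts["intron"] == 1

    def test_promoter_beats_exon(self):
        # promoter window (1000, 0) upstream of TSS 5000 -> 4000..5000
        d = dmr_at("chr1", 4900, 5100)
        annotate_context([d], self.GENES)
        assert d.context == "promoter"

    def test_gene_free_chrom_intergenic(self):
        d = dmr_at("chr9", 100, 500)
        annotate_context([d], self.GENES)
        assert d.context == "intergenic"


class TestClassifyDomains:
    def _pools(self, level_by_genotype, n=10, cov=20):
        pools = {}
        for genotype, level in level_by_genotype.items():
            rows = [("chr1", 10 + 10 * i, "+", "CpG",
                     int(cov * level), cov - int(cov * level))
                    for i in range(n)]
            pools[genotype] = pool_from(rows, genotype)
        return pools

    DOM = [GenomicInterval("chr1", 1, 1000, name="d0")]

    def test_hyperd_below_threshold_lost(self):
        pools = self._pools({"Het": 0.60})
        records, tally = classify_domains(self.DOM, ["HyperD"], pools)
        assert records[0].status["Het"] == "lost"
        assert tally.set_index("genotype").loc["Het", "lost_HyperD"] == 1

    def test_hypod_low_maintained(self):
        pools = self._pools({"Het": 0.10})
        records, _ = classify_domains(self.DOM, ["HypoD"], pools)
        assert records[0].status["Het"] == "maintained"

    def test_boundary_75_is_maintained(self):
        pools = self._pools({"Het": 0.75})
        records, _ = classify_domains(self.DOM, ["HyperD"], pools)
        assert records[0].methylation["Het"] == pytest.approx(75.0)
        assert records[0].status["Het"] == "maintained"

    def test_uncovered_domain_uninformative(self):
        pools = {"Het": pool_from([("chr2", 5, "+", "CpG", 1, 1)], "Het")}
        records, tally = classify_domains(self.DOM, ["HyperD"], pools)
        assert records[0].status["Het"] == "uninformative"
        assert tally.iloc[0]["uninformative"] == 1

    def test_unperturbed_oocyte_domains_stay(self, oocyte_samples, oocyte_plan):
        samples, _ = oocyte_samples
        from gvoomics.methylome_quant import pool_by_genotype
        pools = pool_by_genotype(list(samples.values()))
        domains = [iv for iv, _ in oocyte_plan.domains]
        classes = [cls for _, cls in oocyte_plan.domains]
        _, tally = classify_domains(domains, classes, pools)
        for _, row in tally.iterrows():
            informative = row["maintained"] + row["lost_HyperD"] + row["lost_HypoD"]
            lost_frac = (row["lost_HyperD"] + row["lost_HypoD"]) / informative
            assert lost_frac <= 0.02


class TestIntersectDmrs:
    def test_shared_region_ids(self):
        a = [dmr_at("chr1", 1, 100, rid="t1"), dmr_at("chr1", 101, 200, rid="t2"),
             dmr_at("chr1", 201, 300, rid="t3")]
        b = [dmr_at("chr1", 1, 100, rid="t1"), dmr_at("chr1", 201, 300, rid="t3"),
             dmr_at("chr1", 301, 400, rid="t4")]
        common = intersect_dmrs(a, b)
        assert list(common["region_id"]) == ["t1", "t3"]

    def test_disjoint_sets_empty(self):
        a = [dmr_at("chr1", 1, 100, rid="t1")]
        b = [dmr_at("chr1", 101, 200, rid="t2")]
        assert len(intersect_dmrs(a, b)) == 0

    def test_opposite_directions_flagged_not_dropped(self):
        a = [dmr_at("chr1", 1, 100, delta=25.0, rid="t1")]
        b = [dmr_at("chr1", 1, 100, delta=-25.0, rid="t1")]
        common = intersect_dmrs(a, b)
        assert len(common) == 1 and not common.iloc[0]["concordant"]

    def test_mismatched_tilings_rejected(self):
        a = [dmr_at("chr1", 1, 100, rid="t1")]
        b = [dmr_at("chr1", 51, 150, rid="t1")]
        with pytest.raises(ValueError, match="tiling"):
            intersect_dmrs(a, b)
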