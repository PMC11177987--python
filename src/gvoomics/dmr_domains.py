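"""Differential methylation over tiles/CGIs and oocyte domain classification.

Testing operates on pooled genotype counts: each region contributes a
2x2 table of (methylated, unmethylated) counts per genotype, tested by
Pearson chi-square without continuity correction, falling back to
Fisher's exact test when any expected cell drops below 5. Multiple
testing is controlled by Benjamini-Hochberg q-values (a documented
stand-in for the SLIM estimator used by some methylation callers, whose
parameters are not reproducible here); the q-threshold semantics are
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .config import DEFAULTS
from .diffexpr import bh_adjust
from .genomic_io import GeneModel, GenomicInterval
from .methylome_quant import PooledMethylome, _interval_counts

__all__ = [
    "DMRecord",
    "DomainRecord",
    "DMRTestResult",
    "diff_meth_test",
    "qvalue_adjust",
    "call_dmrs",
    "annotate_context",
    "classify_domains",
    "intersect_dmrs",
    "promoter_interval",
]

MULTIPLE_TEST_NOTE = "q-values: Benjamini-Hochberg step-up (SLIM stand-in)"


@dataclass
class DMRecord:
    region_id: str
    interval: GenomicInterval
    meth_ref: float
    meth_test: float
    delta: float            # test - ref, percentage points
    p_value: float
    q_value: float
    direction: str          # hyper | hypo
    context: Optional[str] = None  # promoter | exon | intron | intergenic

    def __post_init__(self) -> None:
        expected = "hyper" if self.delta > 0 else "hypo"
        if self.direction != expected:
            raise ValueError("direction inconsistent with delta sign")


@dataclass
class DomainRecord:
    domain_id: str
    domain_class: str       # HyperD | HypoD
    interval: GenomicInterval
    methylation: Dict[str, Optional[float]]  # genotype -> weighted %
    status: Dict[str, str]                   # genotype -> maintained|lost|uninformative


@dataclass
class DMRTestResult:
    """All tested regions plus the called subset."""

    table: pd.DataFrame              # one row per tested region
    records: List[DMRecord]          # called DMRs
    note: str = MULTIPLE_TEST_NOTE


def diff_meth_test(pool_ref: PooledMethylome, pool_test: PooledMethylome,
                   region: GenomicInterval,
                   cov_min: int = DEFAULTS.cov_min,
                   ) -> Optional[Tuple[float, float]]:
    """(p_value, delta) for one region, or None when either pool is uncovered."""
    counts = _region_table(pool_ref, pool_test, region, cov_min)
    if counts is None:
        return None
    return _test_table(*counts)


def _region_table(pool_ref, pool_test, region, cov_min):
    m_ref, t_ref, n_ref = _interval_counts(pool_ref, region, cov_min)
    m_test, t_test, n_test = _interval_counts(pool_test, region, cov_min)
    if n_ref == 0 or n_test == 0 or t_ref == 0 or t_test == 0:
        return None
    return m_ref, t_ref, m_test, t_test


def _test_table(m_ref: int, t_ref: int, m_test: int,
                t_test: int) -> Tuple[float, float]:
    table = np.array([[m_ref, t_ref - m_ref], [m_test, t_test - m_test]])
    delta = 100.0 * m_test / t_test - 100.0 * m_ref / t_ref
    # expected cells under independence
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    if (expected < 5).any():
        p = float(sps.fisher_exact(table)[1])
    else:
        p = float(sps.chi2_contingency(table, correction=False)[1])
    return p, float(delta)


def qvalue_adjust(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up q-values (documented surrogate for SLIM)."""
    return bh_adjust(p_values)


def call_dmrs(regions: Sequence[GenomicInterval],
              pool_ref: PooledMethylome, pool_test: PooledMethylome,
              q_max: float = DEFAULTS.dmr_q_max,
              delta_min: float = DEFAULTS.dmr_delta_min,
              cov_min: int = DEFAULTS.cov_min) -> DMRTestResult:
    """Test every region and call DMRs at q < q_max and |delta| >= delta_min.

    The testing universe is the covered subset of ``regions`` (pass
    informative tiles for the tile analysis); q-values are computed over
    that universe only.
    """
    rows = []
    for i, region in enumerate(regions):
        counts = _region_table(pool_ref, pool_test, region, cov_min)
        if counts is None:
            continue
        m_ref, t_ref, m_test, t_test = counts
        p, delta = _test_table(m_ref, t_ref, m_test, t_test)
        rows.append({
            "region_id": region.name or f"region_{i}",
            "chrom": region.chrom, "start": region.start, "end": region.end,
            "meth_ref": 100.0 * m_ref / t_ref,
            "meth_test": 100.0 * m_test / t_test,
            "delta": delta, "p_value": p,
        })
    if not rows:
        table = pd.DataFrame(columns=["region_id", "chrom", "start", "end",
                                      "meth_ref", "meth_test", "delta",
                                      "p_value", "q_value", "called"])
        return DMRTestResult(table, [])
    table = pd.DataFrame(rows)
    table["q_value"] = qvalue_adjust(table["p_value"].to_numpy())
    table["called"] = (table["q_value"] < q_max) & (table["delta"].abs() >= delta_min)
    records = [
        DMRecord(r.region_id, GenomicInterval(r.chrom, r.start, r.end,
                                              name=r.region_id),
                 float(r.meth_ref), float(r.meth_test), float(r.delta),
                 float(r.p_value), float(r.q_value),
                 "hyper" if r.delta > 0 else "hypo")
        for r in table[table["called"]].itertuples()
    ]
    return DMRTestResult(table, records)


def promoter_interval(gene: GeneModel,
                      window: Tuple[int, int] = DEFAULTS.promoter_window,
                      ) -> GenomicInterval:
    """Strand-aware promoter window (upstream, downstream) around the TSS."""
    up, down = window
    tss = gene.tss
    if gene.strand == "-":
        start, end = tss - down, tss + up
    else:
        start, end = tss - up, tss + down
    return GenomicInterval(gene.chrom, max(1, start), max(1, end),
                           gene.strand, f"{gene.gene_id}:promoter")


def annotate_context(dmrs: Sequence[DMRecord], genes: Sequence[GeneModel],
                     promoter_window: Tuple[int, int] = DEFAULTS.promoter_window,
                     ) -> Dict[str, int]:
    """Label each DMR promoter/exon/intron/intergenic by any-overlap.

    Precedence when a DMR overlaps several feature classes:
    promoter > exon > intron > intergenic. Returns the per-context tally.
    """
    promoters: Dict[str, IntervalTree] = {}
    exons: Dict[str, IntervalTree] = {}
    introns: Dict[str, IntervalTree] = {}

    def add(trees, chrom, start, end):
        # intervaltree is half-open; +1 on end keeps inclusive semantics
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)

    for gene in genes:
        prom = promoter_interval(gene, promoter_window)
        add(promoters, prom.chrom, prom.start, prom.end)
        for exon_list in gene.transcripts.values():
            for e in exon_list:
                add(exons, e.chrom, e.start, e.end)
            for a, b in zip(exon_list, exon_list[1:]):
                if b.start - 1 >= a.end + 1:
                    add(introns, gene.chrom, a.end + 1, b.start - 1)

    counts = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
    for dmr in dmrs:
        chrom, lo, hi = dmr.interval.chrom, dmr.interval.start, dmr.interval.end + 1
        if chrom in promoters and promoters[chrom].overlap(lo, hi):
            dmr.context = "promoter"
        elif chrom in exons and exons[chrom].overlap(lo, hi):
            dmr.context = "exon"
        elif chrom in introns and introns[chrom].overlap(lo, hi):
            dmr.context = "intron"
        else:
            dmr.context = "intergenic"
        counts[dmr.context] += 1
    return counts


def classify_domains(domains: Sequence[GenomicInterval],
                     domain_classes: Sequence[str],
                     pools: Dict[str, PooledMethylome],
                     cov_min: int = DEFAULTS.cov_min,
                     hyperd_min: float = DEFAULTS.hyperd_min,
                     hypod_max: float = DEFAULTS.hypod_max,
                     ) -> Tuple[List[DomainRecord], pd.DataFrame]:
    """Maintained/lost status of each HyperD/HypoD per genotype.

    A HyperD is lost when its pooled weighted methylation falls below
    ``hyperd_min`` (inclusive maintenance at the boundary); a HypoD is
    lost when it rises above ``hypod_max``. Domains without coverage in a
    genotype are uninformative there and excluded from loss tallies.
    """
    if len(domains) != len(domain_classes):
        raise ValueError("domains and domain_classes differ in length")
    records = []
    tally_rows = []
    per_genotype = {g: {"lost_HyperD": 0, "lost_HypoD": 0, "maintained": 0,
                        "uninformative": 0} for g in pools}
    for i, (iv, cls) in enumerate(zip(domains, domain_classes)):
        if cls not in ("HyperD", "HypoD"):
            raise ValueError(f"unknown domain class {cls!r}")
        meth: Dict[str, Optional[float]] = {}
        status: Dict[str, str] = {}
        for genotype, pool in pools.items():
            m, t, n = _interval_counts(pool, iv, cov_min)
            if n == 0:
                meth[genotype] = None
                status[genotype] = "uninformative"
                per_genotype[genotype]["uninformative"] += 1
                continue
            value = 100.0 * m / t
            meth[genotype] = value
            lost = value < hyperd_min if cls == "HyperD" else value > hypod_max
            status[genotype] = "lost" if lost else "maintained"
            key = f"lost_{cls}" if lost else "maintained"
            per_genotype[genotype][key] += 1
        records.append(DomainRecord(iv.name or f"domain_{i}", cls, iv, meth,
                                    status))
    for genotype, tally in per_genotype.items():
        tally_rows.append({"genotype": genotype, **tally})
    return records, pd.DataFrame(tally_rows)


def intersect_dmrs(dmrs_a: Sequence[DMRecord], dmrs_b: Sequence[DMRecord],
                   ) -> pd.DataFrame:
    """DMRs called in both comparisons, matched by region_id.

    Both inputs must come from the same tiling; a region id whose
    coordinates disagree between the two sets is an error. Direction
    agreement is reported, not required.
    """
    by_id_a = {d.region_id: d for d in dmrs_a}
    by_id_b = {d.region_id: d for d in dmrs_b}
    rows = []
    for rid in sorted(set(by_id_a) & set(by_id_b)):
        a, b = by_id_a[rid], by_id_b[rid]
        if (a.interval.chrom, a.interval.start, a.interval.end) != \
           (b.interval.chrom, b.interval.start, b.interval.end):
            raise ValueError(f"region {rid} has mismatched coordinates; "
                             "DMR sets come from different tilings")
        rows.append({"region_id": rid, "chrom": a.interval.chrom,
                     "start": a.interval.start, "end": a.interval.end,
                     "delta_a": a.delta, "delta_b": b.delta,
                     "direction_a": a.direction, "direction_b": b.direction,
                     "concordant": a.direction == b.direction})
    columns = ["region_id", "chrom", "start", "end", "delta_a", "delta_b",
               "direction_a", "direction_b", "concordant"]
    return pd.DataFrame(rows, columns=columns)
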