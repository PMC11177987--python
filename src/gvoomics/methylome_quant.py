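"""Methylome quantitation: global levels, features, tiles, pooling and QC.

All methylation values are weighted levels — sum of methylated counts
over sum of total counts across a region's cytosines, times 100 — which
is the standard bisulfite feature statistic and is robust at the low
per-CpG depth of oocyte-pool libraries. Undefined quantities (no covered
CpG) are reported as ``None``/NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .genomic_io import GenomicInterval, MethylomeSample

__all__ = [
    "PooledMethylome",
    "FeatureMethylation",
    "QCReport",
    "BimodalitySummary",
    "global_methylation",
    "weighted_methylation",
    "build_cpg_tiles",
    "build_genome_tiles",
    "informative_tiles",
    "pool_by_genotype",
    "qc_sample",
    "bimodality_summary",
]


class PooledMethylome(MethylomeSample):
    """Genotype-level methylome: member counts summed position-wise."""

    def __init__(self, genotype: str, calls: pd.DataFrame,
                 member_ids: Sequence[str]):
        super().__init__(sample_id=f"pool:{genotype}", genotype=genotype,
                         calls=calls,
                         mapped_read_count=0)
        self.member_ids = list(member_ids)


@dataclass
class FeatureMethylation:
    feature_id: str
    interval: GenomicInterval
    methylation: Optional[float]  # 0-100, None when no covered CpG
    n_cpgs_used: int
    total_coverage: int

    def __post_init__(self) -> None:
        if (self.methylation is not None) != (self.n_cpgs_used >= 1):
            raise ValueError("methylation defined iff n_cpgs_used >= 1")
        if self.methylation is not None and not 0 <= self.methylation <= 100:
            raise ValueError("methylation out of [0, 100]")


@dataclass
class QCReport:
    sample_id: str
    x_cgi_methylation: Optional[float]
    mapped_read_count: int
    pass_contamination: bool
    pass_depth: bool
    included: bool
    reason: str = ""


@dataclass
class BimodalitySummary:
    frac_low: float
    frac_mid: float
    frac_high: float
    bimodal: bool


def global_methylation(sample: MethylomeSample, context: str = "CpG") -> float:
    """Genome-wide weighted methylation % for one cytosine context."""
    calls = sample.context_calls(context)
    total = int(calls["n_meth"].sum() + calls["n_unmeth"].sum())
    if total == 0:
        raise ValueError(
            f"{sample.sample_id}: no covered {context} calls; "
            "global methylation undefined")
    return 100.0 * float(calls["n_meth"].sum()) / total


def _interval_counts(sample: MethylomeSample, iv: GenomicInterval,
                     cov_min: int) -> Tuple[int, int, int]:
    """(n_meth, n_total, n_cpgs) over covered CpGs inside an interval."""
    idx = sample.cpg_index().get(iv.chrom)
    if idx is None:
        return 0, 0, 0
    pos, meth, unmeth = idx
    lo = np.searchsorted(pos, iv.start, side="left")
    hi = np.searchsorted(pos, iv.end, side="right")
    m, u = meth[lo:hi], unmeth[lo:hi]
    cov = m + u
    keep = cov >= cov_min
    return int(m[keep].sum()), int(cov[keep].sum()), int(keep.sum())


def weighted_methylation(sample: MethylomeSample,
                         intervals: Sequence[GenomicInterval],
                         cov_min: int = DEFAULTS.cov_min,
                         ) -> List[FeatureMethylation]:
    """Weighted methylation per interval over CpGs with coverage >= cov_min."""
    if cov_min < 1:
        raise ValueError("cov_min must be >= 1")
    out = []
    for i, iv in enumerate(intervals):
        n_meth, n_total, n_cpgs = _interval_counts(sample, iv, cov_min)
        value = 100.0 * n_meth / n_total if n_cpgs >= 1 else None
        out.append(FeatureMethylation(iv.name or f"region_{i}", iv, value,
                                      n_cpgs, n_total))
    return out


def build_cpg_tiles(cpg_positions: Dict[str, np.ndarray],
                    n_per_tile: int = DEFAULTS.tile_cpg_n,
                    ) -> List[GenomicInterval]:
    """Tiles of exactly ``n_per_tile`` consecutive CpGs per chromosome.

    A trailing remainder shorter than a full tile is dropped; tiles never
    cross chromosomes and span first to last member CpG.
    """
    tiles = []
    for chrom in sorted(cpg_positions):
        pos = np.asarray(cpg_positions[chrom])
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"CpG positions on {chrom} not strictly sorted")
        for k in range(len(pos) // n_per_tile):
            chunk = pos[k * n_per_tile:(k + 1) * n_per_tile]
            tiles.append(GenomicInterval(chrom, int(chunk[0]), int(chunk[-1]),
                                         name=f"{chrom}:cpg{k}"))
    return tiles


def build_genome_tiles(chrom_lengths: Dict[str, int],
                       width: int = DEFAULTS.tile_width) -> List[GenomicInterval]:
    """Adjacent fixed-width windows; the final partial window is kept."""
    tiles = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length < 1:
            raise ValueError(f"chromosome length < 1 for {chrom}")
        start = 1
        k = 0
        while start <= length:
            end = min(start + width - 1, length)
            tiles.append(GenomicInterval(chrom, start, end,
                                         name=f"{chrom}:tile{k}"))
            start = end + 1
            k += 1
    return tiles


def informative_tiles(samples: Sequence[MethylomeSample],
                      tiles: Sequence[GenomicInterval],
                      cov_min: int = DEFAULTS.cov_min,
                      min_cpgs: int = DEFAULTS.min_cpgs,
                      ) -> List[GenomicInterval]:
    """Tiles with >= min_cpgs CpGs at >= cov_min coverage in EVERY sample."""
    if not samples:
        raise ValueError("need at least one sample")
    keep = np.ones(len(tiles), dtype=bool)
    for sample in samples:
        index = sample.cpg_index()
        covered: Dict[str, np.ndarray] = {}
        for chrom, (pos, m, u) in index.items():
            covered[chrom] = pos[(m + u) >= cov_min]
        for i, tile in enumerate(tiles):
            if not keep[i]:
                continue
            pos = covered.get(tile.chrom)
            if pos is None:
                keep[i] = False
                continue
            lo = np.searchsorted(pos, tile.start, side="left")
            hi = np.searchsorted(pos, tile.end, side="right")
            if hi - lo < min_cpgs:
                keep[i] = False
    return [t for t, k in zip(tiles, keep) if k]


def pool_by_genotype(samples: Sequence[MethylomeSample],
                     ) -> Dict[str, PooledMethylome]:
    """Sum counts position-wise within each genotype label.

    Positions present in any member appear in the pool; the pooled counts
    at every position equal the sum of member counts there.
    """
    by_label: Dict[str, List[MethylomeSample]] = {}
    for s in samples:
        by_label.setdefault(s.genotype, []).append(s)
    pools = {}
    for label, members in by_label.items():
        if not members:
            raise ValueError(f"empty genotype group {label!r}")
        frames = [m.calls for m in members]
        merged = (pd.concat(frames, ignore_index=True)
                  .groupby(["chrom", "pos", "strand", "context"],
                           as_index=False, sort=True, observed=True)
                  [["n_meth", "n_unmeth"]].sum())
        pools[label] = PooledMethylome(label, merged,
                                       [m.sample_id for m in members])
    return pools


def qc_sample(sample: MethylomeSample,
              x_cgi_regions: Sequence[GenomicInterval],
              x_cgi_max: float = DEFAULTS.x_cgi_max,
              min_mapped_reads: int = DEFAULTS.min_mapped_reads,
              cov_min: int = DEFAULTS.cov_min) -> QCReport:
    """Granulosa-contamination and depth QC for one library.

    The contamination proxy is the unweighted mean over X-chromosome CGIs
    of their weighted methylation (one vote per CGI, so a single deep CGI
    cannot dominate); oocytes have near-zero X-CGI methylation while
    somatic contaminants do not. Both thresholds are strict inequalities.
    """
    if not x_cgi_regions:
        raise ValueError("X-chromosome CGI region list is empty")
    feats = weighted_methylation(sample, x_cgi_regions, cov_min)
    values = [f.methylation for f in feats if f.methylation is not None]
    pass_depth = sample.mapped_read_count > min_mapped_reads
    if not values:
        return QCReport(sample.sample_id, None, sample.mapped_read_count,
                        False, pass_depth, False,
                        reason="no covered X-CGIs; contamination check undefined")
    x_val = float(np.mean(values))
    pass_cont = x_val < x_cgi_max
    included = pass_cont and pass_depth
    reasons = []
    if not pass_cont:
        reasons.append(f"X-CGI methylation {x_val:.1f} >= {x_cgi_max}")
    if not pass_depth:
        reasons.append(f"mapped reads {sample.mapped_read_count} <= "
                       f"{min_mapped_reads}")
    return QCReport(sample.sample_id, x_val, sample.mapped_read_count,
                    pass_cont, pass_depth, included, "; ".join(reasons))


def bimodality_summary(tile_values: Sequence[float],
                       low: float = DEFAULTS.bimodal_low,
                       high: float = DEFAULTS.bimodal_high,
                       flag_min: float = DEFAULTS.bimodal_flag_min,
                       ) -> BimodalitySummary:
    """Fractions of tiles at the two methylome poles and the bimodality flag.

    An oocyte methylome concentrates tile methylation near 0 and near
    100; the flag fires when the two tails jointly hold >= flag_min of
    the tiles.
    """
    values = np.asarray([v for v in tile_values if v is not None], dtype=float)
    if values.size == 0:
        raise ValueError("no defined tile values")
    frac_low = float((values <= low).mean())
    frac_high = float((values >= high).mean())
    frac_mid = 1.0 - frac_low - frac_high
    return BimodalitySummary(frac_low, frac_mid, frac_high,
                             frac_low + frac_high >= flag_min)
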