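"""Expression-methylation integration.

In growing oocytes transcription drives de novo DNA methylation of gene
bodies, so a transcriptional origin for expression differences should
leave a methylation footprint. This module joins per-gene log2 fold
changes with gene-body weighted-methylation differences (mutant minus
WT, matching the fold-change orientation), measures their Spearman rank
correlation, and extracts the top-quartile quadrant candidates and the
fraction of DEGs with large methylation shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .config import DEFAULTS
from .diffexpr import DEResult
from .genomic_io import GeneModel
from .methylome_quant import PooledMethylome, _interval_counts

__all__ = [
    "IntegrationRecord",
    "gene_body_deltas",
    "spearman",
    "quadrant_candidates",
    "delta_threshold_summary",
    "build_records",
]


@dataclass
class IntegrationRecord:
    gene_id: str
    log2fc: float
    p_adj: float
    meth_delta: Optional[float]  # percentage points, test - ref
    in_deg_set: bool


def gene_body_deltas(pool_ref: PooledMethylome, pool_test: PooledMethylome,
                     genes: Sequence[GeneModel],
                     cov_min: int = DEFAULTS.cov_min,
                     ) -> Dict[str, Optional[float]]:
    """Gene-body weighted methylation difference (test - ref) per gene.

    The gene body is the annotated gene span. Undefined (None) when
    either genotype has no covered CpG over the span.
    """
    deltas: Dict[str, Optional[float]] = {}
    for gene in genes:
        span = gene.gene_span
        m_ref, t_ref, n_ref = _interval_counts(pool_ref, span, cov_min)
        m_test, t_test, n_test = _interval_counts(pool_test, span, cov_min)
        if n_ref == 0 or n_test == 0:
            deltas[gene.gene_id] = None
        else:
            deltas[gene.gene_id] = (100.0 * m_test / t_test
                                    - 100.0 * m_ref / t_ref)
    return deltas


def build_records(results: Sequence[DEResult],
                  meth_deltas: Dict[str, Optional[float]],
                  ) -> List[IntegrationRecord]:
    return [IntegrationRecord(r.gene_id, r.log2fc, r.p_adj,
                              meth_deltas.get(r.gene_id), r.is_deg)
            for r in results]


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value from the large-sample t approximation. Constant vectors have
    no defined rank correlation and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def quadrant_candidates(records: Sequence[IntegrationRecord],
                        fraction: float = DEFAULTS.top_fraction,
                        ) -> List[str]:
    """DEGs in the top ``fraction`` by |log2fc| AND by |meth_delta|.

    Operates on DEGs with a defined methylation delta; the two rankings
    use ceil(fraction * n) genes each, ties broken by gene id so the
    output is order-invariant and deterministic.
    """
    usable = [r for r in records if r.in_deg_set and r.meth_delta is not None]
    n = len(usable)
    if n == 0:
        return []
    k = math.ceil(fraction * n)
    by_fc = sorted(usable, key=lambda r: (-abs(r.log2fc), r.gene_id))[:k]
    by_meth = sorted(usable, key=lambda r: (-abs(r.meth_delta), r.gene_id))[:k]
    top_fc = {r.gene_id for r in by_fc}
    top_meth = {r.gene_id for r in by_meth}
    return sorted(top_fc & top_meth)


def delta_threshold_summary(records: Sequence[IntegrationRecord],
                            delta_min: float = DEFAULTS.integration_delta_min,
                            ) -> Tuple[int, Optional[float]]:
    """(count, percent) of DEGs with |gene-body delta| >= delta_min.

    Percent is over DEGs with defined methylation data, rounded to one
    decimal; None when no such DEG exists.
    """
    usable = [r for r in records if r.in_deg_set and r.meth_delta is not None]
    if not usable:
        return 0, None
    count = sum(1 for r in usable if abs(r.meth_delta) >= delta_min)
    return count, round(100.0 * count / len(usable), 1)
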