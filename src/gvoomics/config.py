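"""Analysis configuration: the single home of every numeric threshold.

Every cutoff used anywhere in the pipeline (DEG calling, DMR calling,
domain maintenance, contamination QC, tiling geometry, integration) is a
field of :class:`AnalysisConfig`. Other modules take these as explicit
parameters whose defaults are drawn from this class, so no threshold is
hard-coded at a call site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Tuple

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and geometry for the full GV-oocyte analysis.

    Units: methylation values and deltas are percentage points (0-100);
    fold changes are log2; q/p cutoffs are probabilities.
    """

    # differential expression
    log2fc_min: float = 1.0          # |log2FC| required for a DEG
    padj_max: float = 0.05           # BH-adjusted p cutoff for a DEG
    pseudo_count: float = 0.5        # added to group means before log2 ratio

    # 10-kb tile differential methylation
    dmr_q_max: float = 0.01
    dmr_delta_min: float = 20.0      # percentage points

    # CGI differential methylation
    cgi_q_max: float = 0.05
    cgi_delta_min: float = 10.0

    # oocyte methylome domains
    hyperd_min: float = 75.0         # HyperD maintained iff >= this
    hypod_max: float = 25.0          # HypoD maintained iff <= this

    # sample QC
    x_cgi_max: float = 13.5          # mean X-chromosome CGI methylation %
    min_mapped_reads: int = 5_000_000

    # coverage / tiling
    cov_min: int = 3                 # per-CpG coverage floor
    min_cpgs: int = 3                # covered CpGs per informative tile
    tile_cpg_n: int = 100            # CpGs per CpG-tile
    tile_width: int = 10_000         # bp per genome tile

    # bimodality summary
    bimodal_low: float = 25.0
    bimodal_high: float = 75.0
    bimodal_flag_min: float = 0.7    # (low + high) fraction for the flag

    # integration
    top_fraction: float = 0.25
    integration_delta_min: float = 20.0

    # promoter window relative to TSS: (upstream bp, downstream bp)
    promoter_window: Tuple[int, int] = (1000, 0)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("log2fc_min", "padj_max", "dmr_q_max", "dmr_delta_min",
                     "cgi_q_max", "cgi_delta_min", "hyperd_min", "hypod_max",
                     "x_cgi_max", "min_mapped_reads", "cov_min", "min_cpgs",
                     "tile_cpg_n", "tile_width", "integration_delta_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 < self.bimodal_flag_min <= 1:
            raise ValueError("bimodal_flag_min must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "promoter_window" in raw:
            raw["promoter_window"] = tuple(raw["promoter_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["promoter_window"] = list(self.promoter_window)
        return d


#: module-level defaults other modules pull their parameter defaults from
DEFAULTS = AnalysisConfig()
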