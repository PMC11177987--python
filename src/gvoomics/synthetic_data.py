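"""Synthetic inputs with ground truth for every arm of the pipeline.

The generators emulate the statistical structure the analysis assumes:

* spliced single-end reads over a synthetic multi-exon annotation, with a
  controllable fraction of reads carrying novel (non-annotated) splice
  junctions — the default 4% mirrors the contamination level typical of
  GV-oocyte cDNA libraries;
* negative-binomial count matrices with planted fold changes, matching
  the differential-expression model;
* bimodal oocyte methylomes simulated at the cytosine-call level: broad
  hypermethylated (HyperD, mean 85%) and hypomethylated (HypoD, mean 5%)
  domains sized so global CpG methylation lands near the 40% level of a
  fully grown oocyte, methylated maternal / unmethylated paternal gDMRs,
  methylated oocyte-specific CGIs, near-unmethylated X-chromosome CGIs,
  optional granulosa-like contamination (a somatic profile with ~70%
  methylation including at X-CGIs) and planted differential regions.

Every generator is a pure function of its parameters and seed, and
returns a truth object sufficient to score recovery without re-reading
the generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, GenomicInterval, MethylomeSample
from .splice_counter import IntronCatalog, build_intron_catalog

__all__ = [
    "AnnotationBundle",
    "ReadSetTruth",
    "CountMatrixTruth",
    "MethylomePlan",
    "PlantedDMR",
    "MethylomeTruth",
    "gen_annotation",
    "gen_spliced_reads",
    "gen_count_matrix",
    "default_methylome_plan",
    "tiling_methylome_plan",
    "gen_methylomes",
    "sam_text",
]

DEFAULT_READ_FRACTIONS = {
    "unspliced": 0.40, "canonical": 0.52,
    "noncanonical": 0.04, "ambiguous": 0.04,
}

#: per-CpG mean methylation by plan element (0-1 scale), oocyte profile
OOCYTE_LEVELS = {
    "HyperD": 0.85, "HypoD": 0.05,
    "maternal_gdmr": 0.95, "paternal_gdmr": 0.02,
    "oocyte_cgi": 0.90, "x_cgi": 0.02,
}
#: granulosa-like somatic profile used for contamination mixing
SOMATIC_LEVELS = {
    "background": 0.70, "HyperD": 0.70, "HypoD": 0.70,
    "maternal_gdmr": 0.50, "paternal_gdmr": 0.50,
    "oocyte_cgi": 0.10, "x_cgi": 0.70,
}
#: Beta concentration (a+b); gDMRs/CGIs are near-binary, hence sharper
CONCENTRATIONS = {
    "HyperD": 20.0, "HypoD": 20.0,
    "maternal_gdmr": 50.0, "paternal_gdmr": 50.0,
    "oocyte_cgi": 50.0, "x_cgi": 50.0,
}


# ---------------------------------------------------------------------------
# annotation

@dataclass
class AnnotationBundle:
    gtf_text: str
    models: List[GeneModel]
    chrom_lengths: Dict[str, int]
    shared_intron_genes: Tuple[str, ...] = ()


def gen_annotation(n_genes: int = 20,
                   exons_per_gene: Tuple[int, int] = (2, 4),
                   exon_len: Tuple[int, int] = (150, 300),
                   intron_len: Tuple[int, int] = (200, 800),
                   intergenic_gap: Tuple[int, int] = (500, 2000),
                   chroms: Sequence[str] = ("chr1", "chr2", "chrX"),
                   share_intron_pair: bool = False,
                   seed: int = 0) -> AnnotationBundle:
    """Non-overlapping multi-exon genes laid out left to right per chrom.

    With ``share_intron_pair`` an extra gene overlapping the first gene
    and sharing its first intron is added, so reads spanning only that
    intron cannot be assigned to a single gene (the ambiguous class).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    cursors = {c: 1000 for c in chroms}
    models: List[GeneModel] = []
    lines: List[str] = []

    def emit(gene_id: str, tx_id: str, chrom: str, strand: str,
             exons: List[Tuple[int, int]]) -> None:
        for start, end in exons:
            attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
            lines.append(f"{chrom}\tsim\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
        models.append(GeneModel(gene_id, chrom, strand, {
            tx_id: [GenomicInterval(chrom, s, e, strand) for s, e in exons]}))

    first_gene_exons: List[Tuple[int, int]] = []
    first_gene_meta: Tuple[str, str] = ("", "")
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        start = cursors[chrom]
        exons = []
        pos = start
        for k in range(n_exons):
            length = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exons.append((pos, pos + length - 1))
            pos += length
            if k < n_exons - 1:
                pos += int(rng.integers(intron_len[0], intron_len[1] + 1))
        gene_id = f"G{i + 1:03d}"
        emit(gene_id, f"{gene_id}.T1", chrom, strand, exons)
        if i == 0:
            first_gene_exons = exons
            first_gene_meta = (chrom, strand)
        cursors[chrom] = pos + int(rng.integers(intergenic_gap[0],
                                                intergenic_gap[1] + 1))

    shared: Tuple[str, ...] = ()
    if share_intron_pair:
        if len(first_gene_exons) < 2:
            raise ValueError("shared-intron pair needs a multi-exon first gene")
        chrom, strand = first_gene_meta
        # same first intron as G001, different outer exon boundaries
        a, b = first_gene_exons[0], first_gene_exons[1]
        alt_exons = [(max(1, a[0] - 60), a[1]), (b[0], b[1] + 60)]
        emit("G001alt", "G001alt.T1", chrom, strand, alt_exons)
        shared = ("G001", "G001alt")

    chrom_lengths = {c: cursors[c] + 2000 for c in chroms}
    return AnnotationBundle("\n".join(lines) + "\n", models, chrom_lengths,
                            shared)


# ---------------------------------------------------------------------------
# spliced reads

@dataclass
class ReadSetTruth:
    class_counts: Dict[str, int]
    canonical_per_gene: Dict[str, int]
    n_reads: int

    @property
    def noncanonical_fraction(self) -> float:
        return self.class_counts["noncanonical"] / self.n_reads


def sam_text(records: Iterable[Tuple[str, int, str, int, str, int]],
             chrom_lengths: Dict[str, int]) -> str:
    """Assemble SAM text from (read_id, flag, chrom, pos, cigar, qlen)."""
    out = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_lengths):
        out.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")
    for read_id, flag, chrom, pos, cigar, qlen in records:
        seq = "A" * qlen if qlen else "*"
        out.append(f"{read_id}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*")
    return "\n".join(out) + "\n"


def _unique_introns(catalog: IntronCatalog,
                    ) -> Dict[str, List[Tuple[str, int, int]]]:
    """gene -> introns mapping to exactly that gene (unambiguous)."""
    out: Dict[str, List[Tuple[str, int, int]]] = {}
    for key, genes in catalog.entries.items():
        chrom, start, end = key[0], key[-2], key[-1]
        if len(genes) == 1:
            g = next(iter(genes))
            out.setdefault(g, []).append((chrom, start, end))
    return out


def gen_spliced_reads(bundle: AnnotationBundle,
                      n_reads: int = 1000,
                      fractions: Optional[Dict[str, float]] = None,
                      gene_weights: Optional[Dict[str, float]] = None,
                      flank: int = 30,
                      sample_id: str = "S1",
                      seed: int = 0) -> Tuple[str, ReadSetTruth]:
    """Simulate single-end spliced reads as SAM text with exact class truth.

    Canonical reads span exactly one intron unique to their gene;
    noncanonical reads use a junction offset by >= 1 bp from every
    annotated intron; ambiguous reads span the planted shared intron.
    Class counts are drawn multinomially and recorded exactly.
    """
    fractions = dict(DEFAULT_READ_FRACTIONS if fractions is None else fractions)
    probs = np.array([fractions.get(k, 0.0) for k in
                      ("unspliced", "canonical", "noncanonical", "ambiguous")])
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    catalog = build_intron_catalog(bundle.models)
    unique = _unique_introns(catalog)
    gene_pool = sorted(unique)
    if gene_weights:
        weights = np.array([gene_weights.get(g, 0.0) for g in gene_pool])
        if weights.sum() <= 0:
            raise ValueError("gene_weights give zero total weight")
        weights = weights / weights.sum()
    else:
        weights = np.full(len(gene_pool), 1.0 / len(gene_pool))
    shared_keys = [k for k, genes in catalog.entries.items() if len(genes) >= 2]

    n_uns, n_can, n_non, n_amb = rng.multinomial(n_reads, probs)
    if n_amb > 0 and not shared_keys:
        raise ValueError("ambiguous reads require >= 2 genes sharing an intron")

    exon_by_gene = {m.gene_id: [e for exons in m.transcripts.values()
                                for e in exons] for m in bundle.models}
    flanks_for = lambda s, e: (min(flank, 20), min(flank, 20))  # noqa: E731

    records = []
    per_gene = {g: 0 for g in sorted(m.gene_id for m in bundle.models)}
    rid = 0

    def junction_read(chrom: str, start: int, end: int) -> Tuple[str, int, int]:
        fl = fr = flank
        pos = start - fl
        cigar = f"{fl}M{end - start + 1}N{fr}M"
        return cigar, pos, fl + fr

    for _ in range(int(n_can)):
        g = gene_pool[int(rng.choice(len(gene_pool), p=weights))]
        chrom, s, e = unique[g][int(rng.integers(len(unique[g])))]
        cigar, pos, qlen = junction_read(chrom, s, e)
        records.append((f"r{rid:07d}", 0, chrom, pos, cigar, qlen))
        per_gene[g] += 1
        rid += 1

    all_intron_keys = list(catalog.entries)
    for _ in range(int(n_non)):
        key = all_intron_keys[int(rng.integers(len(all_intron_keys)))]
        chrom, s, e = key[0], key[-2], key[-1]
        for _ in range(50):
            off = int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
            if catalog.lookup(chrom, (s + off, e + off)) is None:
                break
        else:
            raise RuntimeError("could not find an offset novel junction")
        cigar, pos, qlen = junction_read(chrom, s + off, e + off)
        records.append((f"r{rid:07d}", 0, chrom, max(1, pos), cigar, qlen))
        rid += 1

    for _ in range(int(n_amb)):
        key = shared_keys[int(rng.integers(len(shared_keys)))]
        chrom, s, e = key[0], key[-2], key[-1]
        cigar, pos, qlen = junction_read(chrom, s, e)
        records.append((f"r{rid:07d}", 0, chrom, pos, cigar, qlen))
        rid += 1

    genes_all = sorted(exon_by_gene)
    for _ in range(int(n_uns)):
        g = genes_all[int(rng.integers(len(genes_all)))]
        exons = exon_by_gene[g]
        e = exons[int(rng.integers(len(exons)))]
        rlen = min(60, e.length)
        start = e.start + int(rng.integers(0, e.length - rlen + 1))
        records.append((f"r{rid:07d}", 0, e.chrom, start, f"{rlen}M", rlen))
        rid += 1

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = ReadSetTruth(
        class_counts={"unspliced": int(n_uns), "canonical": int(n_can),
                      "noncanonical": int(n_non), "ambiguous": int(n_amb)},
        canonical_per_gene=per_gene, n_reads=int(n_reads))
    return sam_text(records, bundle.chrom_lengths), truth


# ---------------------------------------------------------------------------
# count matrices

@dataclass
class CountMatrixTruth:
    log2fc: Dict[str, float]
    dispersion: float
    size_factors: pd.Series
    groups: pd.Series


def gen_count_matrix(n_genes: int,
                     n_per_group: Tuple[int, int] = (5, 5),
                     group_labels: Tuple[str, str] = ("WT", "Mut"),
                     means: Optional[np.ndarray] = None,
                     mean_range: Tuple[float, float] = (50.0, 1000.0),
                     dispersion: float = 0.1,
                     planted: Optional[Dict[str, float]] = None,
                     seed: int = 0) -> Tuple[pd.DataFrame, CountMatrixTruth]:
    """NB count matrix with planted log2 fold changes in the second group.

    counts ~ NB(mean * size_factor * 2^(log2fc * is_test), dispersion),
    with per-sample size factors drawn log-uniform on [0.5, 2].
    """
    if min(n_per_group) < 2:
        raise ValueError("each group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    planted = dict(planted or {})
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in matrix: {sorted(unknown)}")
    if means is None:
        means = np.exp(rng.uniform(np.log(mean_range[0]),
                                   np.log(mean_range[1]), size=n_genes))
    else:
        means = np.broadcast_to(np.asarray(means, dtype=float), (n_genes,))
    lfc = np.array([planted.get(g, 0.0) for g in genes])
    ref, test = group_labels
    samples = ([f"{ref}{j + 1}" for j in range(n_per_group[0])]
               + [f"{test}{j + 1}" for j in range(n_per_group[1])])
    groups = pd.Series([ref] * n_per_group[0] + [test] * n_per_group[1],
                       index=samples, name="genotype")
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
    is_test = (groups == test).to_numpy().astype(float)
    mu = means[:, None] * sf[None, :] * np.power(2.0, lfc[:, None] * is_test[None, :])
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    else:
        lam = mu
    counts = pd.DataFrame(rng.poisson(lam), index=genes, columns=samples)
    counts.index.name = "gene_id"
    truth = CountMatrixTruth({g: float(planted.get(g, 0.0)) for g in genes},
                             dispersion,
                             pd.Series(sf, index=samples, name="size_factor"),
                             groups)
    return counts, truth


# ---------------------------------------------------------------------------
# methylomes

@dataclass(frozen=True)
class PlantedDMR:
    interval: GenomicInterval
    delta: float                 # percentage points added to the true level
    genotypes: Tuple[str, ...]   # genotypes carrying the shift


@dataclass
class MethylomePlan:
    """Region plan painting a mean methylation level onto every CpG."""

    chrom_lengths: Dict[str, int]
    cpg_spacing: int
    domains: List[Tuple[GenomicInterval, str]]       # HyperD | HypoD
    gdmrs: List[Tuple[GenomicInterval, str]] = field(default_factory=list)
    cgis: List[Tuple[GenomicInterval, str]] = field(default_factory=list)
    levels: Dict[str, float] = field(default_factory=lambda: dict(OOCYTE_LEVELS))
    somatic_levels: Dict[str, float] = field(
        default_factory=lambda: dict(SOMATIC_LEVELS))
    concentrations: Dict[str, float] = field(
        default_factory=lambda: dict(CONCENTRATIONS))
    noncpg_level: float = 0.05
    noncpg_fraction: float = 0.2   # CHG/CHH calls relative to CpG count

    def __post_init__(self) -> None:
        for group in (self.gdmrs, self.cgis):
            seen: List[GenomicInterval] = []
            for iv, _ in group:
                for other in seen:
                    if iv.overlaps(other):
                        raise ValueError(f"overlapping plan regions: {iv} {other}")
                seen.append(iv)

    def cpg_positions(self) -> Dict[str, np.ndarray]:
        return {c: np.arange(self.cpg_spacing, L + 1, self.cpg_spacing,
                             dtype=np.int64)
                for c, L in sorted(self.chrom_lengths.items())}

    def _paint(self, levels: Dict[str, float], background: float,
               ) -> Dict[str, np.ndarray]:
        out = {}
        for chrom, pos in self.cpg_positions().items():
            arr = np.full(pos.shape, background, dtype=float)
            for group, kind_map in (
                    (self.domains, None), (self.cgis, None), (self.gdmrs, None)):
                for iv, kind in group:
                    if iv.chrom != chrom:
                        continue
                    key = kind if kind in levels else None
                    if key is None:
                        continue
                    lo = np.searchsorted(pos, iv.start, side="left")
                    hi = np.searchsorted(pos, iv.end, side="right")
                    arr[lo:hi] = levels[key]
            out[chrom] = arr
        return out

    def oocyte_means(self) -> Dict[str, np.ndarray]:
        return self._paint(self.levels, background=self.levels["HypoD"])

    def somatic_means(self) -> Dict[str, np.ndarray]:
        return self._paint(self.somatic_levels,
                           background=self.somatic_levels["background"])

    def concentration_of(self) -> Dict[str, np.ndarray]:
        conc_levels = {k: v for k, v in self.concentrations.items()}
        out = {}
        for chrom, pos in self.cpg_positions().items():
            arr = np.full(pos.shape, self.concentrations["HypoD"], dtype=float)
            for group in (self.domains, self.cgis, self.gdmrs):
                for iv, kind in group:
                    if iv.chrom != chrom or kind not in conc_levels:
                        continue
                    lo = np.searchsorted(pos, iv.start, side="left")
                    hi = np.searchsorted(pos, iv.end, side="right")
                    arr[lo:hi] = conc_levels[kind]
            out[chrom] = arr
        return out

    def expected_global_cpg(self) -> float:
        means = self.oocyte_means()
        total = np.concatenate(list(means.values()))
        return 100.0 * float(total.mean())


def default_methylome_plan(scale: float = 1.0) -> MethylomePlan:
    """The standard synthetic oocyte genome.

    Two 1-Mb autosomes plus a 0.5-Mb chrX at 1 CpG / 50 bp; alternating
    HyperD (17.5 kb) / HypoD (22.5 kb) domains put 43.75% of CpGs at the
    85% pole, which lands global CpG methylation at ~40%; 12 gDMRs (6
    maternal, 6 paternal), 18 methylated oocyte-specific CGIs and 20
    near-unmethylated X-CGIs overlay the domains.
    """
    autosome = int(1_000_000 * scale)
    xlen = int(500_000 * scale)
    chrom_lengths = {"chr1": autosome, "chr2": autosome, "chrX": xlen}
    hyper_w, hypo_w = 17_500, 22_500
    domains: List[Tuple[GenomicInterval, str]] = []
    for chrom, length in chrom_lengths.items():
        start = 1
        k = 0
        while start <= length:
            cls = "HyperD" if k % 2 == 0 else "HypoD"
            width = hyper_w if cls == "HyperD" else hypo_w
            end = min(start + width - 1, length)
            domains.append((GenomicInterval(chrom, start, end,
                                            name=f"{chrom}:D{k}"), cls))
            start = end + 1
            k += 1
    gdmrs = []
    for i in range(6):
        # maternal gDMRs inside HyperDs on chr1, paternal inside HypoDs on chr2
        m_start = 1 + i * 120_000            # falls in a HyperD block
        p_start = 20_001 + i * 120_000       # falls in a HypoD block
        if m_start + 1999 <= autosome:
            gdmrs.append((GenomicInterval("chr1", m_start, m_start + 1999,
                                          name=f"mat_gDMR_{i}"), "maternal_gdmr"))
        if p_start + 1999 <= autosome:
            gdmrs.append((GenomicInterval("chr2", p_start, p_start + 1999,
                                          name=f"pat_gDMR_{i}"), "paternal_gdmr"))
    cgis = []
    for i in range(18):
        start = 50_001 + i * 50_000          # avoid the gDMR offsets
        chrom = "chr1" if i % 2 == 0 else "chr2"
        if start + 999 <= autosome:
            cgis.append((GenomicInterval(chrom, start, start + 999,
                                         name=f"cgi_{i}"), "oocyte_cgi"))
    for i in range(20):
        start = 10_001 + i * 24_000
        if start + 999 <= xlen:
            cgis.append((GenomicInterval("chrX", start, start + 999,
                                         name=f"xcgi_{i}"), "x_cgi"))
    return MethylomePlan(chrom_lengths, cpg_spacing=50, domains=domains,
                         gdmrs=gdmrs, cgis=cgis)


def tiling_methylome_plan(n_tiles: int, tile_width: int = 10_000,
                          cpg_spacing: int = 1_000,
                          hyper_period: int = 16, hyper_per_period: int = 7,
                          chrom: str = "chrS") -> MethylomePlan:
    """A single-chromosome plan whose domains coincide with genome tiles.

    Used for tile-level calibration studies: each fixed-width tile is one
    domain, HyperD for ``hyper_per_period`` of every ``hyper_period``
    tiles (7/16 = 43.75%, matching the oocyte global level).
    """
    length = n_tiles * tile_width
    domains = []
    for i in range(n_tiles):
        cls = "HyperD" if (i % hyper_period) < hyper_per_period else "HypoD"
        start = i * tile_width + 1
        domains.append((GenomicInterval(chrom, start, start + tile_width - 1,
                                        name=f"{chrom}:D{i}"), cls))
    return MethylomePlan({chrom: length}, cpg_spacing=cpg_spacing,
                         domains=domains)


@dataclass
class MethylomeTruth:
    plan: MethylomePlan
    planted_dmrs: List[PlantedDMR]
    contamination: Dict[str, float]
    genotypes: Dict[str, str]            # sample_id -> genotype
    expected_global_cpg: float


def gen_methylomes(plan: Optional[MethylomePlan] = None,
                   n_per_genotype: Optional[Dict[str, int]] = None,
                   coverage_mean: float = 10.0,
                   contamination: Optional[Dict[str, float]] = None,
                   planted_dmrs: Optional[Sequence[PlantedDMR]] = None,
                   mapped_read_count: int = 6_000_000,
                   mapped_read_counts: Optional[Dict[str, int]] = None,
                   include_noncpg: bool = True,
                   seed: int = 0,
                   ) -> Tuple[Dict[str, MethylomeSample], MethylomeTruth]:
    """Simulate cytosine-call methylomes for several genotype groups.

    One Beta-distributed true level is drawn per CpG and shared by all
    genotypes, so genotype differences arise only from planted DMRs (and
    contamination); binomial counts at Poisson coverage are then drawn
    per sample. Contamination mixes the somatic profile into the true
    level at the given per-sample fraction before count sampling.
    """
    plan = plan if plan is not None else default_methylome_plan()
    n_per_genotype = dict(n_per_genotype or {"WT": 4, "Het": 4, "Null": 4})
    contamination = dict(contamination or {})
    planted_dmrs = list(planted_dmrs or [])
    rng = np.random.default_rng(seed)

    positions = plan.cpg_positions()
    oocyte = plan.oocyte_means()
    somatic = plan.somatic_means()
    conc = plan.concentration_of()

    base: Dict[str, np.ndarray] = {}
    for chrom in positions:
        mean = np.clip(oocyte[chrom], 1e-3, 1 - 1e-3)
        c = conc[chrom]
        base[chrom] = rng.beta(mean * c, (1 - mean) * c)

    def genotype_level(genotype: str) -> Dict[str, np.ndarray]:
        shifted = {c: arr.copy() for c, arr in base.items()}
        for dmr in planted_dmrs:
            if genotype not in dmr.genotypes:
                continue
            iv = dmr.interval
            pos = positions.get(iv.chrom)
            if pos is None:
                raise ValueError(f"planted DMR on unknown chrom {iv.chrom}")
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="right")
            shifted[iv.chrom][lo:hi] = np.clip(
                shifted[iv.chrom][lo:hi] + dmr.delta / 100.0, 1e-3, 1 - 1e-3)
        return shifted

    samples: Dict[str, MethylomeSample] = {}
    genotype_of: Dict[str, str] = {}
    for genotype in sorted(n_per_genotype):
        level = genotype_level(genotype)
        for j in range(n_per_genotype[genotype]):
            sample_id = f"{genotype}#{j + 1}"
            c = float(contamination.get(sample_id, 0.0))
            frames = []
            for chrom in positions:
                eff = (1 - c) * level[chrom] + c * somatic[chrom]
                cov = rng.poisson(coverage_mean, size=eff.shape)
                meth = rng.binomial(cov, eff)
                frames.append(pd.DataFrame({
                    "chrom": chrom, "pos": positions[chrom], "strand": "+",
                    "context": "CpG", "n_meth": meth, "n_unmeth": cov - meth}))
                if include_noncpg:
                    n_nc = int(len(positions[chrom]) * plan.noncpg_fraction)
                    if n_nc:
                        nc_pos = positions[chrom][:n_nc] + plan.cpg_spacing // 2
                        nc_cov = rng.poisson(coverage_mean, size=n_nc)
                        nc_meth = rng.binomial(nc_cov, plan.noncpg_level)
                        ctx = np.where(np.arange(n_nc) % 2 == 0, "CHH", "CHG")
                        frames.append(pd.DataFrame({
                            "chrom": chrom, "pos": nc_pos, "strand": "+",
                            "context": ctx, "n_meth": nc_meth,
                            "n_unmeth": nc_cov - nc_meth}))
            calls = pd.concat(frames, ignore_index=True)
            reads = (mapped_read_counts or {}).get(sample_id, mapped_read_count)
            samples[sample_id] = MethylomeSample(
                sample_id=sample_id, genotype=genotype, calls=calls,
                mapped_read_count=int(reads))
            genotype_of[sample_id] = genotype

    truth = MethylomeTruth(plan, planted_dmrs, contamination, genotype_of,
                           plan.expected_global_cpg())
    return samples, truth
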