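"""Canonical splice-junction read counting.

GV oocytes are transcriptionally quiescent and their cDNA libraries can
contain trans-spliced products, unprocessed RNA and DNA contamination
that surface as novel, non-annotated splices. The counting rule here is
deliberately strict: a read contributes to a gene's count only when every
splice it carries exactly matches an annotated intron of that gene
(coordinates compared at single-base resolution). Reads with any novel
junction are excluded and tallied; unspliced reads are tallied but not
counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .genomic_io import GeneModel, SamRecord, SamStats, SamStream

__all__ = [
    "IntronCatalog",
    "ReadClassification",
    "SpliceCountResult",
    "build_intron_catalog",
    "extract_junctions",
    "classify_read",
    "count_sample",
    "count_samples",
]

Junction = Tuple[int, int]


@dataclass
class IntronCatalog:
    """Exact intron coordinates -> gene ids, derived from annotation."""

    entries: Dict[Tuple[str, int, int], FrozenSet[str]]
    gene_ids: Tuple[str, ...]
    stranded: bool = False
    # entries keyed (chrom, start, end) when unstranded, else
    # (chrom, strand, start, end)

    def lookup(self, chrom: str, junction: Junction,
               strand: str = ".") -> Optional[FrozenSet[str]]:
        if self.stranded:
            return self.entries.get((chrom, strand, junction[0], junction[1]))
        return self.entries.get((chrom, junction[0], junction[1]))


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    status: str  # unspliced | canonical | noncanonical | ambiguous
    assigned_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.status == "canonical") != (self.assigned_gene is not None):
            raise ValueError("assigned_gene set iff status is canonical")


@dataclass
class SampleStats:
    sample_id: str
    total_records: int = 0
    skipped_unmapped_secondary_dup: int = 0
    unspliced: int = 0
    canonical_assigned: int = 0
    noncanonical_excluded: int = 0
    ambiguous_excluded: int = 0

    def check_conservation(self) -> None:
        parts = (self.skipped_unmapped_secondary_dup + self.unspliced
                 + self.canonical_assigned + self.noncanonical_excluded
                 + self.ambiguous_excluded)
        if parts != self.total_records:
            raise AssertionError(
                f"{self.sample_id}: stats categories sum to {parts}, "
                f"expected {self.total_records}")


@dataclass
class SpliceCountResult:
    """Gene x sample count matrix plus per-sample classification stats."""

    counts: pd.DataFrame          # index gene_id, columns sample_id
    stats: List[SampleStats] = field(default_factory=list)

    def __post_init__(self) -> None:
        for st in self.stats:
            st.check_conservation()
            if st.sample_id in self.counts.columns:
                col_sum = int(self.counts[st.sample_id].sum())
                if col_sum != st.canonical_assigned:
                    raise AssertionError(
                        f"{st.sample_id}: column sum {col_sum} != "
                        f"canonical_assigned {st.canonical_assigned}")

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stats])


def build_intron_catalog(genes: Sequence[GeneModel],
                         stranded: bool = False) -> IntronCatalog:
    """Derive every intron from consecutive exon pairs of every transcript.

    Intron = (previous exon end + 1, next exon start - 1). Identical
    intron coordinates contributed by several transcripts or genes merge
    into one entry carrying the union of gene ids.
    """
    entries: Dict[tuple, Set[str]] = {}
    for gene in genes:
        for tx_id, exons in gene.transcripts.items():
            for a, b in zip(exons, exons[1:]):
                if b.start <= a.end + 1:
                    raise ValueError(
                        f"zero/negative intron between exons of {tx_id} "
                        f"({gene.gene_id})")
                start, end = a.end + 1, b.start - 1
                key = ((gene.chrom, gene.strand, start, end) if stranded
                       else (gene.chrom, start, end))
                entries.setdefault(key, set()).add(gene.gene_id)
    return IntronCatalog(
        entries={k: frozenset(v) for k, v in entries.items()},
        gene_ids=tuple(sorted(g.gene_id for g in genes)),
        stranded=stranded,
    )


_CIGAR_OP_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MD=XN")


def extract_junctions(pos: int, cigar: str) -> List[Junction]:
    """Walk the CIGAR from the 1-based start, emitting one interval per N.

    The reference cursor advances through M, D, =, X and N; I, S, H and P
    consume no reference. An N of length L at cursor c spans (c, c+L-1),
    i.e. the skipped (intronic) reference bases inclusive.
    """
    if cigar == "*":
        return []
    consumed = 0
    cursor = pos
    junctions: List[Junction] = []
    for m in _CIGAR_OP_RE.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        consumed += m.end() - m.start()
        if op == "N":
            if length == 0:
                raise ValueError(f"zero-length N in CIGAR {cigar!r}")
            junctions.append((cursor, cursor + length - 1))
        if op in _REF_CONSUMING:
            cursor += length
    if consumed != len(cigar):
        raise ValueError(f"invalid CIGAR {cigar!r}")
    return junctions


def classify_read(read_id: str, junctions: Sequence[Junction], chrom: str,
                  catalog: IntronCatalog, strand: str = ".") -> ReadClassification:
    """Apply the exact-match rule to one read's junction set.

    No junctions -> unspliced. Any junction absent from the catalog ->
    noncanonical. All annotated: the read is assigned iff the gene sets
    of its junctions intersect in exactly one gene, else ambiguous.
    """
    if not junctions:
        return ReadClassification(read_id, "unspliced")
    gene_sets = []
    for j in junctions:
        genes = catalog.lookup(chrom, j, strand)
        if genes is None:
            return ReadClassification(read_id, "noncanonical")
        gene_sets.append(genes)
    common: FrozenSet[str] = gene_sets[0]
    for s in gene_sets[1:]:
        common = common & s
    if len(common) == 1:
        return ReadClassification(read_id, "canonical", next(iter(common)))
    return ReadClassification(read_id, "ambiguous")


def _record_strand(flag: int) -> str:
    return "-" if flag & 0x10 else "+"


def count_sample(alignments: SamStream | Iterable[SamRecord],
                 catalog: IntronCatalog,
                 sample_id: str) -> Tuple[pd.Series, SampleStats]:
    """Classify every record of one sample and count canonical reads per gene.

    Returns the per-gene count column (zero-filled over the full annotation
    gene universe) and the stats record; the conservation identity is
    asserted before returning.
    """
    counts = {g: 0 for g in catalog.gene_ids}
    stats = SampleStats(sample_id)
    for rec in alignments:
        junctions = extract_junctions(rec.pos, rec.cigar)
        cls = classify_read(rec.read_id, junctions, rec.chrom, catalog,
                            _record_strand(rec.flag))
        if cls.status == "unspliced":
            stats.unspliced += 1
        elif cls.status == "canonical":
            stats.canonical_assigned += 1
            counts[cls.assigned_gene] = counts.get(cls.assigned_gene, 0) + 1
        elif cls.status == "noncanonical":
            stats.noncanonical_excluded += 1
        else:
            stats.ambiguous_excluded += 1
    if isinstance(alignments, SamStream):
        stats.skipped_unmapped_secondary_dup = alignments.stats.skipped
        stats.total_records = alignments.stats.total_records
    else:
        stats.total_records = (stats.unspliced + stats.canonical_assigned
                               + stats.noncanonical_excluded
                               + stats.ambiguous_excluded)
    stats.check_conservation()
    return pd.Series(counts, name=sample_id, dtype=int), stats


def count_samples(sample_streams: Dict[str, SamStream | Iterable[SamRecord]],
                  catalog: IntronCatalog) -> SpliceCountResult:
    """Count every sample against one catalog into a joint matrix."""
    columns = []
    stats = []
    for sample_id, stream in sample_streams.items():
        col, st = count_sample(stream, catalog, sample_id)
        columns.append(col)
        stats.append(st)
    counts = (pd.concat(columns, axis=1) if columns
              else pd.DataFrame(index=list(catalog.gene_ids)))
    counts.index.name = "gene_id"
    return SpliceCountResult(counts=counts.fillna(0).astype(int), stats=stats)
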