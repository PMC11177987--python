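"""Readers/writers for the text formats the pipeline touches.

One coordinate convention is used internally everywhere: 1-based,
inclusive on both ends (the GTF/SAM convention). BED input/output is the
single place where 0-based half-open coordinates appear, and conversion
happens at the parse/write boundary.
"""

from __future__ import annotations

import dataclasses
import io
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, TextIO, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "MethylomeSample",
    "SamRecord",
    "SamStats",
    "SamStream",
    "ParseError",
    "parse_gtf",
    "parse_sam",
    "parse_cytosine_report",
    "write_cytosine_report",
    "parse_regions",
    "write_regions",
    "write_table",
]

STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Malformed input in one of the supported text formats."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


@dataclass
class GeneModel:
    """Exon structure of one gene: transcripts as ordered exon lists."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: Dict[str, List[GenomicInterval]]

    @property
    def gene_span(self) -> GenomicInterval:
        starts = [e.start for exons in self.transcripts.values() for e in exons]
        ends = [e.end for exons in self.transcripts.values() for e in exons]
        return GenomicInterval(self.chrom, min(starts), max(ends),
                               self.strand, self.gene_id)

    @property
    def tss(self) -> int:
        span = self.gene_span
        return span.end if self.strand == "-" else span.start

    def __post_init__(self) -> None:
        for tx_id, exons in self.transcripts.items():
            exons.sort(key=lambda e: e.start)
            for a, b in zip(exons, exons[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping exons in transcript {tx_id} of {self.gene_id}")
            for e in exons:
                if e.chrom != self.chrom:
                    raise ValueError(
                        f"exon on {e.chrom} in gene {self.gene_id} on {self.chrom}")


CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str),
        "pos": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
        "context": pd.Series(dtype=str),
        "n_meth": pd.Series(dtype=np.int64),
        "n_unmeth": pd.Series(dtype=np.int64),
    })


@dataclass
class MethylomeSample:
    """Per-cytosine methylation calls for one library.

    ``calls`` has columns chrom, pos (1-based), strand, context
    (CpG/CHG/CHH), n_meth, n_unmeth. Zero-coverage rows are retained.
    """

    sample_id: str
    genotype: str = "NA"
    calls: pd.DataFrame = field(default_factory=_empty_calls)
    mapped_read_count: int = 0
    _cpg_index: Optional[dict] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"calls missing columns {missing}")
        if (self.calls[["n_meth", "n_unmeth"]].to_numpy() < 0).any():
            raise ValueError("negative methylation counts")
        if self.calls.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) in calls")

    def context_calls(self, context: str) -> pd.DataFrame:
        return self.calls[self.calls["context"] == context]

    def cpg_index(self) -> Dict[str, tuple]:
        """Per-chrom sorted CpG arrays: (pos, n_meth, n_unmeth)."""
        if self._cpg_index is None:
            idx = {}
            cpg = self.context_calls("CpG")
            for chrom, sub in cpg.groupby("chrom", sort=True, observed=True):
                sub = sub.sort_values("pos")
                idx[str(chrom)] = (sub["pos"].to_numpy(np.int64),
                                   sub["n_meth"].to_numpy(np.int64),
                                   sub["n_unmeth"].to_numpy(np.int64))
            object.__setattr__(self, "_cpg_index", idx)
        return self._cpg_index


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _as_lines(source: Union[str, TextIO, Iterable[str]]) -> Iterable[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def parse_gtf(source: Union[str, TextIO, Iterable[str]]) -> List[GeneModel]:
    """Parse GTF text into :class:`GeneModel` objects.

    Only ``exon`` features are used; exons are grouped by transcript_id
    within gene_id and stored sorted by start. Unknown attribute keys are
    ignored; a missing gene_id or transcript_id on an exon is an error.
    """
    genes: Dict[str, dict] = {}
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ParseError(f"GTF line {lineno}: expected >=9 fields, got {len(parts)}")
        chrom, _, feature, start_s, end_s, _, strand, _, attrs = parts[:9]
        if feature != "exon":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"GTF line {lineno}: non-integer coordinates") from exc
        if end < start:
            raise ParseError(f"GTF line {lineno}: end < start")
        attr = dict(_ATTR_RE.findall(attrs))
        if not attr and attrs.strip():
            raise ParseError(f"GTF line {lineno}: malformed attribute string")
        gene_id = attr.get("gene_id")
        tx_id = attr.get("transcript_id")
        if gene_id is None:
            raise ParseError(f"GTF line {lineno}: exon without gene_id")
        if tx_id is None:
            raise ParseError(f"GTF line {lineno}: exon without transcript_id")
        entry = genes.setdefault(gene_id, {"chrom": chrom, "strand": strand, "tx": {}})
        if entry["chrom"] != chrom:
            raise ParseError(f"GTF line {lineno}: gene {gene_id} spans chromosomes")
        entry["tx"].setdefault(tx_id, []).append(
            GenomicInterval(chrom, start, end, strand if strand in STRANDS else "."))
    return [GeneModel(gid, e["chrom"], e["strand"] if e["strand"] in STRANDS else ".",
                      e["tx"])
            for gid, e in genes.items()]


# ---------------------------------------------------------------------------
# SAM

@dataclass(frozen=True)
class SamRecord:
    read_id: str
    flag: int
    chrom: str
    pos: int          # 1-based leftmost aligned position
    cigar: str


@dataclass
class SamStats:
    total_records: int = 0
    yielded: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_duplicate: int = 0
    skipped_supplementary: int = 0

    @property
    def skipped(self) -> int:
        return (self.skipped_unmapped + self.skipped_secondary
                + self.skipped_duplicate + self.skipped_supplementary)


_CIGAR_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


class SamStream:
    """Iterator over primary, mapped, non-duplicate SAM records.

    Filtered-record tallies accumulate in :attr:`stats` as the stream is
    consumed; the conservation identity ``yielded + skipped ==
    total_records`` holds at any point.
    """

    def __init__(self, source: Union[str, TextIO, Iterable[str]]):
        self._lines = _as_lines(source)
        self.stats = SamStats()

    def __iter__(self) -> Iterator[SamRecord]:
        for line in self._lines:
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ParseError(f"SAM record with {len(parts)} fields: {line[:60]!r}")
            read_id = parts[0]
            try:
                flag = int(parts[1])
                pos = int(parts[3])
            except ValueError as exc:
                raise ParseError(f"SAM record {read_id}: non-integer flag/pos") from exc
            self.stats.total_records += 1
            if flag & FLAG_UNMAPPED:
                self.stats.skipped_unmapped += 1
                continue
            if flag & FLAG_SECONDARY:
                self.stats.skipped_secondary += 1
                continue
            if flag & FLAG_DUPLICATE:
                self.stats.skipped_duplicate += 1
                continue
            if flag & FLAG_SUPPLEMENTARY:
                self.stats.skipped_supplementary += 1
                continue
            cigar = parts[5]
            if cigar != "*" and not _CIGAR_RE.match(cigar):
                raise ParseError(f"SAM record {read_id}: invalid CIGAR {cigar!r}")
            self.stats.yielded += 1
            yield SamRecord(read_id, flag, parts[2], pos, cigar)


def parse_sam(source: Union[str, TextIO, Iterable[str]]) -> SamStream:
    """Wrap SAM text in a filtered record stream with skip tallies."""
    return SamStream(source)


# ---------------------------------------------------------------------------
# Bismark-style cytosine report

_CONTEXTS = {"CpG", "CHG", "CHH", "CG", "Unknown"}


def parse_cytosine_report(source: Union[str, TextIO, Iterable[str]],
                          sample_id: str = "sample",
                          genotype: str = "NA",
                          mapped_read_count: int = 0) -> MethylomeSample:
    """Parse a coverage2cytosine-style report into a :class:`MethylomeSample`.

    Expected columns: chrom, 1-based position, strand, count-methylated,
    count-unmethylated, context, [trinucleotide]. All rows are loaded,
    including zero-coverage ones.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    try:
        df = pd.read_csv(
            source, sep="\t", header=None, comment="#",
            names=["chrom", "pos", "strand", "n_meth", "n_unmeth",
                   "context", "tri"],
            usecols=[0, 1, 2, 3, 4, 5],
            dtype={"chrom": str, "pos": np.int64, "strand": str,
                   "n_meth": np.int64, "n_unmeth": np.int64, "context": str},
        )
    except pd.errors.EmptyDataError:
        df = _empty_calls()
    except (ValueError, TypeError) as exc:
        raise ParseError(f"malformed cytosine report: {exc}") from exc
    if len(df):
        if (df[["n_meth", "n_unmeth"]].to_numpy() < 0).any():
            raise ParseError("negative counts in cytosine report")
        df["context"] = df["context"].replace({"CG": "CpG"})
        df = df[["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]]
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ParseError("duplicate (chrom, pos, strand) in cytosine report")
    return MethylomeSample(sample_id=sample_id, genotype=genotype,
                           calls=df.reset_index(drop=True),
                           mapped_read_count=mapped_read_count)


def write_cytosine_report(sample: MethylomeSample, path=None) -> Optional[str]:
    """Serialize a sample back to the 7-column cytosine-report layout.

    Returns the text when ``path`` is None. The trinucleotide column is
    synthesized from the context (it is not retained on parse).
    """
    tri = {"CpG": "CGA", "CHG": "CAG", "CHH": "CAT"}
    rows = sample.calls.sort_values(["chrom", "pos", "strand"])
    lines = [
        f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.n_meth}\t{r.n_unmeth}\t"
        f"{r.context}\t{tri.get(r.context, 'NNN')}"
        for r in rows.itertuples()
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


# ---------------------------------------------------------------------------
# BED regions

def parse_regions(source: Union[str, TextIO, Iterable[str]],
                  label: str = "regions") -> List[GenomicInterval]:
    """Parse BED (0-based half-open) into internal 1-based closed intervals.

    Column 4, when present, is kept as the region id; column 6 as strand.
    """
    out: List[GenomicInterval] = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{label} line {lineno}: BED needs >=3 columns")
        chrom = parts[0]
        try:
            bed_start, bed_end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{label} line {lineno}: non-integer coordinates") from exc
        if bed_end <= bed_start:
            raise ParseError(f"{label} line {lineno}: end <= start in BED")
        name = parts[3] if len(parts) >= 4 and parts[3] != "." else None
        strand = parts[5] if len(parts) >= 6 and parts[5] in STRANDS else "."
        out.append(GenomicInterval(chrom, bed_start + 1, bed_end, strand, name))
    return out


def write_regions(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED6 (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                     f"{iv.name or '.'}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Tabular output

_PCT_SUFFIXES = ("_pct", "_percent", "_methylation")
_PCT_NAMES = {"meth_ref", "meth_test", "delta", "meth_delta", "x_cgi_methylation"}


def _format_value(key: str, value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if key.endswith(_PCT_SUFFIXES) or key in _PCT_NAMES:
            return f"{value:.1f}"
        return f"{value:.6g}"
    return str(value)


def write_table(records, path) -> None:
    """Write records (dataclasses, dicts, or a DataFrame) as a TSV.

    Percentages are printed on the 0-100 scale with 1 decimal. Rows are
    ordered deterministically by (chrom, start, id-like field) when those
    fields exist, so re-running on the same input is byte-identical.
    """
    if isinstance(records, pd.DataFrame):
        rows = records.to_dict("records")
    else:
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in records]
    if rows:
        schema = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != schema:
                raise ValueError("records do not share a field schema")
    else:
        schema = getattr(records, "columns", None)
        schema = list(schema) if schema is not None else []

    def sort_key(r):
        key = []
        for f in ("chrom", "start"):
            if f in r:
                key.append(r[f])
        for f in ("region_id", "feature_id", "gene_id", "sample_id", "name",
                  "domain_id"):
            if f in r:
                key.append(str(r[f]))
                break
        return tuple(key) if key else ()

    rows.sort(key=sort_key)
    with open(path, "w") as fh:
        if schema:
            fh.write("\t".join(schema) + "\n")
        for r in rows:
            fh.write("\t".join(_format_value(k, v) for k, v in r.items()) + "\n")
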