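"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are normalized to 0-based half-open intervals at the I/O
boundary: GTF/GFF3 are 1-based inclusive on disk, BED and the internal
representation are 0-based half-open.  Methylation reports carry 1-based
positions on disk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import pandas as pd

STRANDS = ("+", "-", ".")
METH_CONTEXTS = ("CG", "CHG", "CHH")
HIT_DATABASES = ("EST", "ncRNA", "protein")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bases with *other*; 0 if on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript; the unit of classification and filtering."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "novel"  # {"coding", "novel"}

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon {e} disagrees with span "
                    f"{self.interval} on chrom/strand"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons not sorted/non-overlapping"
                )
        if (
            self.interval.start != self.exons[0].start
            or self.interval.end != self.exons[-1].end
        ):
            raise ValueError(f"{self.transcript_id}: span does not match exon extent")

    @classmethod
    def from_exons(
        cls,
        transcript_id: str,
        gene_id: str,
        exons: Sequence[GenomicInterval],
        biotype: str = "novel",
    ) -> "TranscriptModel":
        """Build a transcript, sorting exons and deriving the span."""
        exs = tuple(sorted(exons, key=lambda e: e.start))
        span = GenomicInterval(
            exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand
        )
        return cls(transcript_id, gene_id, span, exs, biotype)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def unstranded(self) -> bool:
        return self.strand == "."

    @property
    def length(self) -> int:
        """Transcript length = summed exon lengths (not the genomic span)."""
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


@dataclass(frozen=True)
class TEFeature:
    """A repetitive-element annotation with its family label."""

    interval: GenomicInterval
    family: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("TE family must be non-empty")


@dataclass(frozen=True)
class HomologyHit:
    """One database hit for a query transcript (BLAST-style summary row)."""

    query_id: str
    database: str  # one of HIT_DATABASES
    e_value: float
    identity_pct: float
    alignment_length: int
    query_coverage_pct: float

    def __post_init__(self) -> None:
        if self.database not in HIT_DATABASES:
            raise ValueError(f"unknown hit database {self.database!r}")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if not (0 <= self.identity_pct <= 100):
            raise ValueError("identity_pct must be in [0, 100]")
        if self.alignment_length <= 0:
            raise ValueError("alignment_length must be positive")
        if not (0 <= self.query_coverage_pct <= 100):
            raise ValueError("query_coverage_pct must be in [0, 100]")


@dataclass(frozen=True)
class MethylationRecord:
    """One cytosine with context and methylated/unmethylated read counts.

    ``pos`` is 0-based internally; files carry 1-based positions.
    """

    chrom: str
    pos: int
    strand: str
    meth_count: int
    unmeth_count: int
    context: str

    def __post_init__(self) -> None:
        if self.context not in METH_CONTEXTS:
            raise ValueError(f"unknown methylation context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: malformed GTF attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    1-based inclusive coordinates are converted to 0-based half-open; exons
    are grouped per ``transcript_id`` and sorted by start.  Transcripts
    without a strand assignment are kept with strand "." (check the
    ``unstranded`` property) rather than silently dropped.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from exc
            if strand not in STRANDS:
                raise ValueError(f"{path}: line {lineno}: invalid strand {strand!r}")
            attrs = _parse_gtf_attributes(attr, lineno)
            if "transcript_id" not in attrs:
                raise ValueError(f"{path}: line {lineno}: missing transcript_id")
            tid = attrs["transcript_id"]
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                gene_of[tid] = attrs.get("gene_id", tid)
            exons[tid].append(GenomicInterval(chrom, start_i - 1, end_i, strand))
    out = []
    for tid in order:
        out.append(
            TranscriptModel.from_exons(tid, gene_of[tid], exons[tid], biotype="novel")
        )
    return out


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "lncflow",
    header: Sequence[str] = (),
) -> None:
    """Write transcripts as GTF (transcript + exon rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        source,
                        "transcript",
                        str(t.interval.start + 1),
                        str(t.interval.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# GFF3 reference annotation
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_reference_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read protein-coding transcript models from a GFF3 reference.

    Only ``mRNA`` features (and their exons, resolved via Parent) are
    retained, with ``biotype="coding"``.  Exons whose Parent is a non-coding
    feature present in the file are excluded with it; an exon whose Parent is
    never defined raises.
    """
    mrna_gene: dict[str, str] = {}
    mrna_strand: dict[str, str] = {}
    mrna_chrom: dict[str, str] = {}
    other_ids: set[str] = set()
    exon_rows: list[tuple[int, str, int, int, str]] = []  # lineno, parent, s, e, chrom
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 fields, got {len(fields)}"
                )
            chrom, _src, ftype, start, end, _score, strand, _phase, attr = fields
            attrs = _parse_gff3_attributes(attr)
            if ftype == "mRNA":
                mid = attrs.get("ID")
                if mid is None:
                    raise ValueError(f"{path}: line {lineno}: mRNA without ID")
                mrna_gene[mid] = attrs.get("Parent", mid)
                mrna_strand[mid] = strand
                mrna_chrom[mid] = chrom
                order.append(mid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(
                        f"{path}: line {lineno}: exon without Parent attribute"
                    )
                exon_rows.append((lineno, parent, int(start), int(end), chrom))
            else:
                fid = attrs.get("ID")
                if fid is not None:
                    other_ids.add(fid)
    exons: dict[str, list[GenomicInterval]] = {mid: [] for mid in order}
    for lineno, parent, start, end, chrom in exon_rows:
        for pid in parent.split(","):
            if pid in exons:
                exons[pid].append(
                    GenomicInterval(chrom, start - 1, end, mrna_strand[pid])
                )
            elif pid not in other_ids:
                raise ValueError(
                    f"{path}: line {lineno}: orphan exon (unknown Parent {pid!r})"
                )
    out = []
    for mid in order:
        if not exons[mid]:
            raise ValueError(f"{path}: mRNA {mid} has no exons")
        out.append(
            TranscriptModel.from_exons(mid, mrna_gene[mid], exons[mid], biotype="coding")
        )
    return out


def write_reference_gff3(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "lncflow",
    header: Sequence[str] = (),
) -> None:
    """Write coding transcripts as a gene/mRNA/exon GFF3 hierarchy."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header:
            fh.write(f"# {line}\n")
        for gene_id, ts in by_gene.items():
            g_start = min(t.interval.start for t in ts)
            g_end = max(t.interval.end for t in ts)
            chrom, strand = ts[0].chrom, ts[0].strand
            fh.write(
                f"{chrom}\t{source}\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for t in ts:
                fh.write(
                    f"{chrom}\t{source}\tmRNA\t{t.interval.start + 1}\t"
                    f"{t.interval.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\tParent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# BED (TEs), hit tables, methylation reports, expression, misc tables
# ---------------------------------------------------------------------------

def read_te_bed(path: str | Path) -> list[TEFeature]:
    """Read a BED6+1 TE track (column 7 = family); BED is already 0-based."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(
                    f"{path}: line {lineno}: BED6+1 needs 7 columns, got {len(fields)}"
                )
            chrom, start, end, _name, _score, strand, family = fields[:7]
            out.append(
                TEFeature(
                    GenomicInterval(chrom, int(start), int(end), strand), family
                )
            )
    return out


def write_te_bed(tes: Iterable[TEFeature], path: str | Path,
                 header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for i, te in enumerate(tes):
            iv = te.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tTE{i}\t0\t{iv.strand}\t"
                f"{te.family}\n"
            )


def read_hits(path: str | Path) -> list[HomologyHit]:
    """Read a tab-delimited homology-hit table with a header row."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "query_id", "database", "e_value", "identity_pct",
        "alignment_length", "query_coverage_pct",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: hit table missing columns {sorted(missing)}")
    return [
        HomologyHit(
            query_id=str(r.query_id),
            database=str(r.database),
            e_value=float(r.e_value),
            identity_pct=float(r.identity_pct),
            alignment_length=int(r.alignment_length),
            query_coverage_pct=float(r.query_coverage_pct),
        )
        for r in df.itertuples(index=False)
    ]


def write_hits(hits: Iterable[HomologyHit], path: str | Path,
               header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write(
            "query_id\tdatabase\te_value\tidentity_pct\t"
            "alignment_length\tquery_coverage_pct\n"
        )
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.database}\t{h.e_value:g}\t{h.identity_pct:g}\t"
                f"{h.alignment_length}\t{h.query_coverage_pct:g}\n"
            )


def read_methylation_report(path: str | Path) -> Iterator[MethylationRecord]:
    """Stream per-cytosine records; 1-based file positions become 0-based."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(fields)}"
                )
            chrom, pos, strand, meth, unmeth, context = fields
            if context not in METH_CONTEXTS:
                raise ValueError(
                    f"{path}: line {lineno}: unknown context {context!r}"
                )
            yield MethylationRecord(
                chrom=chrom,
                pos=int(pos) - 1,
                strand=strand,
                meth_count=int(meth),
                unmeth_count=int(unmeth),
                context=context,
            )


def write_methylation_report(records: Iterable[MethylationRecord],
                             path: str | Path,
                             header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.meth_count}\t"
                f"{r.unmeth_count}\t{r.context}\n"
            )


def read_expression(path: str | Path) -> pd.DataFrame:
    """FPKM matrix: rows = transcripts (index), columns = samples."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Design table with columns sample, tissue, stage ('.' = not applicable)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample", "tissue", "stage"):
        if col not in df.columns:
            raise ValueError(f"{path}: design table missing column {col!r}")
    return df


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    return sizes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning id -> uppercase sequence."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(df: pd.DataFrame, path: str | Path,
                header: Sequence[str] = (), index: bool = False) -> None:
    """Write a tab-delimited table, preceded by '#' comment header lines."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)
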