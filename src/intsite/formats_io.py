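"""Readers/writers for the external formats the pipeline touches.

Covers FASTQ (plain or gzip), genome FASTA, the 6-column gene BED
(chromosome, start, end, accession, symbol, strand), SAM interchange with an
external aligner backend, and the tab-delimited result tables.  Also defines
the canonical in-memory record types shared across the pipeline.

All internal coordinates are 0-based half-open (BED convention); only
user-facing integration-site positions are 1-based.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Dict, Iterable, Iterator, List, Optional

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FormatError(ValueError):
    """Malformed input file (FASTQ/BED/FASTA/summary)."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class SequenceRead:
    """One FASTQ record; ``mate`` is 0 for single-end, 1/2 for paired mates."""

    read_id: str
    bases: str
    quality: Optional[str] = None
    mate: int = 0

    def __post_init__(self):
        if not self.read_id:
            raise FormatError("SequenceRead: empty read id")
        if not self.bases:
            raise FormatError(f"SequenceRead {self.read_id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise FormatError(
                f"SequenceRead {self.read_id}: quality length "
                f"{len(self.quality)} != sequence length {len(self.bases)}"
            )
        if self.mate not in (0, 1, 2):
            raise FormatError(f"SequenceRead {self.read_id}: mate must be 0/1/2")


@dataclass(frozen=True)
class GeneRecord:
    """One gene model from a BED6 line (0-based half-open span)."""

    contig: str
    start: int
    end: int
    accession: str
    symbol: str
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"GeneRecord {self.accession}: invalid span "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"GeneRecord {self.accession}: strand must be + or -")


@dataclass
class ReferenceGenome:
    """Ordered contig name -> uppercase sequence map."""

    contigs: Dict[str, str]

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"ReferenceGenome: contig {name} is empty")

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


@dataclass(frozen=True)
class PrimerSpec:
    """Primer/adaptor sequences from library preparation.

    ``tr_primer`` is the 5' terminal-repeat primer whose 3' end abuts the
    vector/genome junction.  ``distal_primer`` is the 3' primer/adaptor;
    unless ``distal_is_read_strand`` is set, its reverse complement is the
    form expected at read 3' ends.  ``read2_adaptor`` anchors the 5' end of
    mate 2 in paired-end mode.
    """

    tr_primer: str
    distal_primer: str
    read2_adaptor: Optional[str] = None
    distal_is_read_strand: bool = False

    def __post_init__(self):
        if len(self.tr_primer) < 10:
            raise ValueError("PrimerSpec: tr_primer must be >= 10 bases")
        for name in ("tr_primer", "distal_primer", "read2_adaptor"):
            seq = getattr(self, name)
            if seq is not None and (not seq or set(seq) - set("ACGT")):
                raise ValueError(f"PrimerSpec: {name} must be non-empty over ACGT")


# ---------------------------------------------------------------------------
# FASTQ


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, mate: int = 0) -> Iterator[SequenceRead]:
    """Stream SequenceReads from a (possibly gzipped) 4-line FASTQ file.

    Bases are uppercased; a malformed record raises FormatError naming the
    1-based record index.
    """
    with _open_text(path) as handle:
        parser = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"{path}: record {index + 1}: {exc}") from exc
            index += 1
            read_id = title.split()[0] if title.split() else ""
            try:
                yield SequenceRead(read_id, seq.upper(), qual, mate)
            except FormatError as exc:
                raise FormatError(f"{path}: record {index}: {exc}") from exc


def write_fastq(reads: Iterable[SequenceRead], path) -> None:
    with _open_text(path, "wt") as out:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.bases)
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_genome_fasta(path) -> ReferenceGenome:
    contigs: Dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in contigs:
                raise FormatError(f"{path}: duplicate contig name {record.id}")
            contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(contigs)


def write_genome_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in genome.contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene BED


def read_gene_bed(path) -> List[GeneRecord]:
    """Parse a 6-column gene BED (chrom, start, end, accession, symbol, strand).

    Lines starting with '#' or 'track' (and blank lines) are skipped.  Any
    other malformed line raises FormatError with its 1-based line number.
    """
    genes: List[GeneRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >= 6 columns")
            contig, start_s, end_s, accession, symbol, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            try:
                genes.append(GeneRecord(contig, start, end, accession, symbol, strand))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_gene_bed(genes: Iterable[GeneRecord], path) -> None:
    with _open_text(path, "wt") as out:
        for g in genes:
            out.write(
                f"{g.contig}\t{g.start}\t{g.end}\t{g.accession}\t{g.symbol}\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# result tables

IS_TABLE_HEADER = (
    "contig",
    "position",
    "strand",
    "read_count",
    "class",
    "accession",
    "symbol",
    "tss_distance",
)


def write_is_table(sites, path) -> None:
    """Write the final annotated integration-site table (tab-delimited .txt).

    One row per site: contig, 1-based position, strand, supporting-read
    count, class, nearest-gene accession/symbol and signed TSS distance
    ('NA' when no gene exists on the contig).
    """
    with _open_text(path, "wt") as out:
        out.write("\t".join(IS_TABLE_HEADER) + "\n")
        for a in sites:
            acc = a.accession if a.accession is not None else "NA"
            sym = a.symbol if a.symbol is not None else "NA"
            dist = str(a.tss_distance) if a.tss_distance is not None else "NA"
            out.write(
                f"{a.site.contig}\t{a.site.position}\t{a.site.strand}\t"
                f"{a.site.read_count}\t{a.category.name}\t{acc}\t{sym}\t{dist}\n"
            )


# ---------------------------------------------------------------------------
# SAM interchange (external aligner backend)


def write_hits_sam(hits_by_read: Dict[str, list], genome: ReferenceGenome, path) -> None:
    """Dump alignment hits to SAM (one record per placement, SEQ omitted).

    Used for interchange with/around an external aligner; the first placement
    of a read is primary, the rest are flagged secondary.  Mismatch counts
    are carried in the NM tag.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in genome.lengths().items()],
    }
    names = list(genome.contigs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, hits in hits_by_read.items():
            for i, hit in enumerate(hits):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = read_id
                seg.reference_id = names.index(hit.contig)
                seg.reference_start = hit.start
                seg.cigarstring = f"{hit.end - hit.start}M"
                seg.flag = (16 if hit.strand == "-" else 0) | (256 if i > 0 else 0)
                seg.mapping_quality = 255
                seg.set_tag("NM", int(hit.mismatches))
                out.write(seg)


def read_sam_hits(path) -> Dict[str, list]:
    """Read end-to-end placements back from a SAM file.

    Returns read_id -> list of AlignmentHit (import deferred to avoid a
    module cycle).  Unmapped records are skipped; every mapped record
    (primary or secondary) counts as one placement.
    """
    from .align_filter import AlignmentHit

    hits: Dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                hits.setdefault(seg.query_name, [])
                continue
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            hits.setdefault(seg.query_name, []).append(
                AlignmentHit(
                    read_id=seg.query_name,
                    contig=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    strand="-" if seg.is_reverse else "+",
                    mismatches=int(nm),
                )
            )
    return hits
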