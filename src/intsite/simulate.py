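"""Synthetic junction-fragment fixtures with planted ground truth.

Emulates the amplicon library the pipeline consumes: a random multi-contig
genome carrying non-overlapping stranded gene models; planted integration
events; junction fragments of 100-400 bp (terminal-repeat primer, host
genomic sequence, distal adaptor); PCR duplication with a per-site
duplication factor; a configurable fraction of "into-vector" decoy
amplicons whose post-primer content is vector sequence absent from the
genome; and per-base substitution error.  Paired-end mode adds an inward
mate reading back from the fragment's far end behind the read-2 adaptor.

Every fixture is byte-reproducible from its seed, and each planted site
carries its oracle-computed annotation category so all pipeline stages have
known-answer tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .annotate import classify_site_bruteforce
from .formats_io import (
    GeneRecord,
    PrimerSpec,
    ReferenceGenome,
    SequenceRead,
    write_fastq,
    write_gene_bed,
    write_genome_fasta,
)
from .is_call import IntegrationSite
from .sequtil import revcomp

# fixed default primers: an LTR-style TR primer, a sequencing adaptor as the
# distal primer, and a transposase-style read-2 anchor
DEFAULT_TR_PRIMER = "ACCTGCAGGCATGCAAGCTTGGCGT"
DEFAULT_DISTAL_PRIMER = "AGATCGGAAGAGCACACGTC"
DEFAULT_READ2_ADAPTOR = "CTGTCTCTTATACACATCTG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_EXCLUSION_K = 30  # vector must share no exact 30-mer with the genome


class SimConfigError(ValueError):
    """Unsatisfiable or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for a simulated junction-fragment library."""

    seed: int = 0
    genome_len: int = 1_000_000
    n_contigs: int = 2
    n_genes: int = 200
    gene_len_range: Tuple[int, int] = (500, 4000)
    n_sites: int = 150
    dup_factor_range: Tuple[int, int] = (1, 50)
    decoy_fraction: float = 0.3
    error_rate: float = 0.0
    read_len_range: Tuple[int, int] = (100, 300)
    fragment_len_range: Tuple[int, int] = (100, 400)  # primers included
    mode: str = "single"
    primers: PrimerSpec = field(
        default_factory=lambda: PrimerSpec(
            DEFAULT_TR_PRIMER, DEFAULT_DISTAL_PRIMER, DEFAULT_READ2_ADAPTOR
        )
    )
    vector_len: int = 800
    edge_margin: int = 1000  # min distance of planted sites from contig ends
    tss_window: int = 2500

    def validate(self) -> None:
        for name in ("gene_len_range", "dup_factor_range", "read_len_range",
                     "fragment_len_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise SimConfigError(f"{name} must be an ordered positive range")
        if not (0 <= self.decoy_fraction < 1):
            raise SimConfigError("decoy_fraction must be in [0, 1)")
        if not (0 <= self.error_rate < 1):
            raise SimConfigError("error_rate must be in [0, 1)")
        if self.mode not in ("single", "paired"):
            raise SimConfigError("mode must be 'single' or 'paired'")
        if self.mode == "paired" and self.primers.read2_adaptor is None:
            raise SimConfigError("paired mode requires a read2_adaptor")
        if self.vector_len < 500:
            raise SimConfigError("vector_len must be >= 500")
        overhead = len(self.primers.tr_primer) + len(self.primers.distal_primer)
        if self.fragment_len_range[0] - overhead < 35:
            raise SimConfigError(
                "fragment_len_range too short: fragments must leave >= 35 bp "
                "of genomic sequence after the primers"
            )
        if self.read_len_range[0] < len(self.primers.tr_primer) + 35:
            raise SimConfigError(
                "read_len_range too short to cover the TR primer plus a "
                "mappable genomic stretch"
            )
        if self.fragment_len_range[1] > self.edge_margin:
            raise SimConfigError("fragment_len_range must fit within edge_margin")
        if self.genome_len < self.n_contigs * (2 * self.edge_margin + 100):
            raise SimConfigError("genome too small for the requested contigs")


@dataclass(frozen=True)
class TruthRecord:
    contig: str
    position: int  # 1-based
    strand: str
    dup_factor: int
    expected_category: str
    expected_symbol: Optional[str]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def make_reference(cfg: SimConfig) -> Tuple[ReferenceGenome, List[GeneRecord]]:
    """Random uniform genome plus non-overlapping stranded gene models.

    Genes are placed by splitting each contig's free space into random gaps
    (multinomial composition), which always succeeds when the drawn gene
    lengths fit; otherwise a SimConfigError is raised.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    base_len = cfg.genome_len // cfg.n_contigs
    contig_lens = [base_len] * cfg.n_contigs
    contig_lens[-1] += cfg.genome_len - base_len * cfg.n_contigs
    contigs = {
        f"chr{i + 1}": _random_seq(rng, n) for i, n in enumerate(contig_lens)
    }
    genome = ReferenceGenome(contigs)

    if cfg.n_genes == 0:
        return genome, []
    # distribute genes across contigs proportionally to length
    per_contig = [int(round(cfg.n_genes * n / cfg.genome_len)) for n in contig_lens]
    while sum(per_contig) < cfg.n_genes:
        per_contig[int(np.argmin(per_contig))] += 1
    while sum(per_contig) > cfg.n_genes:
        per_contig[int(np.argmax(per_contig))] -= 1

    genes: List[GeneRecord] = []
    gene_no = 0
    for (name, seq), count in zip(contigs.items(), per_contig):
        if count == 0:
            continue
        lengths = rng.integers(
            cfg.gene_len_range[0], cfg.gene_len_range[1] + 1, count
        )
        free = len(seq) - int(lengths.sum())
        if free < 0:
            raise SimConfigError(
                f"total gene length {int(lengths.sum())} exceeds contig "
                f"{name} length {len(seq)}"
            )
        gaps = rng.multinomial(free, np.full(count + 1, 1.0 / (count + 1)))
        cursor = 0
        for glen, gap in zip(lengths, gaps[:-1]):
            start = cursor + int(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            genes.append(
                GeneRecord(
                    name, start, start + int(glen),
                    f"NM_{gene_no:06d}", f"GENE{gene_no:04d}", strand,
                )
            )
            cursor = start + int(glen)
    return genome, genes


def _make_vector(
    rng: np.random.Generator, genome: ReferenceGenome, length: int
) -> str:
    """Vector sequence sharing no exact 30-mer (either strand) with the genome."""
    haystack = "X".join(genome.contigs.values())
    haystack = haystack + "X" + revcomp(haystack)
    for _ in range(50):
        vec = _random_seq(rng, length)
        if not any(
            vec[i : i + _EXCLUSION_K] in haystack
            for i in range(len(vec) - _EXCLUSION_K + 1)
        ):
            return vec
    raise SimConfigError("could not generate a genome-disjoint vector sequence")


def _apply_error(rng: np.random.Generator, bases: str, rate: float) -> str:
    if rate <= 0:
        return bases
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


@dataclass
class SimulatedLibrary:
    reads1: List[SequenceRead]
    reads2: Optional[List[SequenceRead]]
    truth: List[TruthRecord]
    vector_seq: str


def plant_and_sequence(
    cfg: SimConfig, genome: ReferenceGenome, genes: List[GeneRecord]
) -> SimulatedLibrary:
    """Plant integration sites and sequence the resulting junction library.

    A '+' site at 1-based position p yields reads whose genomic portion
    starts at p+1 running rightward; a '-' site reads leftward from p on the
    reverse strand.  Both conventions make the pipeline's called coordinate
    equal the planted position.  Each site is amplified dup_factor times;
    decoy into-vector amplicons are mixed in at ``decoy_fraction`` of the
    final read total; substitution errors are applied last.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    primers = cfg.primers
    tr = primers.tr_primer
    distal_oriented = revcomp(primers.distal_primer)
    adaptor2 = primers.read2_adaptor
    paired = cfg.mode == "paired"
    vector = _make_vector(rng, genome, cfg.vector_len)

    names = list(genome.contigs)
    lens = np.array([len(genome.contigs[n]) for n in names], dtype=float)
    weights = lens / lens.sum()

    # draw distinct planted sites away from contig ends
    sites: List[Tuple[str, int, str]] = []
    seen = set()
    attempts = 0
    while len(sites) < cfg.n_sites:
        attempts += 1
        if attempts > 100 * cfg.n_sites:
            raise SimConfigError("could not place the requested number of sites")
        ci = rng.choice(len(names), p=weights)
        contig = names[ci]
        n = len(genome.contigs[contig])
        pos = int(rng.integers(cfg.edge_margin, n - cfg.edge_margin + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        key = (contig, pos, strand)
        if key in seen:
            continue
        seen.add(key)
        sites.append(key)

    reads1: List[SequenceRead] = []
    reads2: List[SequenceRead] = [] if paired else None
    truth: List[TruthRecord] = []
    for si, (contig, pos, strand) in enumerate(sites):
        seq = genome.contigs[contig]
        dup = int(rng.integers(cfg.dup_factor_range[0], cfg.dup_factor_range[1] + 1))
        flen = int(
            rng.integers(cfg.fragment_len_range[0], cfg.fragment_len_range[1] + 1)
        )
        g = flen - len(tr) - len(distal_oriented)
        if strand == "+":
            genomic = seq[pos : pos + g]
        else:
            genomic = revcomp(seq[pos - g : pos])
        fragment = tr + genomic + distal_oriented
        for j in range(dup):
            rlen = int(rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1))
            effective = min(rlen, flen)
            # a 1-2 bp adaptor tail is below any trimmer's minimum overlap
            # and would leave unmappable bases; end such reads at the junction
            overlap = effective - (len(tr) + g)
            if 0 < overlap < 3:
                effective = len(tr) + g
            bases = fragment[:effective]
            rid = f"site{si:04d}_dup{j:03d}"
            reads1.append(
                SequenceRead(rid, _apply_error(rng, bases, cfg.error_rate),
                             "I" * effective, mate=1 if paired else 0)
            )
            if paired:
                rlen2 = int(
                    rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1)
                )
                l2g = min(rlen2 - len(adaptor2), g)
                mate2 = adaptor2 + revcomp(genomic[g - l2g :])
                reads2.append(
                    SequenceRead(rid, _apply_error(rng, mate2, cfg.error_rate),
                                 "I" * len(mate2), mate=2)
                )
        annotated = classify_site_bruteforce(
            IntegrationSite(contig, pos, strand, dup), genes, cfg.tss_window
        )
        truth.append(
            TruthRecord(contig, pos, strand, dup,
                        annotated.category.name, annotated.symbol)
        )

    # into-vector decoys: TR primer followed by vector-only sequence
    n_junction = len(reads1)
    n_decoys = int(round(cfg.decoy_fraction / (1 - cfg.decoy_fraction) * n_junction))
    for k in range(n_decoys):
        rlen = int(rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1))
        vlen = min(rlen - len(tr), cfg.vector_len - 1)
        vstart = int(rng.integers(0, cfg.vector_len - vlen + 1))
        bases = tr + vector[vstart : vstart + vlen]
        rid = f"decoy{k:04d}"
        reads1.append(
            SequenceRead(rid, _apply_error(rng, bases, cfg.error_rate),
                         "I" * len(bases), mate=1 if paired else 0)
        )
        if paired:
            rlen2 = int(rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1))
            v2 = min(rlen2 - len(adaptor2), cfg.vector_len - 1)
            v2start = int(rng.integers(0, cfg.vector_len - v2 + 1))
            mate2 = adaptor2 + revcomp(vector[v2start : v2start + v2])
            reads2.append(
                SequenceRead(rid, _apply_error(rng, mate2, cfg.error_rate),
                             "I" * len(mate2), mate=2)
            )

    # deterministic shuffle so decoys interleave with junction reads
    order = rng.permutation(len(reads1))
    reads1 = [reads1[i] for i in order]
    if paired:
        reads2 = [reads2[i] for i in order]
    return SimulatedLibrary(reads1, reads2, truth, vector)


TRUTH_HEADER = ("contig", "position", "strand", "dup_factor", "category", "symbol")


def write_truth_tsv(truth: List[TruthRecord], path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(TRUTH_HEADER) + "\n")
        for t in sorted(truth, key=lambda t: (t.contig, t.position, t.strand)):
            sym = t.expected_symbol if t.expected_symbol is not None else "NA"
            out.write(
                f"{t.contig}\t{t.position}\t{t.strand}\t{t.dup_factor}\t"
                f"{t.expected_category}\t{sym}\n"
            )


def write_fixture(cfg: SimConfig, out_dir) -> Dict[str, Path]:
    """Generate a complete ready-to-run fixture directory.

    Writes genome.fa, genes.bed, reads_1.fastq (and reads_2.fastq in paired
    mode) and truth.tsv; returns the path map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, genes = make_reference(cfg)
    library = plant_and_sequence(cfg, genome, genes)
    paths = {
        "genome": out_dir / "genome.fa",
        "genes": out_dir / "genes.bed",
        "reads1": out_dir / "reads_1.fastq",
        "truth": out_dir / "truth.tsv",
    }
    write_genome_fasta(genome, paths["genome"])
    write_gene_bed(genes, paths["genes"])
    write_fastq(library.reads1, paths["reads1"])
    if library.reads2 is not None:
        paths["reads2"] = out_dir / "reads_2.fastq"
        write_fastq(library.reads2, paths["reads2"])
    write_truth_tsv(library.truth, paths["truth"])
    return paths
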