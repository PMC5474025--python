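"""End-to-end pipeline orchestration: trim -> align -> call -> annotate -> report."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import align_filter, annotate, formats_io, is_call, primer_trim, report_stats

logger = logging.getLogger(__name__)


class MissingInputError(FileNotFoundError):
    """A required input file or parameter is absent."""


@dataclass
class PipelineConfig:
    mode: str
    fastq1: str
    tr_primer: str
    distal_primer: str
    genome_fasta: str
    gene_bed: str
    out_dir: str
    fastq2: Optional[str] = None
    read2_adaptor: Optional[str] = None
    window: int = annotate.DEFAULT_TSS_WINDOW
    min_len: int = primer_trim.MIN_TRIMMED_LEN
    insert_min: int = 50
    insert_max: int = 500
    backend: str = "internal"
    external_cmd: Optional[str] = None
    fraction_decimals: int = 0

    def validate(self) -> None:
        if self.mode not in ("single", "paired"):
            raise ValueError(f"mode must be 'single' or 'paired', got {self.mode!r}")
        if self.mode == "paired":
            if not self.fastq2:
                raise MissingInputError("paired mode requires fastq2")
            if not self.read2_adaptor:
                raise MissingInputError("paired mode requires read2_adaptor")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.backend not in ("internal", "external"):
            raise ValueError("backend must be 'internal' or 'external'")
        if self.backend == "external" and not self.external_cmd:
            raise MissingInputError("external backend requires external_cmd")
        for name in ("fastq1", "fastq2", "genome_fasta", "gene_bed"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise MissingInputError(f"{name}: {path} does not exist")


@dataclass
class PipelineResult:
    summary: report_stats.DatasetSummary
    annotated: List[annotate.AnnotatedSite]
    top_genes: List[report_stats.GeneISCount]
    n_dropped_contig_start: int
    outputs: Dict[str, Path]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the result tables.

    Outputs in ``cfg.out_dir``: the annotated site table (sites.txt), the
    funnel summary (summary.tsv), the gene ranking (top_genes.tsv) and a
    per-stage run log (run_log.txt).  Succeeds (with header-only tables) on
    empty input.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = formats_io.read_genome_fasta(cfg.genome_fasta)
    genes = formats_io.read_gene_bed(cfg.gene_bed)
    primers = formats_io.PrimerSpec(
        tr_primer=cfg.tr_primer,
        distal_primer=cfg.distal_primer,
        read2_adaptor=cfg.read2_adaptor,
    )

    if cfg.backend == "external":
        backend = align_filter.ExternalAligner(cfg.external_cmd)
    else:
        backend = align_filter.InternalAligner(genome)

    if cfg.mode == "single":
        reads = formats_io.read_fastq(cfg.fastq1)
        trimmed, trim_stats = primer_trim.select_and_trim(
            reads, primers, mode="single", min_len=cfg.min_len
        )
        hits, rounds = align_filter.progressive_unique_filter(
            trimmed, genome, backend=backend
        )
        calls = [is_call.call_site(h) for h in hits]
    else:
        pairs = zip(
            formats_io.read_fastq(cfg.fastq1, mate=1),
            formats_io.read_fastq(cfg.fastq2, mate=2),
        )
        trimmed_pairs, trim_stats = primer_trim.select_and_trim(
            pairs, primers, mode="paired", min_len=cfg.min_len
        )
        pair_hits, rounds = align_filter.paired_concordant_unique(
            trimmed_pairs, genome, cfg.insert_min, cfg.insert_max, backend=backend
        )
        calls = [is_call.call_site_paired(p) for p in pair_hits]

    n_dropped = sum(1 for c in calls if c is None)
    sites = is_call.dedup_sites(calls)
    annotated = annotate.annotate_all(sites, genes, cfg.window)
    summary = report_stats.summarize(
        trim_stats, rounds, annotated, decimals=cfg.fraction_decimals
    )
    genes_ranked = report_stats.top_genes(annotated) if annotated else []

    outputs = {
        "sites": out_dir / "sites.txt",
        "summary": out_dir / "summary.tsv",
        "top_genes": out_dir / "top_genes.tsv",
        "run_log": out_dir / "run_log.txt",
    }
    formats_io.write_is_table(annotated, outputs["sites"])
    report_stats.write_summary_tsv(summary, outputs["summary"])
    report_stats.write_top_genes_tsv(genes_ranked, outputs["top_genes"])
    _write_run_log(outputs["run_log"], cfg, trim_stats, rounds, summary, n_dropped)
    return PipelineResult(summary, annotated, genes_ranked, n_dropped, outputs)


def _write_run_log(path, cfg, trim_stats, rounds, summary, n_dropped) -> None:
    with open(path, "w") as log:
        log.write(f"mode\t{cfg.mode}\n")
        log.write(f"n_raw\t{trim_stats.n_input}\n")
        log.write(f"n_tr_matched\t{trim_stats.n_tr_matched}\n")
        log.write(f"n_no_primer\t{trim_stats.n_input - trim_stats.n_tr_matched}\n")
        log.write(f"n_too_short\t{trim_stats.n_tr_matched - trim_stats.n_after_minlen}\n")
        log.write(f"n_filtered\t{trim_stats.n_after_minlen}\n")
        log.write(f"n_distal_trimmed\t{trim_stats.n_distal_trimmed}\n")
        log.write(f"n_unique_mm0\t{rounds.n_unique_mm0}\n")
        log.write(f"n_unique_mm1\t{rounds.n_unique_mm1}\n")
        log.write(f"n_unique_mm2\t{rounds.n_unique_mm2}\n")
        log.write(
            f"n_unaligned_or_multimapped\t"
            f"{trim_stats.n_after_minlen - rounds.n_unique_mm0}\n"
        )
        log.write(f"n_dropped_contig_start\t{n_dropped}\n")
        log.write(f"n_unique_is\t{summary.n_unique_is}\n")
        for cat in report_stats.CATEGORIES:
            log.write(f"n_{cat.name.lower()}\t{summary.category_counts[cat]}\n")


def run_compare(summary_a_path, summary_b_path, out_path) -> Dict:
    """Fisher comparison of two saved dataset summaries; writes a TSV."""
    a = report_stats.read_summary_tsv(summary_a_path)
    b = report_stats.read_summary_tsv(summary_b_path)
    pvalues = report_stats.compare_categories(a, b)
    report_stats.write_comparisons_tsv(a, b, pvalues, out_path)
    return pvalues
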