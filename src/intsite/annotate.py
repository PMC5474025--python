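"""Classification of integration sites against gene models.

Each unique site is labelled by precedence:

1. TSS-proximal — within +/- ``window`` bp (default 2500, inclusive) of
   some gene's transcription start site;
2. intragenic — inside some gene's transcript span (TSS to transcription
   end) but not TSS-proximal;
3. intergenic — everything else.

The reported gene is the nearest-TSS gene among qualifying genes (the
containing genes for intragenic sites, any gene on the contig for
intergenic ones); ties break by lexicographic accession.  The signed TSS
distance is oriented by gene strand (positive = downstream of the TSS).
Site strand plays no role.  ``classify_site_bruteforce`` is a deliberately
plain linear-scan implementation of the same three rules, kept as an
independent oracle for the indexed path.
"""
from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .formats_io import GeneRecord
from .is_call import IntegrationSite

DEFAULT_TSS_WINDOW = 2500


class Category(enum.Enum):
    TSS_PROXIMAL = "TSS_PROXIMAL"
    INTRAGENIC = "INTRAGENIC"
    INTERGENIC = "INTERGENIC"

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class AnnotatedSite:
    site: IntegrationSite
    category: Category
    accession: Optional[str]
    symbol: Optional[str]
    tss_distance: Optional[int]


def gene_tss(gene: GeneRecord) -> int:
    """1-based transcription start: start+1 for '+' genes, end for '-'."""
    return gene.start + 1 if gene.strand == "+" else gene.end


def _signed_distance(position: int, gene: GeneRecord) -> int:
    tss = gene_tss(gene)
    return position - tss if gene.strand == "+" else tss - position


class GeneIndex:
    """Per-contig arrays of TSS positions and transcript spans."""

    def __init__(self, genes: Iterable[GeneRecord]):
        by_contig: Dict[str, List[GeneRecord]] = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append(g)
        self._contigs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, List[GeneRecord]]] = {}
        for contig, recs in by_contig.items():
            tss = np.array([gene_tss(g) for g in recs], dtype=np.int64)
            starts = np.array([g.start for g in recs], dtype=np.int64)
            ends = np.array([g.end for g in recs], dtype=np.int64)
            self._contigs[contig] = (tss, starts, ends, recs)

    def contig_genes(self, contig: str):
        return self._contigs.get(contig)


def _pick(position: int, genes: Sequence[GeneRecord]) -> GeneRecord:
    """Nearest-TSS gene; ties broken by lexicographic accession."""
    return min(genes, key=lambda g: (abs(position - gene_tss(g)), g.accession))


def classify_site(
    site: IntegrationSite,
    genes: Union[GeneIndex, Iterable[GeneRecord]],
    window: int = DEFAULT_TSS_WINDOW,
) -> AnnotatedSite:
    """Classify one site and attach its reported gene."""
    if window < 0:
        raise ValueError("window must be >= 0")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    entry = index.contig_genes(site.contig)
    if entry is None:
        return AnnotatedSite(site, Category.INTERGENIC, None, None, None)
    tss, starts, ends, recs = entry
    pos = site.position

    near = np.abs(pos - tss) <= window
    if near.any():
        gene = _pick(pos, [recs[i] for i in np.flatnonzero(near)])
        return AnnotatedSite(
            site, Category.TSS_PROXIMAL, gene.accession, gene.symbol,
            _signed_distance(pos, gene),
        )

    inside = (starts + 1 <= pos) & (pos <= ends)
    if inside.any():
        gene = _pick(pos, [recs[i] for i in np.flatnonzero(inside)])
        return AnnotatedSite(
            site, Category.INTRAGENIC, gene.accession, gene.symbol,
            _signed_distance(pos, gene),
        )

    gene = _pick(pos, recs)
    return AnnotatedSite(
        site, Category.INTERGENIC, gene.accession, gene.symbol,
        _signed_distance(pos, gene),
    )


def classify_site_bruteforce(
    site: IntegrationSite,
    genes: Iterable[GeneRecord],
    window: int = DEFAULT_TSS_WINDOW,
) -> AnnotatedSite:
    """Linear-scan oracle applying the three rules in order of precedence."""
    contig_genes = [g for g in genes if g.contig == site.contig]
    if not contig_genes:
        return AnnotatedSite(site, Category.INTERGENIC, None, None, None)
    pos = site.position

    proximal = [g for g in contig_genes if abs(pos - gene_tss(g)) <= window]
    if proximal:
        gene = _pick(pos, proximal)
        return AnnotatedSite(
            site, Category.TSS_PROXIMAL, gene.accession, gene.symbol,
            _signed_distance(pos, gene),
        )

    containing = [g for g in contig_genes if g.start + 1 <= pos <= g.end]
    if containing:
        gene = _pick(pos, containing)
        return AnnotatedSite(
            site, Category.INTRAGENIC, gene.accession, gene.symbol,
            _signed_distance(pos, gene),
        )

    gene = _pick(pos, contig_genes)
    return AnnotatedSite(
        site, Category.INTERGENIC, gene.accession, gene.symbol,
        _signed_distance(pos, gene),
    )


def annotate_all(
    sites: Sequence[IntegrationSite],
    genes: Iterable[GeneRecord],
    window: int = DEFAULT_TSS_WINDOW,
) -> List[AnnotatedSite]:
    """Classify every site (input order preserved)."""
    index = GeneIndex(genes)
    return [classify_site(s, index, window) for s in sites]
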