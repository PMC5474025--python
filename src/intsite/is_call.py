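"""Integration-site calling and deduplication.

The genomic nucleotide abutting the vector terminal repeat marks the
integration event: for a read mapped on the forward strand this is the
nucleotide preceding the read's first aligned position; for a reverse-
mapped read it is the read's last aligned position.  Calls sharing
(contig, position, strand) collapse into one unique site whose
supporting-read count reflects PCR duplication and/or clonal expansion.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

from .align_filter import AlignmentHit, PairHit

logger = logging.getLogger(__name__)

Call = Tuple[str, int, str]  # contig, 1-based position, strand


@dataclass(frozen=True)
class IntegrationSite:
    contig: str
    position: int  # 1-based position of the integration-adjacent nucleotide
    strand: str
    read_count: int

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("IntegrationSite: position must be >= 1")
        if self.read_count < 1:
            raise ValueError("IntegrationSite: read_count must be >= 1")


def call_site(hit: AlignmentHit) -> Optional[Call]:
    """Integration coordinate for one unique alignment.

    Forward hit: 1-based position of the nucleotide preceding the alignment
    start (equals the 0-based start).  Reverse hit: 1-based position of the
    last aligned nucleotide (equals the 0-based exclusive end).  A forward
    hit flush with the contig start has no preceding nucleotide and yields
    None with a warning.
    """
    if hit.strand == "+":
        if hit.start == 0:
            logger.warning(
                "read %s aligns at the start of contig %s; no preceding "
                "nucleotide to call, site dropped", hit.read_id, hit.contig,
            )
            return None
        return (hit.contig, hit.start, "+")
    return (hit.contig, hit.end, "-")


def call_site_paired(pair: PairHit) -> Optional[Call]:
    """The TR-bearing mate (mate 1) defines the junction coordinate."""
    return call_site(pair.mate1)


def dedup_sites(calls: Iterable[Optional[Call]]) -> List[IntegrationSite]:
    """Collapse per-read calls into unique sites with supporting-read counts.

    None entries (dropped calls) are ignored.  Output is sorted by
    (contig, position, strand); the read counts sum to the number of calls.
    """
    counts = Counter(c for c in calls if c is not None)
    return [
        IntegrationSite(contig, pos, strand, n)
        for (contig, pos, strand), n in sorted(counts.items())
    ]
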