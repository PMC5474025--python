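"""End-to-end read placement and unique-mapping filters.

Alignments are ungapped and end-to-end: a placement of a trimmed read is a
(contig, start, strand) with a Hamming mismatch count (N never matches).
Single-end reads pass a three-round progressive filter — a read must place
at exactly one location at 0 mismatches, then again at budget 1, then
budget 2; any round with more than one qualifying placement discards the
read.  This guards integration-site calls against false-positive mapping of
reads carrying sequencing errors.  Paired-end reads are kept only when
exactly one concordant zero-mismatch placement exists (mates on one contig,
inward-facing, fragment length inside the insert window).

Two backends satisfy the aligner contract (``align(reads, max_mm)`` ->
read_id -> placements): an internal exhaustive aligner (ground truth; a
pigeonhole-seeded k-mer index on large genomes, a full sliding scan on
small ones) and an external command producing SAM.
"""
from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import ReferenceGenome, write_fastq, SequenceRead
from .primer_trim import TrimmedRead
from .sequtil import N_CODE, encode, revcomp

SEED_K = 10
_INDEXED_GENOME_MIN = 100_000  # below this a direct scan is faster than indexing


class BackendError(RuntimeError):
    """External aligner invocation failed."""


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped end-to-end placement (0-based half-open span)."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    round: int = 0


@dataclass(frozen=True)
class RoundSummary:
    n_input: int
    n_unique_mm0: int
    n_unique_mm1: int
    n_unique_mm2: int


@dataclass(frozen=True)
class PairHit:
    mate1: AlignmentHit
    mate2: AlignmentHit
    fragment_len: int


# ---------------------------------------------------------------------------
# internal exhaustive aligner


def _scan_hits(contig_codes: np.ndarray, q: np.ndarray, max_mm: int) -> np.ndarray:
    """All start offsets with Hamming distance <= max_mm (full sliding scan)."""
    L, n = len(q), len(contig_codes)
    W = n - L + 1
    if W <= 0:
        return np.empty(0, dtype=np.int64)
    mm = np.zeros(W, dtype=np.int32)
    q_is_n = q == N_CODE
    for i in range(L):
        col = contig_codes[i : i + W]
        mm += (col != q[i]) | (col == N_CODE) | q_is_n[i]
    return np.flatnonzero(mm <= max_mm)


class _ContigIndex:
    """Sorted k-mer integer index over one contig (k = SEED_K)."""

    def __init__(self, codes: np.ndarray, k: int = SEED_K):
        self.codes = codes
        self.k = k
        n = len(codes)
        if n < k:
            self.sorted_kmers = np.empty(0, dtype=np.int64)
            self.order = np.empty(0, dtype=np.int64)
            return
        vals = np.zeros(n - k + 1, dtype=np.int64)
        has_n = np.zeros(n - k + 1, dtype=bool)
        c = codes.astype(np.int64)
        for j in range(k):
            window = c[j : n - k + 1 + j]
            vals = vals * 4 + np.where(window == N_CODE, 0, window)
            has_n |= window == N_CODE
        vals[has_n] = -1
        self.order = np.argsort(vals, kind="stable")
        self.sorted_kmers = vals[self.order]

    def lookup(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_kmers, kmer, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmer, side="right")
        return self.order[lo:hi]


def _kmer_int(q: np.ndarray) -> Optional[int]:
    if (q == N_CODE).any():
        return None
    val = 0
    for b in q:
        val = val * 4 + int(b)
    return val


def _seeded_hits(
    index: _ContigIndex, q: np.ndarray, max_mm: int
) -> Optional[np.ndarray]:
    """Exhaustive hits via pigeonhole seeding, or None when inapplicable.

    The query is split into max_mm+1 chunks; any placement within budget has
    at least one mismatch-free chunk, whose first k bases then hit the index
    exactly.  Requires every chunk to be at least k long.
    """
    L, k = len(q), index.k
    n_chunks = max_mm + 1
    if L // n_chunks < k:
        return None
    codes = index.codes
    n = len(codes)
    if n < L:
        return np.empty(0, dtype=np.int64)
    bounds = [(i * L) // n_chunks for i in range(n_chunks)]
    candidates: set[int] = set()
    for b in bounds:
        kmer = _kmer_int(q[b : b + k])
        if kmer is None:
            continue
        for pos in index.lookup(kmer):
            start = int(pos) - b
            if 0 <= start <= n - L:
                candidates.add(start)
    if not candidates:
        return np.empty(0, dtype=np.int64)
    starts = np.array(sorted(candidates), dtype=np.int64)
    keep = []
    q_is_n = q == N_CODE
    for s in starts:
        window = codes[s : s + L]
        mm = int(np.count_nonzero((window != q) | (window == N_CODE) | q_is_n))
        if mm <= max_mm:
            keep.append(s)
    return np.array(keep, dtype=np.int64)


def _window_mismatches(codes: np.ndarray, q: np.ndarray, start: int) -> int:
    window = codes[start : start + len(q)]
    return int(
        np.count_nonzero((window != q) | (window == N_CODE) | (q == N_CODE))
    )


def enumerate_alignments(
    query: str,
    genome: ReferenceGenome,
    max_mm: int,
    read_id: str = "",
    _indexes: Optional[Dict[str, _ContigIndex]] = None,
    _codes: Optional[Dict[str, np.ndarray]] = None,
) -> List[AlignmentHit]:
    """Every ungapped end-to-end placement of ``query`` with <= max_mm
    mismatches, on either strand of any contig, ordered by (contig, start,
    strand)."""
    if len(query) < 1:
        raise ValueError("query must be non-empty")
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    hits: List[AlignmentHit] = []
    queries = {"+": encode(query), "-": encode(revcomp(query))}
    for contig, seq in genome.contigs.items():
        codes = _codes[contig] if _codes is not None else encode(seq)
        index = _indexes.get(contig) if _indexes is not None else None
        contig_hits: List[Tuple[int, str, int]] = []
        for strand, q in queries.items():
            starts = None
            if index is not None and len(codes) >= _INDEXED_GENOME_MIN:
                starts = _seeded_hits(index, q, max_mm)
            if starts is None:
                starts = _scan_hits(codes, q, max_mm)
            for s in starts:
                contig_hits.append((int(s), strand, _window_mismatches(codes, q, int(s))))
        contig_hits.sort(key=lambda h: (h[0], h[1]))
        for start, strand, mm in contig_hits:
            hits.append(
                AlignmentHit(read_id, contig, start, start + len(query), strand, mm)
            )
    return hits


class InternalAligner:
    """Exhaustive in-process aligner; caches a k-mer index and per-read hits.

    Hits are computed once per read at the maximum budget (2) and filtered
    per round, which is equivalent to realigning at each round's budget.
    """

    MAX_BUDGET = 2

    def __init__(self, genome: ReferenceGenome, k: int = SEED_K):
        self.genome = genome
        self._codes = {name: encode(seq) for name, seq in genome.contigs.items()}
        self._indexes: Dict[str, _ContigIndex] = {}
        for name, codes in self._codes.items():
            if len(codes) >= _INDEXED_GENOME_MIN:
                self._indexes[name] = _ContigIndex(codes, k)
        self._cache: Dict[Tuple[str, int, str], List[AlignmentHit]] = {}

    def align(
        self, reads: Sequence[TrimmedRead], max_mm: int
    ) -> Dict[str, List[AlignmentHit]]:
        if max_mm > self.MAX_BUDGET:
            raise ValueError(f"budget {max_mm} exceeds supported maximum 2")
        out: Dict[str, List[AlignmentHit]] = {}
        for read in reads:
            key = (read.read_id, read.mate, read.bases)
            cached = self._cache.get(key)
            if cached is None:
                cached = enumerate_alignments(
                    read.bases,
                    self.genome,
                    self.MAX_BUDGET,
                    read_id=read.read_id,
                    _indexes=self._indexes,
                    _codes=self._codes,
                )
                self._cache[key] = cached
            out[read.read_id] = [h for h in cached if h.mismatches <= max_mm]
        return out


class ExternalAligner:
    """Adapter for an external aligner producing SAM.

    ``command`` is a template with ``{reads}``, ``{sam}`` and ``{max_mm}``
    placeholders; it must report every placement within the mismatch budget
    (secondary records included) so multi-mappers are visible.  Reads with
    any placement beyond the budget's NM are filtered here.
    """

    def __init__(self, command: str):
        self.command = command

    def align(
        self, reads: Sequence[TrimmedRead], max_mm: int
    ) -> Dict[str, List[AlignmentHit]]:
        from .formats_io import read_sam_hits

        with tempfile.TemporaryDirectory(prefix="intsite_aln_") as tmp:
            reads_path = Path(tmp) / "reads.fastq"
            sam_path = Path(tmp) / "hits.sam"
            write_fastq(
                (SequenceRead(r.read_id, r.bases, mate=r.mate) for r in reads),
                reads_path,
            )
            cmd = self.command.format(reads=reads_path, sam=sam_path, max_mm=max_mm)
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise BackendError(
                    f"external aligner failed (exit {proc.returncode}): {proc.stderr}"
                )
            raw = read_sam_hits(sam_path)
        out: Dict[str, List[AlignmentHit]] = {}
        for read in reads:
            hits = raw.get(read.read_id, [])
            out[read.read_id] = [h for h in hits if h.mismatches <= max_mm]
        return out


# ---------------------------------------------------------------------------
# filters

_BUDGETS = (0, 1, 2)


def progressive_unique_filter(
    reads: Sequence[TrimmedRead],
    genome: ReferenceGenome,
    backend=None,
) -> Tuple[List[AlignmentHit], RoundSummary]:
    """Three-round progressive unique-mapping filter for single-end reads.

    Round budgets 0, 1, 2 mismatches; each round keeps only reads with
    exactly one placement within its budget, and feeds its survivors to the
    next round.  Survivors carry their (unique) final placement with the
    last round's budget recorded.
    """
    if backend is None:
        backend = InternalAligner(genome)
    survivors = list(reads)
    counts = []
    final: Dict[str, List[AlignmentHit]] = {}
    for budget in _BUDGETS:
        result = backend.align(survivors, budget)
        survivors = [r for r in survivors if len(result.get(r.read_id, [])) == 1]
        counts.append(len(survivors))
        final = result
    hits = [
        replace(final[r.read_id][0], round=_BUDGETS[-1]) for r in survivors
    ]
    summary = RoundSummary(
        n_input=len(reads),
        n_unique_mm0=counts[0],
        n_unique_mm1=counts[1],
        n_unique_mm2=counts[2],
    )
    return hits, summary


def _concordant_combos(
    hits1: List[AlignmentHit],
    hits2: List[AlignmentHit],
    insert_min: int,
    insert_max: int,
) -> List[PairHit]:
    combos = []
    for h1 in hits1:
        for h2 in hits2:
            if h1.contig != h2.contig or h1.strand == h2.strand:
                continue
            plus, minus = (h1, h2) if h1.strand == "+" else (h2, h1)
            if plus.start > minus.start:
                continue  # outward-facing
            frag = minus.end - plus.start
            if insert_min <= frag <= insert_max:
                combos.append(PairHit(h1, h2, frag))
    return combos


def paired_concordant_unique(
    pairs: Sequence[Tuple[TrimmedRead, TrimmedRead]],
    genome: ReferenceGenome,
    insert_min: int = 50,
    insert_max: int = 500,
    backend=None,
) -> Tuple[List[PairHit], RoundSummary]:
    """Keep pairs with exactly one concordant zero-mismatch placement.

    Concordance: mates on the same contig, opposite strands, inward-facing,
    outer fragment span within [insert_min, insert_max].  No progressive
    relaxation is applied in paired mode.
    """
    if insert_min > insert_max:
        raise ValueError("insert_min must be <= insert_max")
    if backend is None:
        backend = InternalAligner(genome)
    mates1 = [p[0] for p in pairs]
    mates2 = [p[1] for p in pairs]
    res1 = backend.align(mates1, 0)
    res2 = backend.align(mates2, 0)
    kept: List[PairHit] = []
    for m1, m2 in pairs:
        combos = _concordant_combos(
            res1.get(m1.read_id, []), res2.get(m2.read_id, []), insert_min, insert_max
        )
        if len(combos) == 1:
            kept.append(combos[0])
    n = len(kept)
    summary = RoundSummary(
        n_input=len(pairs), n_unique_mm0=n, n_unique_mm1=n, n_unique_mm2=n
    )
    return kept, summary
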