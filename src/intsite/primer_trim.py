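"""Candidate junction-read selection and vector-primer trimming.

A junction read is expected to begin with (a suffix of) the known terminal
repeat (TR) primer, followed by host genomic sequence, optionally running
into the reverse complement of the 3' distal primer/adaptor when the
sequenced fragment is shorter than the read.

Selection searches the read's 5' region for the best-placed TR suffix under
a length-dependent mismatch ladder: suffixes of >= 20 bases tolerate two
mismatches, 10-19 bases one, and below 10 bases none.  Matched primer
sequence is trimmed, the distal adaptor (if present at the 3' end) is
trimmed, and trimmed reads shorter than 30 bp are eliminated.  In paired-end
mode a pair is kept only when mate 1 carries the TR primer and mate 2
carries the read-2 adaptor, both trimmed mates passing the length floor.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Optional, Tuple, Union

import numpy as np

from .formats_io import PrimerSpec, SequenceRead
from .sequtil import N_CODE, encode, hamming, revcomp

MIN_TRIMMED_LEN = 30
MIN_TR_SUFFIX = 5  # floor on considered TR suffix length; avoids 1-2 nt hits


class TrimError(ValueError):
    """Desynchronized or otherwise unusable paired input."""


@dataclass(frozen=True)
class TrimmedRead:
    """Genomic query remaining after primer/adaptor trimming."""

    read_id: str
    bases: str
    tr_match_len: int
    tr_mismatches: int
    distal_trimmed: bool
    mate: int = 0


@dataclass
class TrimStats:
    n_input: int = 0
    n_tr_matched: int = 0
    n_after_minlen: int = 0
    n_distal_trimmed: int = 0


class TrMatch(NamedTuple):
    match_end: int  # 0-based offset just past the matched TR suffix
    match_len: int
    mismatches: int


def mismatch_allowance(match_len: int) -> int:
    """Allowed mismatches for a TR suffix match of the given length.

    Two mismatches for >= 20 bases, one for 10-19, none below 10.
    """
    if match_len < 1:
        raise ValueError("match_len must be >= 1")
    if match_len >= 20:
        return 2
    if match_len >= 10:
        return 1
    return 0


def _allowance_vector(max_len: int) -> np.ndarray:
    lengths = np.arange(1, max_len + 1)
    return np.where(lengths >= 20, 2, np.where(lengths >= 10, 1, 0))


def match_tr_primer(
    read: SequenceRead, tr_primer: str, min_suffix: int = MIN_TR_SUFFIX
) -> Optional[TrMatch]:
    """Find the best qualifying TR-primer suffix placement in a read.

    Considers every suffix of ``tr_primer`` of length >= ``min_suffix`` at
    every offset where it ends inside the read; a placement qualifies when
    its mismatch count (N counts as a mismatch) is within the ladder for its
    length.  Preference: longest suffix, then fewest mismatches, then
    leftmost end.  Returns None when nothing qualifies.
    """
    bases = read.bases
    R, T = len(bases), len(tr_primer)
    if R < min_suffix:
        return None
    # fast path: exact full primer at the read start (the designed layout)
    if R >= T and bases[:T] == tr_primer and "N" not in tr_primer:
        return TrMatch(T, T, 0)

    q = encode(bases).astype(np.int16)
    t = encode(tr_primer).astype(np.int16)
    ends = np.arange(1, R + 1)  # suffix end offset in read (exclusive)
    j = np.arange(T)
    # read index aligned with tr position j for suffix ending at e
    ridx = ends[:, None] - T + j[None, :]
    valid = ridx >= 0
    qv = q[np.clip(ridx, 0, R - 1)]
    mm = ((qv != t) | (qv == N_CODE) | (t == N_CODE)) & valid
    # suffix mismatch counts: suf[e, L-1] = mismatches of tr[-L:] vs read
    suf = np.cumsum(mm[:, ::-1], axis=1)

    max_len = min(T, R)
    lengths = np.arange(1, max_len + 1)
    allow = _allowance_vector(max_len)
    # a suffix of length L must fit inside the read: L <= e
    fits = lengths[None, :] <= ends[:, None]
    ok = fits & (suf[:, :max_len] <= allow[None, :]) & (lengths[None, :] >= min_suffix)
    if not ok.any():
        return None
    best_len = int(lengths[ok.any(axis=0)].max())
    col = ok[:, best_len - 1]
    cand_ends = ends[col]
    cand_mm = suf[col, best_len - 1]
    order = np.lexsort((cand_ends, cand_mm))
    pick = order[0]
    return TrMatch(int(cand_ends[pick]), best_len, int(cand_mm[pick]))


def trim_distal(
    bases: str,
    distal_oriented: str,
    max_mismatch_rate: float = 0.1,
    min_overlap: int = 3,
) -> Tuple[str, bool]:
    """Trim the 3' distal primer/adaptor overlap from a trimmed read.

    Removes the longest prefix of ``distal_oriented`` (the adaptor as it
    appears on the read strand) found as a suffix of ``bases``, allowing
    mismatches at <= ``max_mismatch_rate`` of the matched length (floored).
    Absence of the adaptor leaves the read unchanged.
    """
    if not bases:
        return bases, False
    n = len(bases)
    for L in range(min(len(distal_oriented), n), min_overlap - 1, -1):
        allowed = int(max_mismatch_rate * L)
        if hamming(bases[n - L :], distal_oriented[:L], limit=allowed) <= allowed:
            return bases[: n - L], True
    return bases, False


def _mate_key(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def _oriented_distal(primers: PrimerSpec) -> str:
    if primers.distal_is_read_strand:
        return primers.distal_primer
    return revcomp(primers.distal_primer)


def _trim_one(
    read: SequenceRead,
    anchor: str,
    distal_oriented: str,
    min_len: int,
) -> Tuple[Optional[TrimmedRead], bool, bool]:
    """Returns (trimmed-or-None, anchor_matched, distal_trimmed)."""
    match = match_tr_primer(read, anchor)
    if match is None:
        return None, False, False
    remainder = read.bases[match.match_end :]
    remainder, was_trimmed = trim_distal(remainder, distal_oriented)
    if len(remainder) < min_len:
        return None, True, was_trimmed
    return (
        TrimmedRead(
            read_id=read.read_id,
            bases=remainder,
            tr_match_len=match.match_len,
            tr_mismatches=match.mismatches,
            distal_trimmed=was_trimmed,
            mate=read.mate,
        ),
        True,
        was_trimmed,
    )


def select_and_trim(
    reads: Union[Iterable[SequenceRead], Iterable[Tuple[SequenceRead, SequenceRead]]],
    primers: PrimerSpec,
    mode: str = "single",
    min_len: int = MIN_TRIMMED_LEN,
):
    """Select and trim candidate junction reads.

    Single mode consumes SequenceReads and returns (list of TrimmedRead,
    TrimStats).  Paired mode consumes synchronized (mate1, mate2) tuples —
    mate 1 must carry the TR primer and mate 2 the read-2 adaptor, both
    trimmed mates must reach ``min_len`` — and returns (list of TrimmedRead
    pairs, TrimStats).  In paired mode the stats count pairs.
    """
    if mode not in ("single", "paired"):
        raise ValueError(f"unknown mode {mode!r}")
    stats = TrimStats()
    distal_oriented = _oriented_distal(primers)

    if mode == "single":
        kept: List[TrimmedRead] = []
        for read in reads:
            stats.n_input += 1
            trimmed, matched, distal = _trim_one(
                read, primers.tr_primer, distal_oriented, min_len
            )
            if matched:
                stats.n_tr_matched += 1
            if distal:
                stats.n_distal_trimmed += 1
            if trimmed is not None:
                stats.n_after_minlen += 1
                kept.append(trimmed)
        return kept, stats

    if primers.read2_adaptor is None:
        raise ValueError("paired mode requires primers.read2_adaptor")
    # mate 2's 3' end can run back into the TR primer; trim its complement
    mate2_distal = revcomp(primers.tr_primer)
    pairs: List[Tuple[TrimmedRead, TrimmedRead]] = []
    for r1, r2 in reads:
        stats.n_input += 1
        if _mate_key(r1.read_id) != _mate_key(r2.read_id):
            raise TrimError(
                f"desynchronized mates at pair {stats.n_input}: "
                f"{r1.read_id!r} vs {r2.read_id!r}"
            )
        t1, matched1, distal1 = _trim_one(r1, primers.tr_primer, distal_oriented, min_len)
        t2, matched2, distal2 = _trim_one(r2, primers.read2_adaptor, mate2_distal, min_len)
        if matched1 and matched2:
            stats.n_tr_matched += 1
        if distal1 or distal2:
            stats.n_distal_trimmed += 1
        if t1 is not None and t2 is not None and matched1 and matched2:
            pairs.append(
                (
                    TrimmedRead(t1.read_id, t1.bases, t1.tr_match_len,
                                t1.tr_mismatches, t1.distal_trimmed, mate=1),
                    TrimmedRead(t2.read_id, t2.bases, t2.tr_match_len,
                                t2.tr_mismatches, t2.distal_trimmed, mate=2),
                )
            )
            stats.n_after_minlen += 1
    return pairs, stats
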