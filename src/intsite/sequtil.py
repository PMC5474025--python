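"""Small shared sequence helpers: encoding, reverse complement, Hamming distance.

Bases are encoded A=0, C=1, G=2, T=3, N(or anything else)=4.  An N — in a
read or in the reference — never matches anything, including another N.
"""
from __future__ import annotations

import numpy as np

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings; N counts as a mismatch.

    With ``limit`` set, returns early with ``limit + 1`` once exceeded.
    """
    if len(a) != len(b):
        raise ValueError("hamming: length mismatch")
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm


def mismatch_profile(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Boolean per-position mismatch array for two equal-length code arrays."""
    return (codes_a != codes_b) | (codes_a == N_CODE) | (codes_b == N_CODE)
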