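"""Shared nucleotide-alphabet helpers.

Sequences are stored internally as uppercase DNA (T, not U); writers can
emit the RNA alphabet on request.  Numeric encoding maps A,C,G,U/T to
0..3 with 255 as a never-matching sentinel.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (DNA or RNA input; DNA output except U->A)."""
    return seq.translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


ENC_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGU"):
    ENC_TABLE[ord(_b)] = _i
    ENC_TABLE[ord(_b.lower())] = _i
ENC_TABLE[ord("T")] = 3
ENC_TABLE[ord("t")] = 3


def encode(seq: str, strict: bool = True) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, U/T=3).

    With strict=True any character outside the AUCG/T alphabet raises;
    otherwise it becomes the sentinel 255, which never matches a base.
    """
    arr = ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if strict and (arr == 255).any():
        bad = sorted({c for c in seq if ENC_TABLE[ord(c)] == 255})
        raise ValueError(f"sequence contains non-AUCG/T characters: {bad!r}")
    return arr


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
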