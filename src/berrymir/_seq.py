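"""Small shared sequence helpers (RNA alphabet, complement, encoding)."""

from __future__ import annotations

import numpy as np

RNA_ALPHABET = "ACGU"

_COMP_RNA = str.maketrans("ACGUTacgut", "UGCAAugcaa")
_COMP_DNA = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")
_TO_RNA = str.maketrans("Tt", "Uu")
_TO_DNA = str.maketrans("Uu", "Tt")

# integer encoding used by the folding kernels: A=0 C=1 G=2 U=3
_ENC = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(RNA_ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("T")] = 3
_ENC[ord("t")] = 3


def to_rna(seq: str) -> str:
    """Normalize T->U, uppercase."""
    return seq.upper().translate(_TO_RNA)


def to_dna(seq: str) -> str:
    """Normalize U->T, uppercase."""
    return seq.upper().translate(_TO_DNA)


def revcomp_rna(seq: str) -> str:
    """Reverse complement in the RNA alphabet (accepts T, emits U)."""
    return seq.translate(_COMP_RNA)[::-1]


def revcomp_dna(seq: str) -> str:
    """Reverse complement in the DNA alphabet (accepts U, emits T)."""
    return seq.translate(_COMP_DNA)[::-1]


def revcomp(seq: str) -> str:
    """Reverse complement, keeping the alphabet of the input (U -> RNA)."""
    return revcomp_rna(seq) if ("U" in seq or "u" in seq) else revcomp_dna(seq)


def is_rna(seq: str) -> bool:
    return bool(seq) and all(c in RNA_ALPHABET for c in to_rna(seq))


def encode(seq: str) -> np.ndarray:
    """Encode an ACGU/ACGT string as int8 codes; raises on other symbols."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    return arr
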