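"""Small shared sequence primitives (reverse complement, canonical kmers, rotations)."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a kmer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def equal_up_to_rotation_strand(a: str, b: str) -> bool:
    """True if two circular sequences are the same up to rotation and strand."""
    if len(a) != len(b):
        return False
    doubled = b + b
    return a in doubled or revcomp(a) in doubled


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings; N never matches.

    Stops early once ``limit`` is exceeded (returns limit+1).
    """
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm
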