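"""Paired-end read cleaning: the adaptor / unknown-base / low-quality pair filter.

A pair is discarded whole when either mate contains the adaptor, has more than
``max_n_frac`` unknown bases (N), or has more than ``max_lowq_frac`` of its
bases below the quality threshold.  Thresholds are strict ("more than"), kept
reads are untouched (no trimming).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import revcomp

PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the record index."""

    def __init__(self, index: int, message: str):
        super().__init__(f"record {index}: {message}")
        self.index = index


@dataclass
class ReadPair:
    """Two mated reads with Phred+33 quality strings."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")

    def mates(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.seq1, self.qual1), (self.seq2, self.qual2)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Stream mated records from two parallel FASTQ files (gzip-transparent)."""
    with _open_text(r1) as h1, _open_text(r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for i, (rec1, rec2) in enumerate(zip(it1, it2, strict=True)):
            (t1, s1, q1), (t2, s2, q2) = rec1, rec2
            name1 = t1.split()[0].removesuffix("/1")
            name2 = t2.split()[0].removesuffix("/2")
            if name1 != name2:
                raise FastqParseError(i, f"mate names differ: {name1} vs {name2}")
            try:
                yield ReadPair(name1, s1.upper(), q1, s2.upper(), q2)
            except ValueError as e:
                raise FastqParseError(i, str(e)) from e


def write_fastq_pairs(pairs: Iterable[ReadPair], r1: str | Path, r2: str | Path) -> int:
    """Write pairs to two FASTQ files with /1 and /2 mate suffixes; returns count."""
    n = 0
    with _open_text(r1, "wt") as h1, _open_text(r2, "wt") as h2:
        for p in pairs:
            h1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            h2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def _has_adaptor(seq: str, adaptor: str, adaptor_rc: str, min_prefix: int | None) -> bool:
    if adaptor in seq or adaptor_rc in seq:
        return True
    if min_prefix is not None:
        # read-through semantics: an adaptor prefix of length >= min_prefix at the 3' end
        for m in range(len(adaptor) - 1, min_prefix - 1, -1):
            if seq.endswith(adaptor[:m]):
                return True
    return False


def _mate_fails(
    seq: str,
    qual: str,
    adaptor: str | None,
    adaptor_rc: str | None,
    max_n_frac: float,
    low_q_thresh: int,
    max_lowq_frac: float,
    min_adaptor_prefix: int | None,
) -> str | None:
    """First failing rule for one mate, in the fixed order adaptor, N, quality."""
    if adaptor and _has_adaptor(seq, adaptor, adaptor_rc, min_adaptor_prefix):
        return "adaptor"
    n = len(seq)
    if n and seq.count("N") > max_n_frac * n:
        return "n_bases"
    if n:
        lowq = sum(1 for c in qual if ord(c) - PHRED_OFFSET < low_q_thresh)
        if lowq > max_lowq_frac * n:
            return "low_quality"
    return None


def qc_filter_pairs(
    pairs: Iterable[ReadPair],
    adaptor: str | None = None,
    max_n_frac: float = 0.10,
    low_q_thresh: int = 5,
    max_lowq_frac: float = 0.50,
    min_adaptor_prefix: int | None = None,
) -> tuple[list[ReadPair], Counter]:
    """Apply the pair-level cleaning rule; returns (kept, discard counts by reason).

    A pair fails on the first failing rule in the fixed order (adaptor, N,
    quality), checking the rule against both mates before moving to the next
    rule, so discard reasons are mutually exclusive and reproducible.
    """
    if not (0 <= max_n_frac <= 1 and 0 <= max_lowq_frac <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    adaptor = adaptor.upper() if adaptor else None
    adaptor_rc = revcomp(adaptor) if adaptor else None
    kept: list[ReadPair] = []
    discarded: Counter = Counter()
    for p in pairs:
        reason = None
        for rule in ("adaptor", "n_bases", "low_quality"):
            for seq, qual in p.mates():
                r = _mate_fails(
                    seq, qual, adaptor, adaptor_rc, max_n_frac, low_q_thresh,
                    max_lowq_frac, min_adaptor_prefix,
                )
                if r == rule:
                    reason = r
                    break
            if reason:
                break
        if reason:
            discarded[reason] += 1
        else:
            kept.append(p)
    return kept, discarded


def total_bases(n_pairs: int, read_length: int) -> int:
    """Library size in bases for ``n_pairs`` pairs of ``read_length`` nt reads."""
    return n_pairs * 2 * read_length
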