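"""Exact and near-exact read placement over small references.

Implements the pipeline's exact-match semantics: the "at least one end maps
exactly, so the pair is plastid and is removed" classifier, plus shared-region
masking between the two organelle genomes and per-region depth statistics.

Mapping is seed-and-verify with non-overlapping seeds: a full-length placement
with at most m mismatches must contain one exact seed of length
seed_k <= floor(read_length / (m+1)) (pigeonhole), so no placement is missed.
There are no indels, no clipping, and N never matches any base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import canonical, hamming, revcomp
from .readqc import ReadPair
from .vcqa import _round_half_away


class MappingParameterError(ValueError):
    pass


@dataclass(frozen=True)
class Placement:
    """One full-length, gap-free placement of a read on a reference."""

    ref_id: str
    start: int  # 0-based, on the forward strand of the reference
    strand: str  # '+' or '-'
    mismatches: int
    length: int
    read_id: str = ""
    mate: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length


class SeedIndex:
    """Positions of every seed_k-mer of a set of references.

    Seeds are stored on the forward strand; reverse-strand placements are found
    by querying the reverse complement of the read.  Circular references get a
    ``wrap`` overhang so reads crossing the origin are placeable; positions are
    always reported modulo the reference length.
    """

    def __init__(
        self,
        refs: Mapping[str, str],
        seed_k: int = 31,
        circular: Iterable[str] = (),
        wrap: int = 0,
    ):
        if seed_k < 1:
            raise MappingParameterError("seed_k must be positive")
        self.seed_k = seed_k
        self.circular = set(circular)
        self.wrap = wrap
        self.refs = {rid: seq.upper() for rid, seq in refs.items()}
        self._ext = {
            rid: seq + seq[: wrap] if rid in self.circular else seq
            for rid, seq in self.refs.items()
        }
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for rid, ext in self._ext.items():
            L = len(self.refs[rid])
            n_pos = L if rid in self.circular else max(0, L - seed_k + 1)
            for i in range(n_pos):
                s = ext[i : i + seed_k]
                if len(s) < seed_k or "N" in s:
                    continue
                self.seeds.setdefault(s, []).append((rid, i))


def build_index(
    refs: Mapping[str, str] | str,
    seed_k: int = 31,
    circular: Iterable[str] = (),
    wrap: int = 0,
) -> SeedIndex:
    """Build a seed index; a bare string becomes reference id ``"ref"``."""
    if isinstance(refs, str):
        refs = {"ref": refs}
    return SeedIndex(refs, seed_k=seed_k, circular=circular, wrap=wrap)


def map_read(
    read: str,
    index: SeedIndex,
    max_mismatch: int = 0,
    first_only: bool = False,
    read_id: str = "",
    mate: int = 0,
) -> list[Placement]:
    """All full-length placements of ``read`` with <= max_mismatch mismatches.

    Both strands are searched; N in the read (or reference) counts as a
    mismatch everywhere.  ``first_only`` short-circuits at the first hit,
    for existence queries.
    """
    read = read.upper()
    rl = len(read)
    k = index.seed_k
    if rl < k:
        raise MappingParameterError("read shorter than seed_k")
    n_seeds = max_mismatch + 1
    if k > rl // n_seeds:
        raise MappingParameterError(
            f"seed_k={k} too large for {max_mismatch} mismatches on a {rl} nt read"
        )
    step = rl // n_seeds
    placements: list[Placement] = []
    seen: set[tuple[str, int, str]] = set()
    for strand, q in (("+", read), ("-", revcomp(read))):
        for si in range(n_seeds):
            off = si * step
            seed = q[off : off + k]
            if "N" in seed:
                continue
            for rid, pos in index.seeds.get(seed, ()):
                L = len(index.refs[rid])
                start = pos - off
                if rid in index.circular:
                    start %= L
                    if start + rl > len(index._ext[rid]):
                        continue
                elif start < 0 or start + rl > L:
                    continue
                key = (rid, start, strand)
                if key in seen:
                    continue
                seen.add(key)
                mm = hamming(q, index._ext[rid][start : start + rl], limit=max_mismatch)
                if mm <= max_mismatch:
                    placements.append(Placement(rid, start, strand, mm, rl, read_id, mate))
                    if first_only:
                        return placements
    placements.sort(key=lambda p: (p.ref_id, p.start, p.strand))
    return placements


def partition_pairs(
    pairs: Iterable[ReadPair],
    index: SeedIndex,
    max_mismatch: int = 0,
) -> tuple[list[ReadPair], list[ReadPair]]:
    """Split pairs into (mapped, unmapped) by the >=1-end-maps-exactly rule."""
    mapped: list[ReadPair] = []
    unmapped: list[ReadPair] = []
    for p in pairs:
        hit = map_read(p.seq1, index, max_mismatch, first_only=True) or map_read(
            p.seq2, index, max_mismatch, first_only=True
        )
        (mapped if hit else unmapped).append(p)
    return mapped, unmapped


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def shared_region_mask(
    ref_a: str, ref_b: str, min_run: int = 100
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Intervals of each reference covered by exact shared runs >= min_run.

    Shared canonical min_run-mers are collected and merged into maximal runs;
    the complement of the mask is the "unique regions" used for unbiased depth
    estimates.  Strand-symmetric: a tract shared in reverse complement masks
    both references.
    """
    ref_a, ref_b = ref_a.upper(), ref_b.upper()

    def kmer_set(seq: str) -> set[str]:
        return {
            canonical(seq[i : i + min_run])
            for i in range(len(seq) - min_run + 1)
            if "N" not in seq[i : i + min_run]
        }

    shared = kmer_set(ref_a) & kmer_set(ref_b)

    def mask(seq: str) -> list[tuple[int, int]]:
        iv = [
            (i, i + min_run)
            for i in range(len(seq) - min_run + 1)
            if canonical(seq[i : i + min_run]) in shared
        ]
        return _merge_intervals(iv)

    return mask(ref_a), mask(ref_b)


def unique_regions(length: int, mask: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Complement of a mask within [0, length)."""
    out = []
    prev = 0
    for s, e in _merge_intervals(mask):
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


@dataclass
class Region:
    """A named set of intervals on one reference, e.g. "unique plastid"."""

    name: str
    ref_id: str
    intervals: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class DepthRow:
    name: str
    mapped_reads: int
    mapped_bases: int
    region_length: int

    @property
    def depth(self) -> int:
        """Layers of coverage, rounded to the nearest integer for reporting."""
        if self.region_length <= 0:
            raise MappingParameterError(f"region {self.name} has zero length")
        return int(_round_half_away(self.mapped_bases / self.region_length, 0))


@dataclass
class DepthReport:
    rows: list[DepthRow] = field(default_factory=list)

    def __getitem__(self, name: str) -> DepthRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.name, r.region_length, r.mapped_reads, r.mapped_bases, r.depth)
                for r in self.rows
            ],
            columns=["region", "reference_length", "mapped_reads", "mapped_bases", "depth"],
        )

    def to_tsv(self, path: str | Path | None = None) -> str:
        text = self.to_frame().to_csv(sep="\t", index=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def depth_stats(
    placements: Iterable[Placement],
    regions: Sequence[Region],
    read_length: int,
) -> DepthReport:
    """Count placements per region and derive depth = mapped_bases / length.

    A placement is attributed to a region when its start lies inside one of the
    region's intervals; every placement of a multi-placed read counts (so the
    doubled depth of a collapsed inverted repeat is visible).  For these
    full-length placements mapped_bases = mapped_reads x read_length.
    """
    for r in regions:
        if r.length <= 0:
            raise MappingParameterError(f"region {r.name} has zero length")
    counts = {r.name: 0 for r in regions}
    for p in placements:
        for r in regions:
            if r.ref_id != p.ref_id:
                continue
            if any(s <= p.start < e for s, e in r.intervals):
                counts[r.name] += 1
    rows = [
        DepthRow(r.name, counts[r.name], counts[r.name] * read_length, r.length)
        for r in regions
    ]
    return DepthReport(rows)


def write_sam(
    placements: Iterable[Placement],
    index: SeedIndex,
    path: str | Path,
    reads: Mapping[str, str] | None = None,
) -> None:
    """Minimal SAM export: QNAME/FLAG/RNAME/POS/CIGAR=<len>M with an NM tag."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rid, seq in index.refs.items():
            fh.write(f"@SQ\tSN:{rid}\tLN:{len(seq)}\n")
        for p in placements:
            flag = 16 if p.strand == "-" else 0
            seq = reads.get(p.read_id, "*") if reads else "*"
            if seq != "*" and p.strand == "-":
                seq = revcomp(seq)
            fh.write(
                f"{p.read_id or 'read'}\t{flag}\t{p.ref_id}\t{p.start + 1}\t255\t"
                f"{p.length}M\t*\t0\t0\t{seq}\t*\tNM:i:{p.mismatches}\n"
            )


def write_bed(intervals: list[tuple[int, int]], ref_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{ref_id}\t{s}\t{e}\n")
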