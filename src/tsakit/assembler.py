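"""Depth-stratified de Bruijn assembly.

The isolation mechanism of the two-step method: with the plastid stratum some
~20x deeper than the mitochondrial one and ~2000x deeper than nuclear, a large
kmer-frequency threshold keeps only the kmers of the deep stratum, and the
surviving graph assembles that compartment alone.

The graph is strand-symmetric: kmers are counted canonically (lexicographic
minimum of kmer and reverse complement) and every surviving kmer contributes
a directed edge in both orientations between its flanking (k-1)-mers.
Contigs are maximal non-branching paths (unitigs): paths are never extended
through a branch, and no bubble popping or tip clipping is done beyond the two
count thresholds, which keeps the behaviour auditable.  A contig whose first
and last (k-1)-mers coincide is a complete cycle; it is reported circular with
the duplicated overlap trimmed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import canonical, revcomp
from .readqc import ReadPair


class AssemblyParameterError(ValueError):
    """Raised for invalid assembly parameters (e.g. kmer longer than reads)."""


@dataclass(frozen=True)
class AssemblyParams:
    """Kmer size and count thresholds for one assembly pass.

    k must be odd (no reverse-complement-palindromic kmers) and >= 15.
    min_kmer_freq discards rare kmers before graph construction;
    min_edge_cov removes weakly supported edges; min_contig_len filters output.
    """

    k: int = 41
    min_kmer_freq: int = 20
    min_edge_cov: int = 20
    min_contig_len: int = 1000

    def __post_init__(self) -> None:
        if self.k < 15 or self.k % 2 == 0:
            raise AssemblyParameterError("k must be odd and >= 15")
        if min(self.min_kmer_freq, self.min_edge_cov, self.min_contig_len) < 1:
            raise AssemblyParameterError("thresholds must be >= 1")


@dataclass
class Contig:
    sequence: str
    coverage: float  # mean count of constituent canonical kmers
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ContigSet:
    contigs: list[Contig] = field(default_factory=list)
    k: int = 41

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    @property
    def total_bases(self) -> int:
        return sum(c.length for c in self.contigs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, c in enumerate(self.contigs):
                fh.write(
                    f">contig_{i} length={c.length} cov={c.coverage:.1f} "
                    f"circular={str(c.circular).lower()}\n"
                )
                for j in range(0, c.length, 70):
                    fh.write(c.sequence[j : j + 70] + "\n")


def _read_seqs(reads: Iterable[ReadPair | str]) -> Iterable[str]:
    for r in reads:
        if isinstance(r, str):
            yield r
        else:
            yield r.seq1
            yield r.seq2


def count_kmers(reads: Iterable[ReadPair | str], k: int) -> Counter:
    """Canonical kmer counts over all mates; kmers containing N are skipped."""
    counts: Counter = Counter()
    max_len = 0
    n_seqs = 0
    for seq in _read_seqs(reads):
        n_seqs += 1
        L = len(seq)
        if L > max_len:
            max_len = L
        if L < k:
            continue
        rc = revcomp(seq)
        if "N" in seq:
            kmers = []
            for i in range(L - k + 1):
                fwd = seq[i : i + k]
                if "N" in fwd:
                    continue
                rck = rc[L - k - i : L - i]
                kmers.append(fwd if fwd <= rck else rck)
        else:
            kmers = [
                fwd if fwd <= (rck := rc[L - k - i : L - i]) else rck
                for i in range(L - k + 1)
                for fwd in (seq[i : i + k],)
            ]
        counts.update(kmers)
    if n_seqs and not counts and max_len < k:
        raise AssemblyParameterError(f"k={k} exceeds the read length ({max_len})")
    return counts


def assemble_contigs(
    reads: Iterable[ReadPair | str],
    params: AssemblyParams,
    kmer_counts: Counter | None = None,
) -> ContigSet:
    """Threshold the canonical kmer graph and emit unitigs.

    Precomputed ``kmer_counts`` (from :func:`count_kmers` with the same k) may
    be supplied to avoid recounting.  Output order is deterministic: length
    descending, then lexicographic.
    """
    k = params.k
    counts = kmer_counts if kmer_counts is not None else count_kmers(reads, k)
    threshold = max(params.min_kmer_freq, params.min_edge_cov)
    solid = {km: c for km, c in counts.items() if c >= threshold}
    if not solid:
        return ContigSet([], k=k)

    # doubly stranded edge set: node = (k-1)-mer, edge = kmer
    out_edges: dict[str, list[str]] = {}
    indeg: Counter = Counter()
    for km in solid:
        for kmer in (km, revcomp(km)):
            u, v = kmer[:-1], kmer[1:]
            out_edges.setdefault(u, []).append(kmer)
            indeg[v] += 1
            if kmer == km and kmer == revcomp(km):  # cannot happen for odd k
                break

    def is_simple(v: str) -> bool:
        return len(out_edges.get(v, ())) == 1 and indeg[v] == 1

    visited: set[str] = set()  # oriented kmers consumed by a path

    def walk(start_kmer: str) -> str:
        path = [start_kmer]
        visited.add(start_kmer)
        v = start_kmer[1:]
        while is_simple(v):
            nxt = out_edges[v][0]
            if nxt in visited:
                break
            visited.add(nxt)
            path.append(nxt)
            v = nxt[1:]
        return path[0] + "".join(p[-1] for p in path[1:])

    raw: list[str] = []
    for u in sorted(out_edges):
        if is_simple(u):
            continue
        for kmer in out_edges[u]:
            if kmer not in visited:
                raw.append(walk(kmer))
    # remaining unvisited edges lie on perfect cycles
    for u in sorted(out_edges):
        for kmer in out_edges[u]:
            if kmer not in visited:
                raw.append(walk(kmer))

    def mean_cov(seq: str) -> float:
        vals = [solid[canonical(seq[i : i + k])] for i in range(len(seq) - k + 1)]
        return sum(vals) / len(vals)

    seen_keys: set = set()
    contigs: list[Contig] = []
    for seq in raw:
        circular = len(seq) > 2 * (k - 1) and seq[: k - 1] == seq[-(k - 1) :]
        if circular:
            seq_t = seq[: len(seq) - (k - 1)]
            key = frozenset(canonical(seq[i : i + k]) for i in range(len(seq) - k + 1))
        else:
            seq_t = seq
            key = min(seq, revcomp(seq))
        if key in seen_keys:
            continue
        seen_keys.add(key)
        if len(seq_t) < params.min_contig_len:
            continue
        cov = mean_cov(seq)
        contigs.append(Contig(min(seq_t, revcomp(seq_t)), cov, circular))
    contigs.sort(key=lambda c: (-c.length, c.sequence))
    return ContigSet(contigs, k=k)
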