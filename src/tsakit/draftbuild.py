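"""Reference-guided ordering of assembled scaffolds into an N-gapped draft.

Scaffolds are placed on the reference by chaining exact anchor kmers that are
unique in the reference (kmers inside a collapsed inverted repeat occur twice
and are excluded, so repeat-only scaffolds are reported unplaceable rather
than guessed).  Placed scaffolds are ordered and oriented by reference
position and joined: seamlessly where their sequence ends share an exact
overlap, otherwise with a run of N sized by the reference-implied distance.
Sample-specific insertions inside a scaffold survive untouched — only the
ordering consults the reference.

For circular references the chain is lifted onto the dominant diagonal modulo
the reference length, so a scaffold spanning the origin still places; the
wrap-around gap between the last and first scaffolds is internalised by
starting the draft mid-scaffold, which keeps downstream gap closure a purely
linear problem.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from ._seq import canonical, revcomp


class AmbiguityError(ValueError):
    """Two scaffolds claim the same reference interval with conflicting sequence."""


@dataclass
class AnchorRun:
    scaffold_pos: int
    ref_pos: int  # lifted coordinate (may exceed reference length on circular refs)
    length: int


@dataclass
class ScaffoldAlignment:
    scaffold_id: str
    strand: str
    ref_start: int  # implied start of the full scaffold, lifted coordinates
    ref_end: int
    coverage: float  # fraction of scaffold length covered by chained anchors
    chain: list[AnchorRun]
    scaffold_length: int
    circular_scaffold: bool = False


def _lis_chain(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing ref positions (matches sorted by
    scaffold position)."""
    tails: list[int] = []  # ref_pos of best chain of each length
    tails_idx: list[int] = []
    parent = [-1] * len(matches)
    for i, (_, rp) in enumerate(matches):
        j = bisect_left(tails, rp)
        if j == len(tails):
            tails.append(rp)
            tails_idx.append(i)
        else:
            tails[j] = rp
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    if not tails_idx:
        return []
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(matches[i])
        i = parent[i]
    return chain[::-1]


def _compress_runs(chain: list[tuple[int, int]], k: int) -> list[AnchorRun]:
    runs: list[AnchorRun] = []
    for sp, rp in chain:
        if runs and sp == runs[-1].scaffold_pos + runs[-1].length - k + 1 and rp - sp == runs[-1].ref_pos - runs[-1].scaffold_pos:
            runs[-1].length += 1
        else:
            runs.append(AnchorRun(sp, rp, k))
    return runs


def unique_kmer_positions(reference: str, k: int) -> dict[str, int]:
    """Kmers occurring exactly once in the reference, counted strand-symmetrically.

    A kmer inside an inverted repeat occurs once forward and once as a reverse
    complement, so it is excluded — repeat-only scaffolds then place nowhere
    instead of being assigned to one repeat copy silently.
    """
    counts: Counter = Counter(
        canonical(reference[i : i + k]) for i in range(len(reference) - k + 1)
    )
    pos: dict[str, int] = {}
    for i in range(len(reference) - k + 1):
        km = reference[i : i + k]
        if counts[canonical(km)] == 1:
            pos[km] = i
    return pos


def align_scaffold(
    scaffold: str,
    reference: str,
    anchor_k: int = 31,
    min_coverage: float = 0.5,
    circular: bool = False,
    scaffold_id: str = "scaffold",
    unique_pos: dict[str, int] | None = None,
    diag_band: int = 200,
) -> ScaffoldAlignment | None:
    """Place one scaffold on the reference by unique-anchor chaining.

    Returns None when the chained anchors cover less than ``min_coverage`` of
    the scaffold (unrelated sequence, or a repeat-only scaffold with no unique
    anchors).  On circular references anchors are lifted onto the dominant
    diagonal modulo the reference length before chaining, tolerating indels up
    to ``diag_band``.
    """
    if anchor_k < 15:
        raise ValueError("anchor_k must be >= 15")
    reference = reference.upper()
    L = len(reference)
    if unique_pos is None:
        unique_pos = unique_kmer_positions(reference, anchor_k)
    best: ScaffoldAlignment | None = None
    for strand in ("+", "-"):
        seq = scaffold.upper() if strand == "+" else revcomp(scaffold.upper())
        matches = []
        for i in range(len(seq) - anchor_k + 1):
            rp = unique_pos.get(seq[i : i + anchor_k])
            if rp is not None:
                matches.append((i, rp))
        if not matches:
            continue
        if circular:
            diags = Counter(((rp - sp) % L) // max(1, diag_band) for sp, rp in matches)
            mode_bin = max(diags.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            mode = mode_bin * max(1, diag_band)
            lifted = []
            for sp, rp in matches:
                off = ((rp - sp - mode) + L // 2) % L - L // 2
                if abs(off) > 2 * diag_band + L // 4:
                    continue
                lifted.append((sp, sp + mode + off))
            matches = sorted(lifted)
        chain = _lis_chain(matches)
        if not chain:
            continue
        covered = _merge_len([(sp, sp + anchor_k) for sp, _ in chain])
        cov = covered / len(seq)
        if cov < min_coverage:
            continue
        runs = _compress_runs(chain, anchor_k)
        start = chain[0][1] - chain[0][0]
        cand = ScaffoldAlignment(
            scaffold_id=scaffold_id,
            strand=strand,
            ref_start=start,
            ref_end=start + len(seq),
            coverage=cov,
            chain=runs,
            scaffold_length=len(seq),
        )
        if best is None or cand.coverage > best.coverage:
            best = cand
    return best


def _merge_len(iv: list[tuple[int, int]]) -> int:
    iv = sorted(iv)
    total = 0
    prev_end = -1
    for s, e in iv:
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
        prev_end = max(prev_end, e)
    return total


@dataclass
class LayoutEntry:
    scaffold_id: str
    strand: str
    draft_start: int
    length: int


@dataclass
class GapEntry:
    start: int
    end: int
    provenance: str  # inter-scaffold | unfilled | residual


@dataclass
class DraftGenome:
    """A reference-ordered concatenation of scaffolds with N-run gaps."""

    sequence: str
    layout: list[LayoutEntry] = field(default_factory=list)
    gap_provenance: dict[int, str] = field(default_factory=dict)
    circular: bool = False

    def gaps(self) -> list[GapEntry]:
        """N runs in the sequence, with recorded provenance where known."""
        out = []
        i = 0
        n = len(self.sequence)
        while i < n:
            if self.sequence[i] == "N":
                j = i
                while j < n and self.sequence[j] == "N":
                    j += 1
                out.append(GapEntry(i, j, self.gap_provenance.get(i, "inter-scaffold")))
                i = j
            else:
                i += 1
        return out

    @property
    def n_count(self) -> int:
        return self.sequence.count("N")

    def to_fasta(self, path: str | Path, name: str = "draft") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name} length={len(self.sequence)} circular={str(self.circular).lower()}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    def layout_tsv(self) -> str:
        lines = ["scaffold_id\tstrand\tdraft_start\tlength"]
        lines += [f"{e.scaffold_id}\t{e.strand}\t{e.draft_start}\t{e.length}" for e in self.layout]
        return "\n".join(lines) + "\n"


def _exact_overlap(a: str, b: str, min_overlap: int, cap: int) -> int:
    """Largest o in [min_overlap, cap] with a[-o:] == b[:o]; 0 if none."""
    cap = min(cap, len(a), len(b))
    for o in range(cap, min_overlap - 1, -1):
        if a[-o:] == b[:o]:
            return o
    return 0


def build_draft(
    alignments: Sequence[ScaffoldAlignment],
    scaffolds: Mapping[str, str],
    reference: str,
    min_overlap: int = 30,
    gap_floor: int = 100,
    circular: bool = False,
) -> DraftGenome:
    """Order, orient and join placed scaffolds into an N-gapped draft.

    Adjacent scaffolds sharing an exact end overlap >= min_overlap are joined
    seamlessly; otherwise an N run of max(reference-implied distance,
    gap_floor) separates them.  Heavily overlapping reference claims with
    irreconcilable sequences raise :class:`AmbiguityError` rather than picking
    one silently (a redundant scaffold contained verbatim in another is simply
    dropped).  On circular references the wrap-around gap is internalised by
    rotating the layout to start mid-way through the first scaffold.
    """
    if not alignments:
        raise ValueError("no alignments to build a draft from")
    L = len(reference)
    alns = sorted(alignments, key=lambda a: (a.ref_start % L if circular else a.ref_start, a.scaffold_id))
    oriented = {
        a.scaffold_id: (
            scaffolds[a.scaffold_id].upper()
            if a.strand == "+"
            else revcomp(scaffolds[a.scaffold_id].upper())
        )
        for a in alns
    }

    # single complete circular scaffold: the draft is the scaffold itself
    if circular and len(alns) == 1 and alns[0].circular_scaffold:
        a = alns[0]
        seq = oriented[a.scaffold_id]
        return DraftGenome(seq, [LayoutEntry(a.scaffold_id, a.strand, 0, len(seq))], {}, True)

    # drop scaffolds wholly contained (verbatim) in another placed scaffold
    keep: list[ScaffoldAlignment] = []
    for a in alns:
        contained = False
        for b in alns:
            if a is b or a.scaffold_length > b.scaffold_length:
                continue
            sa, ea = a.ref_start, a.ref_end
            sb, eb = b.ref_start, b.ref_end
            if sb <= sa and ea <= eb:
                if oriented[a.scaffold_id] in oriented[b.scaffold_id]:
                    contained = True
                else:
                    raise AmbiguityError(
                        f"scaffolds {a.scaffold_id} and {b.scaffold_id} claim the same "
                        f"reference interval with conflicting sequences"
                    )
                break
        if not contained:
            keep.append(a)
    alns = keep

    pieces: list[tuple[str, str, str]] = []  # (kind, payload, scaffold_id)
    for i, a in enumerate(alns):
        pieces.append(("scaffold", oriented[a.scaffold_id], a.scaffold_id))
        nxt = alns[(i + 1) % len(alns)]
        last = i == len(alns) - 1
        if last and not circular:
            break
        if last:
            dist = (nxt.ref_start - a.ref_end) % L
            if dist > L // 2:
                dist -= L
        else:
            dist = nxt.ref_start - a.ref_end
        seq_a = oriented[a.scaffold_id]
        seq_b = oriented[nxt.scaffold_id]
        cap = max(min_overlap, -dist + 500, 500)
        o = _exact_overlap(seq_a, seq_b, min_overlap, cap)
        if o:
            pieces.append(("join", str(o), ""))
        else:
            pieces.append(("gap", "N" * max(dist, gap_floor), ""))

    # assemble pieces, applying seamless joins by trimming the next scaffold
    segs: list[tuple[str, str, str]] = []
    trim_next = 0
    for kind, payload, sid in pieces:
        if kind == "scaffold":
            seq = payload[trim_next:]
            trim_next = 0
            segs.append(("scaffold", seq, sid))
        elif kind == "join":
            trim_next = int(payload)
        else:
            segs.append(("gap", payload, ""))
    if trim_next:  # circular closure: the wrap join trims the first scaffold
        first = segs[0]
        segs[0] = (first[0], first[1][trim_next:], first[2])

    if circular and segs and segs[-1][0] == "gap":
        # rotate: start the draft mid-way through the first scaffold so the
        # wrap gap sits internally with real sequence on both flanks
        first_kind, first_seq, first_id = segs[0]
        r = len(first_seq) // 2
        segs = [(first_kind, first_seq[r:], first_id)] + segs[1:] + [(first_kind, first_seq[:r], first_id)]

    sequence_parts: list[str] = []
    layout: list[LayoutEntry] = []
    gap_prov: dict[int, str] = {}
    pos = 0
    strand_of = {a.scaffold_id: a.strand for a in alns}
    for kind, payload, sid in segs:
        if kind == "scaffold":
            if payload:
                layout.append(LayoutEntry(sid, strand_of[sid], pos, len(payload)))
        else:
            gap_prov[pos] = "inter-scaffold"
        sequence_parts.append(payload)
        pos += len(payload)
    return DraftGenome("".join(sequence_parts), layout, gap_prov, circular)
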