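"""Strict iterative gap closure by anchored mate extension.

One cycle: map all reads to the draft; keep pairs with at least one mate
placed exactly (full length, zero mismatches — N in the draft matches
nothing); use the anchored mate's position and the library's insert geometry
to collect the unanchored mates expected to fall over a gap; grow each gap
flank base by base under a strict-majority vote with a minimum support floor.
When the two growing flanks of a gap meet with an exact overlap the gap
closes and its residual Ns disappear; otherwise the N run shrinks by the
extension amounts.  Cycles repeat until no gap extends (globally) or an
iteration cap is reached.  A majority tie stops extension at that base —
never a guessed base.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

from ._seq import revcomp
from .draftbuild import DraftGenome, GapEntry
from .exactmap import Placement, SeedIndex, map_read
from .readqc import ReadPair


@dataclass
class GapCloseParams:
    """Insert geometry and voting thresholds for gap closure."""

    insert_mean: int = 500
    insert_sd: float = 50.0
    min_support: int = 3
    seed_k: int = 31
    overlap_k: int = 50  # exact prefix length that places a fill read on the growing tip
    splice_k: int = 40  # exact overlap required for two flank extensions to meet
    max_iter: int = 20

    @property
    def insert_max(self) -> int:
        return int(self.insert_mean + 3 * self.insert_sd)

    @property
    def insert_min(self) -> int:
        return max(0, int(self.insert_mean - 3 * self.insert_sd))


@dataclass
class GapExtensionReport:
    iteration: int
    pairs_mapped: int
    pairs_kept: int
    extensions: list[tuple[int, int, int]] = field(default_factory=list)  # (gap_start, left, right)
    gaps_closed: int = 0  # cumulative closed gaps after this iteration

    @property
    def bases_extended(self) -> int:
        return sum(l + r for _, l, r in self.extensions)


@dataclass
class AnchoredPair:
    pair: ReadPair
    placements1: list[Placement]
    placements2: list[Placement]


def anchored_pairs(
    pairs: list[ReadPair], draft: DraftGenome, seed_k: int = 31
) -> list[AnchoredPair]:
    """Pairs with >=1 mate exactly and fully placed on the draft, with anchors."""
    if not draft.sequence.strip("N"):
        raise ValueError("draft is empty")
    index = SeedIndex({"draft": draft.sequence}, seed_k=seed_k)
    kept = []
    for p in pairs:
        pl1 = map_read(p.seq1, index, 0, read_id=p.id, mate=1)
        pl2 = map_read(p.seq2, index, 0, read_id=p.id, mate=2)
        if pl1 or pl2:
            kept.append(AnchoredPair(p, pl1, pl2))
    return kept


def _candidates_for_gap(
    kept: list[AnchoredPair], gap: GapEntry, params: GapCloseParams, read_length_hint: int
) -> list[str]:
    """Unanchored mates whose anchored partner places them over the gap, oriented
    to the draft's forward strand."""
    lo = gap.start - params.insert_max
    hi = gap.end + params.insert_max
    out: list[str] = []
    seen: set[tuple[str, int]] = set()
    for ap in kept:
        for mate_idx, placements, partner_seq in (
            (1, ap.placements1, ap.pair.seq2),
            (2, ap.placements2, ap.pair.seq1),
        ):
            # the partner is usable fill material even when it also places
            # somewhere on the draft: a read inside one inverted-repeat copy
            # always maps to the other copy, yet its pair geometry says it
            # belongs over the gap.  Placement on the growing tip still
            # requires an exact overlap, so mis-recruited reads never vote.
            if not placements or "N" in partner_seq:
                continue
            rl = len(partner_seq)
            for pl in placements:
                if pl.strand == "+":
                    w0 = pl.start + params.insert_min - rl
                    w1 = pl.start + params.insert_max
                    oriented = revcomp(partner_seq)
                else:
                    w0 = pl.end - params.insert_max
                    w1 = pl.end - params.insert_min + rl
                    oriented = partner_seq
                if w1 < lo or w0 > hi:
                    continue
                key = (ap.pair.id, mate_idx)
                if key in seen:
                    break
                seen.add(key)
                out.append(oriented)
                break
    return out


def _vote_extend(
    tail: str, candidates: list[str], params: GapCloseParams, cap: int
) -> tuple[str, str]:
    """Grow ``tail`` rightward by strict-majority voting among candidate reads.

    A candidate is placed once its first ``overlap_k`` bases match the
    assembled sequence exactly (and the rest of its current overlap verifies);
    placed reads vote one base each per position.  Returns (extension,
    stop_reason).
    """
    olap = params.overlap_k
    index: dict[str, list[str]] = defaultdict(list)
    for c in candidates:
        if len(c) >= olap:
            index[c[:olap]].append(c)
    assembled = tail
    base0 = len(tail)
    votes: dict[int, Counter] = defaultdict(Counter)
    # j scans candidate start positions as the tip grows past them
    j = max(0, base0 - max((len(c) for c in candidates), default=olap))
    ext = 0
    reason = "exhausted"

    def place_at(j: int) -> None:
        key = assembled[j : j + olap]
        for c in index.pop(key, ()):  # each candidate is placed at most once
            avail = min(len(c), len(assembled) - j)
            if c[:avail] != assembled[j : j + avail]:
                continue
            for t in range(avail, len(c)):
                votes[j + t][c[t]] += 1

    while True:
        while j + olap <= len(assembled):
            place_at(j)
            j += 1
        p = len(assembled)
        vc = votes.get(p)
        if not vc:
            break
        (top_base, top_n), *rest = vc.most_common(2) if len(vc) > 1 else [vc.most_common(1)[0]]
        total = sum(vc.values())
        if top_n < params.min_support:
            reason = "support"
            break
        if rest and rest[0][1] == top_n:
            reason = "tie"
            break
        if 2 * top_n <= total:
            reason = "majority"
            break
        assembled += top_base
        ext += 1
        if ext >= cap:
            reason = "cap"
            break
    return assembled[base0:], reason


def _splice(left_str: str, right_str: str, splice_k: int) -> int:
    """Largest exact overlap >= splice_k between the end of left_str and the
    start of right_str; 0 if none."""
    cap = min(len(left_str), len(right_str))
    for o in range(cap, splice_k - 1, -1):
        if left_str[-o:] == right_str[:o]:
            return o
    return 0


def extend_gaps(
    draft: DraftGenome,
    kept: list[AnchoredPair],
    params: GapCloseParams,
) -> tuple[DraftGenome, list[tuple[int, int, int]], int]:
    """One round of flank extension over every gap.

    Returns (new draft, per-gap (start, left_ext, right_ext), gaps closed this
    round).  Non-gap bases are never rewritten: extensions insert between the
    existing flanks, replacing only Ns.
    """
    gaps = draft.gaps()
    if not gaps or not kept:
        return draft, [(g.start, 0, 0) for g in gaps], 0
    read_len = len(kept[0].pair.seq1)
    seq = draft.sequence
    edits: list[tuple[int, int, str]] = []  # (start, end, replacement) over [flankL, flankR]
    stats: list[tuple[int, int, int]] = []
    closed = 0
    flank_w = 2 * read_len + params.overlap_k
    for gi, g in enumerate(gaps):
        cands = _candidates_for_gap(kept, g, params, read_len)
        gap_len = g.end - g.start
        # bound the per-round overshoot so a splice, if any, lands inside the
        # retained flank window
        cap = gap_len + 2 * read_len
        # flank windows are kept disjoint between neighbouring gaps (split at
        # the midpoint) so the per-gap sequence edits never overlap
        left_bound = 0 if gi == 0 else (gaps[gi - 1].end + g.start + 1) // 2
        right_bound = len(seq) if gi == len(gaps) - 1 else (g.end + gaps[gi + 1].start) // 2
        fl_start = max(left_bound, g.start - flank_w)
        left_flank = seq[fl_start : g.start]
        if "N" in left_flank:
            fl_start += left_flank.rindex("N") + 1
            left_flank = seq[fl_start : g.start]
        fr_end = min(right_bound, g.end + flank_w)
        right_flank = seq[g.end : fr_end]
        if "N" in right_flank:
            fr_end = g.end + right_flank.index("N")
            right_flank = seq[g.end : fr_end]
        left_ext, _ = _vote_extend(left_flank, cands, params, cap)
        rc_cands = [revcomp(c) for c in cands]
        right_ext_rc, _ = _vote_extend(revcomp(right_flank), rc_cands, params, cap)
        right_ext = revcomp(right_ext_rc)
        left_str = left_flank + left_ext
        right_str = right_ext + right_flank
        o = _splice(left_str, right_str, params.splice_k) if (left_ext or right_ext) else 0
        if o:
            fill = left_str + right_str[o:]
            edits.append((fl_start, fr_end, fill))
            closed += 1
            stats.append((g.start, len(left_ext), len(right_ext)))
        else:
            residual = max(gap_len - len(left_ext) - len(right_ext), 1)
            if left_ext or right_ext:
                fill = left_str + "N" * residual + right_str
                edits.append((fl_start, fr_end, fill))
            stats.append((g.start, len(left_ext), len(right_ext)))
    new_seq = seq
    for start, end, repl in sorted(edits, reverse=True):
        new_seq = new_seq[:start] + repl + new_seq[end:]
    new_prov = {}
    new_draft = DraftGenome(new_seq, draft.layout, new_prov, draft.circular)
    return new_draft, stats, closed


def close_gaps_iterative(
    draft: DraftGenome,
    pairs: list[ReadPair],
    params: GapCloseParams | None = None,
) -> tuple[DraftGenome, list[GapExtensionReport]]:
    """Alternate mapping, anchored filtering and gap extension to a fixpoint.

    Stops when an iteration extends zero bases everywhere (the global reading
    of "no gap extends") or after ``max_iter`` iterations, in which case a
    warning is emitted and the residual gaps stay in the returned draft's gap
    table for downstream finishing (e.g. targeted PCR).
    """
    params = params or GapCloseParams()
    reports: list[GapExtensionReport] = []
    closed_total = 0
    current = draft
    for it in range(1, params.max_iter + 1):
        if not current.gaps():
            break
        kept = anchored_pairs(pairs, current, seed_k=params.seed_k)
        current, stats, closed = extend_gaps(current, kept, params)
        closed_total += closed
        rep = GapExtensionReport(
            iteration=it,
            pairs_mapped=len(kept),
            pairs_kept=len(kept),
            extensions=stats,
            gaps_closed=closed_total,
        )
        reports.append(rep)
        if rep.bases_extended == 0 and closed == 0:
            break
    else:
        if current.gaps() and reports and reports[-1].bases_extended > 0:
            warnings.warn("iteration cap reached with gaps still extending", stacklevel=2)
    return current, reports
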