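"""Iterative anchored gap closure: voting extension, splicing, fixpoints."""

import numpy as np
import pytest

from tsakit import gapclose, simgen
from tsakit._seq import revcomp
from tsakit.draftbuild import DraftGenome
from tsakit.gapclose import GapCloseParams, _vote_extend, close_gaps_iterative
from tsakit.readqc import ReadPair


def _paired_reads(genome, n, seed, rl=100, insert=500, sd=50):
    """Error-free inner-oriented pairs from a circular genome."""
    rng = np.random.default_rng(seed)
    ext = genome + genome
    q = "I" * rl
    out = []
    for i in range(n):
        ins = int(np.clip(round(rng.normal(insert, sd)), 2 * rl, len(genome)))
        s = int(rng.integers(0, len(genome)))
        frag = ext[s : s + ins]
        fwd, rev = frag[:rl], revcomp(frag[-rl:])
        if rng.integers(0, 2):
            out.append(ReadPair(f"p{i}", rev, q, fwd, q))
        else:
            out.append(ReadPair(f"p{i}", fwd, q, rev, q))
    return out


@pytest.fixture(scope="module")
def truth_and_reads():
    genome = simgen.random_sequence(6000, np.random.default_rng(30))
    reads = _paired_reads(genome, 1500, seed=31)  # ~50x
    return genome, reads


def test_gap_closed_exactly(truth_and_reads):
    genome, reads = truth_and_reads
    draft = DraftGenome(genome[:2000] + "N" * 200 + genome[2200:])
    final, reports = close_gaps_iterative(draft, reads, GapCloseParams(min_support=3))
    assert final.gaps() == []
    assert final.sequence == genome


def test_zero_kept_pairs_leaves_draft_unchanged():
    genome = simgen.random_sequence(2000, np.random.default_rng(32))
    draft = DraftGenome(genome[:900] + "N" * 100 + genome[1000:])
    unrelated = _paired_reads(simgen.random_sequence(3000, np.random.default_rng(33)), 50, 34)
    final, reports = close_gaps_iterative(draft, unrelated, GapCloseParams())
    assert final.sequence == draft.sequence
    assert reports[0].pairs_kept == 0 and reports[0].bases_extended == 0


def test_gapless_draft_returns_immediately(truth_and_reads):
    genome, reads = truth_and_reads
    final, reports = close_gaps_iterative(DraftGenome(genome), reads, GapCloseParams())
    assert final.sequence == genome and reports == []


def test_n_count_non_increasing_and_flanks_untouched(truth_and_reads):
    genome, reads = truth_and_reads
    left = genome[:1500]
    right = genome[4500:]
    draft = DraftGenome(left + "N" * 3000 + right)  # too wide to close in one round
    params = GapCloseParams(min_support=3, max_iter=1)
    current = draft
    n_prev = current.n_count
    for _ in range(3):
        kept = gapclose.anchored_pairs(reads, current, seed_k=params.seed_k)
        current, stats, closed = gapclose.extend_gaps(current, kept, params)
        assert current.n_count <= n_prev
        n_prev = current.n_count
        assert current.sequence.startswith(left[:1200])
        assert current.sequence.endswith(right[-1200:])


def test_extensions_write_only_true_bases(truth_and_reads):
    """With error-free reads every base written by extension matches the truth
    genome (min_support=1)."""
    genome, reads = truth_and_reads
    draft = DraftGenome(genome[:2500] + "N" * 400 + genome[2900:])
    final, _ = close_gaps_iterative(draft, reads, GapCloseParams(min_support=1))
    assert final.sequence == genome


def test_iteration_report_monotone_closed(truth_and_reads):
    genome, reads = truth_and_reads
    draft = DraftGenome(
        genome[:1000] + "N" * 150 + genome[1150:3000] + "N" * 150 + genome[3150:]
    )
    final, reports = close_gaps_iterative(draft, reads, GapCloseParams())
    closed = [r.gaps_closed for r in reports]
    assert closed == sorted(closed)
    assert final.gaps() == [] and final.sequence == genome


def test_vote_tie_stops_extension():
    tail = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"  # 50 nt
    cands = [tail + "A", tail + "T"]  # 1 vote each beyond the tip -> tie
    params = GapCloseParams(min_support=1, overlap_k=50)
    ext, reason = _vote_extend(tail, cands, params, cap=10)
    assert ext == "" and reason == "tie"


def test_min_support_floor_blocks_single_voter():
    tail = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"
    cands = [tail + "GGGG"]
    ext, reason = _vote_extend(tail, cands, GapCloseParams(min_support=3, overlap_k=50), cap=10)
    assert ext == "" and reason == "support"
    ext, _ = _vote_extend(tail, cands * 3, GapCloseParams(min_support=3, overlap_k=50), cap=10)
    assert ext == "GGGG"


def test_homology_trap_gap_requires_full_read_pool(small_triple, small_library):
    """After plastid-pair removal the mito draft's tract gap cannot be filled
    from the surviving pool alone, but closes with all clean reads — the
    reason the closure stage maps the full read set."""
    from tsakit import exactmap

    pairs, truth, _ = small_library
    mito = small_triple.mito
    t0, t1 = small_triple.segment("mito", "tract")
    draft = DraftGenome(mito[: t0 + 100] + "N" * (t1 - t0 - 200) + mito[t1 - 100 :])
    idx = exactmap.build_index({"plastid": small_triple.plastid}, seed_k=31,
                               circular={"plastid"}, wrap=99)
    removed, survivors = exactmap.partition_pairs(pairs, idx)
    params = GapCloseParams()
    final_survivors, _ = close_gaps_iterative(draft, survivors, params)
    final_all, _ = close_gaps_iterative(draft, pairs, params)
    assert final_all.gaps() == [] and final_all.sequence == mito
    assert final_survivors.n_count > 0  # the hole cannot be repaired without them
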