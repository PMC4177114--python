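"""Seed-and-verify exact mapping, pair partitioning, masks and depth."""

import numpy as np
import pytest

from tsakit import exactmap, simgen
from tsakit._seq import hamming, revcomp
from tsakit.exactmap import (
    DepthRow,
    Region,
    build_index,
    depth_stats,
    map_read,
    partition_pairs,
    shared_region_mask,
    unique_regions,
)


def test_index_trivial_positions():
    idx = build_index("ACGTACGT", seed_k=4)
    assert sorted(pos for _, pos in idx.seeds["ACGT"]) == [0, 4]


def test_index_duplicate_reference_doubles_hits():
    idx = build_index({"a": "ACGTACGTCC", "b": "ACGTACGTCC"}, seed_k=4)
    assert len(idx.seeds["ACGT"]) == 4


def test_map_read_trivial_and_strand_symmetry():
    rng = np.random.default_rng(0)
    ref = simgen.random_sequence(2000, rng)
    idx = build_index(ref, seed_k=31)
    read = ref[100:200]
    (pl,) = map_read(read, idx)
    assert (pl.start, pl.strand, pl.mismatches) == (100, "+", 0)
    (pl,) = map_read(revcomp(read), idx)
    assert (pl.start, pl.strand) == (100, "-")


def test_one_substitution_needs_mismatch_budget():
    rng = np.random.default_rng(1)
    ref = simgen.random_sequence(1000, rng)
    read = ref[300:400]
    read = read[:50] + ("A" if read[50] != "A" else "C") + read[51:]
    idx = build_index(ref, seed_k=31)
    assert map_read(read, idx, 0) == []
    (pl,) = map_read(read, idx, 1)
    assert (pl.start, pl.mismatches) == (300, 1)


def test_n_in_read_never_matches_exactly():
    rng = np.random.default_rng(2)
    ref = simgen.random_sequence(500, rng)
    read = "N" + ref[101:200]
    idx = build_index(ref, seed_k=31)
    assert map_read(read, idx, 0) == []
    (pl,) = map_read(read, idx, 1)
    assert pl.start == 100


def test_map_read_agrees_with_brute_force_hamming_scan():
    rng = np.random.default_rng(7)
    ref = simgen.random_sequence(2000, rng)
    idx = build_index({"r": ref}, seed_k=20)
    for _ in range(60):
        s = int(rng.integers(0, 1900))
        read = ref[s : s + 100]
        if rng.integers(0, 2):
            read = revcomp(read)
        if rng.integers(0, 3) == 0:
            i = int(rng.integers(0, 100))
            read = read[:i] + "ACGT"[int(rng.integers(0, 4))] + read[i + 1 :]
        for mm in (0, 1, 2):
            got = {(p.start, p.strand, p.mismatches) for p in map_read(read, idx, mm)}
            brute = set()
            for st in range(len(ref) - 99):
                for strand, q in (("+", read), ("-", revcomp(read))):
                    h = hamming(q, ref[st : st + 100])
                    if h <= mm:
                        brute.add((st, strand, h))
            assert got == brute


def test_every_substring_of_circular_reference_self_maps():
    rng = np.random.default_rng(3)
    ref = simgen.random_sequence(3000, rng)
    idx = build_index({"r": ref}, seed_k=31, circular={"r"}, wrap=99)
    ext = ref + ref
    for s in range(0, len(ref), 7):
        placements = map_read(ext[s : s + 100], idx, 0)
        assert any(p.start == s and p.strand == "+" for p in placements)


def test_partition_is_exhaustive_and_exclusive(small_triple, small_library):
    pairs, truth, _ = small_library
    sub = pairs[:3000]
    idx = build_index({"plastid": small_triple.plastid}, seed_k=31,
                      circular={"plastid"}, wrap=99)
    mapped, unmapped = partition_pairs(sub, idx)
    assert len(mapped) + len(unmapped) == len(sub)
    ids_m = {p.id for p in mapped}
    ids_u = {p.id for p in unmapped}
    assert not ids_m & ids_u
    lab = truth.set_index("read_id").compartment
    # every pure plastid pair is removed; mito pairs away from the tract survive
    t0, t1 = small_triple.segment("mito", "tract")
    for p in sub:
        if lab[p.id] == "plastid":
            assert p.id in ids_m
    tract = small_triple.mito[t0:t1]
    for p in unmapped:
        if lab[p.id] == "mito":
            assert p.seq1 not in tract and revcomp(p.seq1) not in tract


def test_homology_tract_mate_removal(small_triple):
    """A pair with one mate inside the plastid-homologous tract is removed even
    though its other mate is pure mitochondrial — the origin of the mito gap."""
    t0, t1 = small_triple.segment("mito", "tract")
    mito = small_triple.mito
    in_tract = mito[t0 + 50 : t0 + 150]
    outside = mito[t0 - 400 : t0 - 300]
    pair = __import__("tsakit").readqc.ReadPair("h", outside, "I" * 100,
                                                revcomp(in_tract), "I" * 100)
    idx = build_index({"plastid": small_triple.plastid}, seed_k=31,
                      circular={"plastid"}, wrap=99)
    mapped, unmapped = partition_pairs([pair], idx)
    assert len(mapped) == 1 and not unmapped


def test_shared_mask_disjoint_random_sequences_empty():
    rng = np.random.default_rng(4)
    a = simgen.random_sequence(3000, rng)
    b = simgen.random_sequence(3000, rng)
    ma, mb = shared_region_mask(a, b, 100)
    assert ma == [] and mb == []


def test_shared_mask_recovers_planted_tract(small_triple):
    s0, s1 = small_triple.segment("plastid", "tract_source")
    t0, t1 = small_triple.segment("mito", "tract")
    mask_pt, mask_mt = shared_region_mask(small_triple.plastid, small_triple.mito, 100)
    # besides the tract, the plastid's own IRs are not inter-genome shared
    assert len(mask_mt) == 1
    (g0, g1) = mask_mt[0]
    assert abs(g0 - t0) <= 99 and abs(g1 - t1) <= 99
    assert any(abs(g0 - s0) <= 99 and abs(g1 - s1) <= 99 for g0, g1 in mask_pt)


def test_shared_mask_identical_sequences_full_cover():
    rng = np.random.default_rng(5)
    a = simgen.random_sequence(500, rng)
    ma, mb = shared_region_mask(a, a, 100)
    assert ma == [(0, 500)] and mb == [(0, 500)]


def test_unique_regions_complement():
    assert unique_regions(1000, [(100, 300), (900, 1000)]) == [(0, 100), (300, 900)]
    assert unique_regions(100, []) == [(0, 100)]


def test_depth_row_rounding_arithmetic():
    assert DepthRow("x", 10, 1000, 300).depth == 3
    assert DepthRow("x", 10, 1050, 300).depth == 4  # 3.5 rounds away from zero
    with pytest.raises(exactmap.MappingParameterError):
        DepthRow("x", 0, 0, 0).depth


def test_depth_stats_counts_and_linearity():
    region = Region("u", "r", [(0, 500)])
    pls = [exactmap.Placement("r", s, "+", 0, 100) for s in (0, 100, 499)]
    rep = depth_stats(pls, [region], 100)
    row = rep["u"]
    assert row.mapped_reads == 3 and row.mapped_bases == 300
    assert row.depth == 1  # 300/500 rounds to 1
    rep2 = depth_stats(pls + pls, [region], 100)
    assert rep2["u"].mapped_reads == 6 and rep2["u"].mapped_bases == 600
    empty = depth_stats([], [region], 100)
    assert empty["u"].depth == 0


def test_realized_unique_depth_matches_copy_fold_within_ten_percent(small_triple, small_library):
    """On error-free simulated reads the mitochondrial unique-region depth lands
    within 10% of the copy-fold expectation."""
    pairs, truth, params = small_library
    expected = simgen.expected_depths(small_triple, params)
    mask_pt, mask_mt = shared_region_mask(small_triple.plastid, small_triple.mito, 100)
    region = Region("mito_unique", "mito", unique_regions(len(small_triple.mito), mask_mt))
    idx = build_index({"mito": small_triple.mito}, seed_k=31, circular={"mito"}, wrap=99)
    placements = []
    for p in pairs:
        placements.extend(map_read(p.seq1, idx, 0))
        placements.extend(map_read(p.seq2, idx, 0))
    depth = depth_stats(placements, [region], params.read_length)["mito_unique"].depth
    assert depth == pytest.approx(expected["mito"], rel=0.10)


def test_sam_export_readable_by_pysam(tmp_path):
    import pysam

    rng = np.random.default_rng(6)
    ref = simgen.random_sequence(400, rng)
    idx = build_index({"chr": ref}, seed_k=31)
    pls = map_read(ref[50:150], idx, 0, read_id="r1")
    out = tmp_path / "out.sam"
    exactmap.write_sam(pls, idx, out, reads={"r1": ref[50:150]})
    with pysam.AlignmentFile(str(out), "r") as fh:
        recs = list(fh)
    assert len(recs) == 1
    assert recs[0].reference_start == 50 and recs[0].cigarstring == "100M"
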