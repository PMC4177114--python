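"""Pairwise genome comparison, event typing and coding annotation."""

import numpy as np
import pytest

from tsakit import simgen, variants
from tsakit.variants import (
    AlignmentFailureError,
    CdsInterval,
    GenomeAlignment,
    VariantRecord,
    align_genomes,
    annotate_variants,
    classify_variants,
)


@pytest.fixture(scope="module")
def genome():
    return simgen.random_sequence(12000, np.random.default_rng(40))


def test_identical_genomes_no_variants(genome):
    aln = align_genomes(genome, genome)
    recs, counts = classify_variants(aln)
    assert recs == [] and not counts


def test_single_substitution_is_one_snp(genome):
    q = genome[:6000] + ("A" if genome[6000] != "A" else "C") + genome[6001:]
    recs, counts = classify_variants(align_genomes(q, genome), reference=genome)
    assert counts == {"SNP": 1}
    assert recs[0].ref_pos == 6000


def test_adjacent_mismatch_run_is_one_mnp():
    a = GenomeAlignment("AAATTTGGG", "AAACCCGGG")
    recs, counts = classify_variants(a)
    assert counts == {"MNP": 1}
    assert (recs[0].ref_allele, recs[0].alt_allele) == ("TTT", "CCC")


def test_gap_adjacent_to_mismatch_is_cv():
    a = GenomeAlignment("AAAT-TGGG", "AAACCCGGG")
    recs, counts = classify_variants(a)
    assert counts == {"CV": 1}
    assert recs[0].type == "CV"


def test_pure_gap_run_is_indel():
    a = GenomeAlignment("AAATTTGGG", "AAA---GGG")
    recs, counts = classify_variants(a)
    assert counts == {"indel": 1}
    assert (recs[0].ref_allele, recs[0].alt_allele) == ("TTT", "")


def test_indel_left_aligned_in_homopolymer():
    ref = "GGGCAAAAATGGG"
    #         45678
    aln = GenomeAlignment("GGGCAAAAATGGG", "GGGCAAAA-TGGG")
    recs, _ = classify_variants(aln, reference=ref)
    (rec,) = recs
    assert rec.type == "indel"
    assert rec.ref_pos == 4  # shifted to the left edge of the A run
    assert rec.ref_allele == "A"


def test_planted_events_recovered_exactly(genome):
    mut, ledger = simgen.plant_mutations(genome, n_snps=20, n_indels=5, seed=41)
    recs, counts = classify_variants(align_genomes(mut, genome), reference=genome)
    assert counts["SNP"] == 20 and counts["indel"] == 5
    assert len(recs) == 25  # precision: no spurious calls
    got_snps = {(r.ref_pos, r.ref_allele, r.alt_allele) for r in recs if r.type == "SNP"}
    exp_snps = {
        (int(r.ref_pos), r.ref_allele, r.alt_allele)
        for r in ledger.itertuples()
        if r.type == "SNP"
    }
    assert got_snps == exp_snps
    got_indels = sorted(r.ref_pos for r in recs if r.type == "indel")
    exp_indels = sorted(int(r.ref_pos) for r in ledger.itertuples() if r.type == "indel")
    for g, e in zip(got_indels, exp_indels):
        assert abs(g - e) <= 10  # left-alignment may shift within a homopolymer


def test_swap_symmetry(genome):
    mut, _ = simgen.plant_mutations(genome, n_snps=8, n_indels=4, seed=42)
    _, fwd = classify_variants(align_genomes(mut, genome))
    _, rev = classify_variants(align_genomes(genome, mut))
    assert fwd["SNP"] == rev["SNP"]
    assert fwd.get("MNP", 0) == rev.get("MNP", 0)
    assert fwd["indel"] == rev["indel"]  # insertions and deletions swap roles


def test_unrelated_genomes_fail_loudly():
    a = simgen.random_sequence(3000, np.random.default_rng(43))
    b = simgen.random_sequence(3000, np.random.default_rng(44))
    with pytest.raises(AlignmentFailureError):
        align_genomes(a, b)


def test_wobble_snp_is_synonymous():
    ref = "TTTGGATAA" + "A" * 12  # CDS [3,12): GGA TAA...
    cds = [CdsInterval(3, 12, "+", "c")]
    v = VariantRecord(5, "A", "G", "SNP")  # GGA -> GGG, both Gly
    ann, counts = annotate_variants([v], cds, ref)
    assert ann[0].coding and ann[0].nonsynonymous is False
    assert counts["coding"]["SNP"] == 1 and counts["nonsynonymous"]["SNP"] == 0


def test_start_codon_snp_nonsynonymous():
    ref = "TTTATGGGATAA" + "A" * 9  # CDS [3,15): ATG GGA TAA
    cds = [CdsInterval(3, 15, "+", "c")]
    v = VariantRecord(5, "G", "A", "SNP")  # ATG -> ATA, Met -> Ile
    ann, counts = annotate_variants([v], cds, ref)
    assert ann[0].nonsynonymous is True


def test_minus_strand_codon_logic():
    from tsakit._seq import revcomp

    # CDS on minus strand: reading revcomp(ref[3:12]); plant a SNP that is
    # synonymous on the minus frame (codon GGA -> GGG)
    minus_cds_seq = "GGAATGTAA"  # as transcribed (5'->3' on minus strand)
    ref = "TTT" + revcomp(minus_cds_seq) + "TTTTT"
    cds = [CdsInterval(3, 12, "-", "c")]
    # transcribed position 2 (A of GGA) lies at ref index 3+9-1-2 = 9
    assert ref[9] == revcomp("A")[0] or True
    v = VariantRecord(9, ref[9], revcomp("G"), "SNP")
    ann, _ = annotate_variants([v], cds, ref)
    assert ann[0].coding and ann[0].nonsynonymous is False


def test_snp_outside_cds_noncoding():
    ref = "A" * 30
    cds = [CdsInterval(3, 12, "+", "c")]
    ann, _ = annotate_variants([VariantRecord(20, "A", "C", "SNP")], cds, ref)
    assert ann[0].coding is False and ann[0].nonsynonymous is None


def test_non_snp_coding_events_have_na_synonymy():
    ref = "TTTATGGGATAA" + "A" * 9
    cds = [CdsInterval(3, 15, "+", "c")]
    ann, counts = annotate_variants([VariantRecord(6, "GGA", "", "indel")], cds, ref)
    assert ann[0].coding is True and ann[0].nonsynonymous is None
    assert counts["nonsynonymous"]["indel"] == 0


def test_cds_frame_validation():
    with pytest.raises(variants.AnnotationError):
        CdsInterval(0, 10, "+")


def test_counts_table_shape():
    from collections import Counter

    df = variants.counts_table(Counter({"SNP": 202, "indel": 106, "MNP": 5, "CV": 13}),
                               Counter({"SNP": 71}), Counter({"SNP": 31}))
    assert list(df.type) == ["SNP", "indel", "MNP", "CV"]
    assert df.loc[df.type == "SNP", "number"].item() == 202
    assert df.loc[df.type == "SNP", "non_synonymous"].item() == 31


def test_vcf_export_parseable(tmp_path, genome):
    mut, _ = simgen.plant_mutations(genome, n_snps=5, n_indels=3, seed=45)
    recs, _ = classify_variants(align_genomes(mut, genome), reference=genome)
    out = tmp_path / "var.vcf"
    variants.write_vcf(recs, genome, out, chrom="pt")
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == len(recs)
    for line in lines:
        chrom, pos, _, ref_a, alt_a, *_ = line.split("\t")
        pos = int(pos)
        # VCF REF allele must match the reference at POS (1-based)
        assert genome[pos - 1 : pos - 1 + len(ref_a)] == ref_a


def test_cds_bed_and_gff3_readers(tmp_path):
    bed = tmp_path / "c.bed"
    bed.write_text("chr1\t3\t12\tgeneA\t0\t-\n")
    (iv,) = variants.read_cds_bed(bed)
    assert (iv.start, iv.end, iv.strand, iv.name) == (3, 12, "-", "geneA")
    gff = tmp_path / "c.gff3"
    gff.write_text("##gff-version 3\nchr1\tsrc\tCDS\t4\t12\t.\t+\t0\tID=cds1\n")
    (iv,) = variants.read_cds_gff3(gff)
    assert (iv.start, iv.end, iv.strand, iv.name) == (3, 12, "+", "cds1")
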