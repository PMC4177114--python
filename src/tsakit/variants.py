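"""Pairwise genome comparison and variant classification.

Two colinear genomes are aligned by chaining exact anchor kmers unique in
both sequences, then globally aligning each inter-anchor segment with unit
mismatch/gap costs (edlib).  Maximal runs of adjacent difference columns are
merged into single events and typed:

    SNP    one substituted base
    MNP    equal-length multi-base substitution, every position differing
    indel  pure insertion or deletion (one allele empty)
    CV     complex variation — a length-changing event with both alleles
           non-empty (mixed substitution/gap run)

Indels are left-aligned in homopolymer context for deterministic coordinates.
Coding annotation marks events overlapping a CDS; for coding SNPs the codon is
re-translated (standard genetic code, strand-aware) to call synonymy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from ._seq import revcomp
from .draftbuild import unique_kmer_positions, _lis_chain

_CODON = standard_dna_table.forward_table


class AlignmentFailureError(ValueError):
    """No chainable anchors between the two genomes (rearranged or unrelated)."""


class AnnotationError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One difference between query and reference, in reference coordinates."""

    ref_pos: int  # 0-based; for pure insertions, the insertion point
    ref_allele: str
    alt_allele: str
    type: str  # SNP | MNP | indel | CV
    coding: bool = False
    nonsynonymous: bool | None = None  # None = not applicable (non-SNP or non-coding)


@dataclass
class GenomeAlignment:
    """A gapped pairwise alignment as two equal-length strings over ACGTN-."""

    ref_aligned: str
    query_aligned: str

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.query_aligned):
            raise ValueError("aligned strings must have equal length")


def _cigar_to_alignment(query: str, ref: str, cigar: str) -> tuple[str, str]:
    qa, ra = [], []
    qi = ri = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            qa.append(query[qi : qi + n])
            ra.append(ref[ri : ri + n])
            qi += n
            ri += n
        elif ch == "I":  # consumes query
            qa.append(query[qi : qi + n])
            ra.append("-" * n)
            qi += n
        elif ch == "D":  # consumes reference
            qa.append("-" * n)
            ra.append(ref[ri : ri + n])
            ri += n
        else:
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    return "".join(ra), "".join(qa)


def _align_segment(query: str, ref: str) -> tuple[str, str]:
    if not query and not ref:
        return "", ""
    if not query:
        return ref, "-" * len(ref)
    if not ref:
        return "-" * len(query), query
    res = edlib.align(query, ref, mode="NW", task="path")
    return _cigar_to_alignment(query, ref, res["cigar"])


def align_genomes(query: str, reference: str, anchor_k: int = 31) -> GenomeAlignment:
    """Anchor-chained global alignment of two colinear genomes.

    Anchor kmers must be unique in both genomes; the largest colinear chain is
    kept and the segments between consecutive anchors aligned globally.
    Raises :class:`AlignmentFailureError` when no anchors chain (the method
    does not type variants across rearrangements).
    """
    query, reference = query.upper(), reference.upper()
    uq = unique_kmer_positions(query, anchor_k)
    ur = unique_kmer_positions(reference, anchor_k)
    matches = sorted(
        (qpos, ur[km]) for km, qpos in uq.items() if km in ur
    )
    chain = _lis_chain(matches)
    if not chain:
        raise AlignmentFailureError("no chainable unique anchors between genomes")
    ra_parts: list[str] = []
    qa_parts: list[str] = []
    prev_q = prev_r = 0
    for qpos, rpos in chain:
        if qpos < prev_q or rpos < prev_r:  # overlapping anchors; skip
            continue
        ra, qa = _align_segment(query[prev_q:qpos], reference[prev_r:rpos])
        ra_parts.append(ra)
        qa_parts.append(qa)
        ra_parts.append(reference[rpos : rpos + anchor_k])
        qa_parts.append(query[qpos : qpos + anchor_k])
        prev_q, prev_r = qpos + anchor_k, rpos + anchor_k
    ra, qa = _align_segment(query[prev_q:], reference[prev_r:])
    ra_parts.append(ra)
    qa_parts.append(qa)
    return GenomeAlignment("".join(ra_parts), "".join(qa_parts))


def _left_align_indel(rec: VariantRecord, reference: str) -> VariantRecord:
    pos, ref_a, alt_a = rec.ref_pos, rec.ref_allele, rec.alt_allele
    if ref_a and not alt_a:  # deletion
        while pos > 0 and reference[pos - 1] == ref_a[-1]:
            ref_a = reference[pos - 1] + ref_a[:-1]
            pos -= 1
    elif alt_a and not ref_a:  # insertion
        while pos > 0 and reference[pos - 1] == alt_a[-1]:
            alt_a = reference[pos - 1] + alt_a[:-1]
            pos -= 1
    return VariantRecord(pos, ref_a, alt_a, rec.type)


def classify_variants(
    alignment: GenomeAlignment, reference: str | None = None
) -> tuple[list[VariantRecord], Counter]:
    """Merge adjacent difference columns into events and type them.

    ``reference`` (the plain sequence) enables homopolymer left-alignment of
    indels; without it coordinates are as aligned.  Returns (records, counts
    by type).
    """
    ra, qa = alignment.ref_aligned, alignment.query_aligned
    records: list[VariantRecord] = []
    ref_pos = 0
    i = 0
    n = len(ra)
    while i < n:
        r, q = ra[i], qa[i]
        if r == q and r != "-":
            ref_pos += 1
            i += 1
            continue
        start_ref = ref_pos
        ref_allele = []
        alt_allele = []
        while i < n and (ra[i] != qa[i] or ra[i] == "-"):
            if ra[i] != "-":
                ref_allele.append(ra[i])
                ref_pos += 1
            if qa[i] != "-":
                alt_allele.append(qa[i])
            i += 1
        ref_s, alt_s = "".join(ref_allele), "".join(alt_allele)
        if len(ref_s) == len(alt_s) == 1:
            vtype = "SNP"
        elif len(ref_s) == len(alt_s):
            vtype = "MNP"
        elif not ref_s or not alt_s:
            vtype = "indel"
        else:
            vtype = "CV"
        rec = VariantRecord(start_ref, ref_s, alt_s, vtype)
        if vtype == "indel" and reference is not None:
            rec = _left_align_indel(rec, reference.upper())
        records.append(rec)
    counts = Counter(r.type for r in records)
    return records, counts


@dataclass
class CdsInterval:
    """One CDS with 0-based half-open coordinates; length must be a codon multiple."""

    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise AnnotationError(f"CDS {self.name or self.start}: length not divisible by 3")
        if self.strand not in "+-":
            raise AnnotationError("strand must be + or -")


def _translate_codon(codon: str) -> str:
    return _CODON.get(codon, "*")


def annotate_variants(
    variants: Iterable[VariantRecord],
    cds: Sequence[CdsInterval],
    reference: str,
) -> tuple[list[VariantRecord], dict[str, Counter]]:
    """Mark coding overlap and, for coding SNPs, synonymy.

    Returns annotated copies plus per-type counters of coding and
    non-synonymous events (non-SNP events never count as non-synonymous: their
    synonymy is not applicable).
    """
    reference = reference.upper()
    out: list[VariantRecord] = []
    coding_counts: Counter = Counter()
    nonsyn_counts: Counter = Counter()
    for v in variants:
        span_end = v.ref_pos + max(len(v.ref_allele), 1 if not v.ref_allele else 0)
        if not v.ref_allele:  # insertion point: coding if strictly inside a CDS
            overlaps = [c for c in cds if c.start < v.ref_pos < c.end]
        else:
            overlaps = [c for c in cds if c.start < span_end and v.ref_pos < c.end]
        coding = bool(overlaps)
        nonsyn: bool | None = None
        if coding and v.type == "SNP":
            c = overlaps[0]
            if c.strand == "+":
                off = v.ref_pos - c.start
                cstart = c.start + (off // 3) * 3
                codon_ref = reference[cstart : cstart + 3]
                codon_alt = list(codon_ref)
                codon_alt[off % 3] = v.alt_allele
            else:
                off = (c.end - 1) - v.ref_pos  # distance from the CDS 5' end on -
                cstart_hi = c.end - (off // 3) * 3
                codon_ref = revcomp(reference[cstart_hi - 3 : cstart_hi])
                codon_alt = list(codon_ref)
                codon_alt[off % 3] = revcomp(v.alt_allele)
            nonsyn = _translate_codon(codon_ref) != _translate_codon("".join(codon_alt))
        out.append(VariantRecord(v.ref_pos, v.ref_allele, v.alt_allele, v.type, coding, nonsyn))
        if coding:
            coding_counts[v.type] += 1
            if nonsyn:
                nonsyn_counts[v.type] += 1
    return out, {"coding": coding_counts, "nonsynonymous": nonsyn_counts}


def counts_table(
    counts: Counter, coding: Counter | None = None, nonsyn: Counter | None = None
) -> pd.DataFrame:
    """Per-type event counts shaped like a variant-summary table."""
    rows = []
    for t in ("SNP", "indel", "MNP", "CV"):
        rows.append(
            (
                t,
                counts.get(t, 0),
                (coding or Counter()).get(t, 0),
                (nonsyn or Counter()).get(t, 0),
            )
        )
    return pd.DataFrame(rows, columns=["type", "number", "coding_region", "non_synonymous"])


def read_cds_bed(path: str | Path) -> list[CdsInterval]:
    """CDS intervals from BED (chrom start end name score strand)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "+"
            name = f[3] if len(f) > 3 else ""
            out.append(CdsInterval(int(f[1]), int(f[2]), strand, name))
    return out


def read_cds_gff3(path: str | Path) -> list[CdsInterval]:
    """CDS features from GFF3 (1-based inclusive coordinates converted)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] != "CDS":
                continue
            attrs = f[8] if len(f) > 8 else ""
            name = ""
            for kv in attrs.split(";"):
                if kv.startswith(("ID=", "Name=")):
                    name = kv.split("=", 1)[1]
                    break
            out.append(CdsInterval(int(f[3]) - 1, int(f[4]), f[6], name))
    return out


def write_vcf(
    variants: Iterable[VariantRecord],
    reference: str,
    path: str | Path,
    chrom: str = "genome",
) -> None:
    """Minimal single-sample-free VCF (1-based; indels padded with the previous base)."""
    reference = reference.upper()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(reference)}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Event type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if v.type == "indel" or (v.type == "CV" and (not v.ref_allele or not v.alt_allele)):
                if v.ref_pos > 0:
                    pad = reference[v.ref_pos - 1]
                    pos = v.ref_pos  # 1-based position of the pad base
                    ref_a = pad + v.ref_allele
                    alt_a = pad + v.alt_allele
                else:
                    pos = 1
                    ref_a = v.ref_allele or "."
                    alt_a = v.alt_allele or "."
            else:
                pos = v.ref_pos + 1
                ref_a = v.ref_allele
                alt_a = v.alt_allele
            fh.write(f"{chrom}\t{pos}\t.\t{ref_a}\t{alt_a}\t.\tPASS\tTYPE={v.type}\n")
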