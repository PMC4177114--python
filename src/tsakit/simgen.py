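"""Synthetic mixed-organelle libraries with known truth.

Generates a nuclear / plastid / mitochondrial genome triple and copy-fold
weighted paired-end reads, so every downstream stage of the pipeline can be
audited against ground truth without any external data.

The plastid genome carries the canonical quadripartite layout
LSC + IRa + SSC + IRb, with IRb the reverse complement of IRa.  The
mitochondrial genome contains one tract copied verbatim from the plastid
single-copy region — the homology trap: exact-match plastid read removal
deletes the tract's read coverage and opens the gap that iterative anchored
closure must repair.  Copy folds weight how many read pairs each compartment
contributes, emulating a mixed-organelle DNA sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import revcomp
from .readqc import ReadPair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimParameterError(ValueError):
    """Raised for inconsistent simulation parameters."""


def random_sequence(n: int, rng: np.random.Generator) -> str:
    """i.i.d. uniform ACGT sequence of length n."""
    if n <= 0:
        raise SimParameterError("sequence length must be positive")
    return bytes(_BASES[rng.integers(0, 4, n, dtype=np.uint8)]).decode()


@dataclass
class GenomeTriple:
    """Nuclear (linear), plastid (circular, quadripartite) and mito (circular) genomes.

    truth_layout holds every named segment with 0-based half-open coordinates,
    including the plastid-homologous tract planted in the mitochondrion and its
    source interval on the plastid.
    """

    nuclear: str
    plastid: str
    mito: str
    truth_layout: pd.DataFrame

    def segment(self, genome: str, name: str) -> tuple[int, int]:
        row = self.truth_layout.query("genome == @genome and segment == @name")
        if row.empty:
            raise KeyError(f"no segment {name!r} on {genome}")
        r = row.iloc[0]
        return int(r.start), int(r.end)

    @property
    def lengths(self) -> dict[str, int]:
        return {"plastid": len(self.plastid), "mito": len(self.mito), "nuclear": len(self.nuclear)}


@dataclass
class ReadSimParams:
    """Sequencing-library emulation parameters.

    Defaults mirror a 100 nt paired-end library with ~500 bp inserts; copy
    folds are (plastid, mito, nuclear) genome copies per nuclear copy.
    """

    read_length: int = 100
    insert_mean: int = 500
    insert_sd: float = 50.0
    copy_folds: tuple[float, float, float] = (100.0, 10.0, 1.0)
    total_pairs: int = 10000
    error_rate: float = 0.0
    seed: int = 0
    adaptor: str | None = None
    adaptor_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise SimParameterError("read_length must not exceed insert_mean")
        if any(f <= 0 for f in self.copy_folds):
            raise SimParameterError("copy folds must be positive")
        if not (0 <= self.error_rate < 1):
            raise SimParameterError("error_rate must lie in [0, 1)")


def make_genomes(
    lsc: int = 8000,
    ssc: int = 2000,
    ir: int = 2500,
    mito: int = 20000,
    nuclear: int = 50000,
    homology_tract: int = 1000,
    seed: int = 0,
) -> GenomeTriple:
    """Build a deterministic genome triple with the quadripartite plastid layout.

    ``homology_tract`` bases are copied from the middle of the plastid LSC into
    the middle of the mitochondrion (0 disables the trap).  The tract must fit
    inside a single-copy region and inside the mitochondrion.
    """
    for name, v in (("lsc", lsc), ("ssc", ssc), ("ir", ir), ("mito", mito), ("nuclear", nuclear)):
        if v <= 0:
            raise SimParameterError(f"{name} size must be positive")
    if homology_tract < 0:
        raise SimParameterError("homology_tract must be >= 0")
    if homology_tract > max(lsc, ssc):
        raise SimParameterError("homology tract longer than any plastid single-copy region")
    if homology_tract >= mito:
        raise SimParameterError("homology tract must be shorter than the mitochondrion")
    rng = np.random.default_rng(seed)
    lsc_seq = random_sequence(lsc, rng)
    ira_seq = random_sequence(ir, rng)
    ssc_seq = random_sequence(ssc, rng)
    plastid = lsc_seq + ira_seq + ssc_seq + revcomp(ira_seq)
    mito_seq = random_sequence(mito, rng)
    nuclear_seq = random_sequence(nuclear, rng)

    rows = [
        ("plastid", "LSC", 0, lsc),
        ("plastid", "IRa", lsc, lsc + ir),
        ("plastid", "SSC", lsc + ir, lsc + ir + ssc),
        ("plastid", "IRb", lsc + ir + ssc, lsc + 2 * ir + ssc),
        ("nuclear", "nuclear", 0, nuclear),
    ]
    if homology_tract > 0:
        src = (lsc - homology_tract) // 2  # middle of the LSC
        dst = (mito - homology_tract) // 2
        tract = plastid[src : src + homology_tract]
        mito_seq = mito_seq[:dst] + tract + mito_seq[dst + homology_tract :]
        rows.append(("plastid", "tract_source", src, src + homology_tract))
        rows.append(("mito", "tract", dst, dst + homology_tract))
    rows.append(("mito", "mito", 0, mito))
    layout = pd.DataFrame(rows, columns=["genome", "segment", "start", "end"])
    return GenomeTriple(nuclear=nuclear_seq, plastid=plastid, mito=mito_seq, truth_layout=layout)


def compartment_weights(g: GenomeTriple, copy_folds: tuple[float, float, float]) -> dict[str, float]:
    """Sampling weights: copy fold x genome length per compartment."""
    pf, mf, nf = copy_folds
    return {"plastid": pf * len(g.plastid), "mito": mf * len(g.mito), "nuclear": nf * len(g.nuclear)}


def expected_depths(g: GenomeTriple, p: ReadSimParams) -> dict[str, float]:
    """Expected per-compartment sequencing depth (layers) for the parameter set."""
    w = compartment_weights(g, p.copy_folds)
    tot = sum(w.values())
    bases = p.total_pairs * 2 * p.read_length
    return {c: bases * wi / tot / len(getattr(g, c)) for c, wi in w.items()}


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = bytearray(seq, "ascii")
    for i in pos:
        alts = [b for b in b"ACGT" if b != s[i]]
        s[i] = alts[rng.integers(0, 3)]
    return s.decode()


def sample_read_pairs(g: GenomeTriple, p: ReadSimParams) -> tuple[list[ReadPair], pd.DataFrame]:
    """Sample copy-fold-weighted paired-end reads with a sidecar truth table.

    Pairs per compartment follow a multinomial over copy_fold x length weights.
    Circular genomes (plastid, mito) are sampled across the origin; the nuclear
    genome is linear.  Mates have inner (FR) orientation; fragment strand is
    chosen uniformly.  Qualities are fixed at Q40; substitution errors are
    applied at ``error_rate`` per base.  Truth labels (compartment, fragment
    start on the forward strand, mate strands) go only to the sidecar table.
    """
    rng = np.random.default_rng(p.seed)
    seqs = {"plastid": g.plastid, "mito": g.mito, "nuclear": g.nuclear}
    circular = {"plastid": True, "mito": True, "nuclear": False}
    w = compartment_weights(g, p.copy_folds)
    comps = list(w)
    probs = np.array([w[c] for c in comps], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(p.total_pairs, probs)

    rl = p.read_length
    qual = chr(33 + 40) * rl
    pairs: list[ReadPair] = []
    truth_rows = []
    idx = 0
    for comp, n in zip(comps, counts):
        seq = seqs[comp]
        L = len(seq)
        if not circular[comp] and p.insert_mean > L:
            raise SimParameterError(f"insert_mean exceeds linear genome {comp} length")
        ext = seq + seq if circular[comp] else seq
        for _ in range(int(n)):
            lo, hi = 2 * rl, min(L, p.insert_mean + 4 * p.insert_sd)
            ins = int(round(rng.normal(p.insert_mean, p.insert_sd)))
            ins = max(lo, min(int(hi), ins))
            start = int(rng.integers(0, L if circular[comp] else L - ins + 1))
            frag = ext[start : start + ins]
            fwd = frag[:rl]
            rev = revcomp(frag[-rl:])
            flip = bool(rng.integers(0, 2))  # which mate is the forward read
            s1, s2 = (rev, fwd) if flip else (fwd, rev)
            if p.error_rate > 0:
                s1 = _apply_errors(s1, rng, p.error_rate)
                s2 = _apply_errors(s2, rng, p.error_rate)
            contaminated = False
            if p.adaptor and p.adaptor_frac > 0 and rng.random() < p.adaptor_frac:
                a = p.adaptor.upper()
                s1 = s1[: rl - len(a)] + a  # read-through into the adaptor at the 3' end
                contaminated = True
            rid = f"{comp[:2]}_{idx}"
            pairs.append(ReadPair(rid, s1, qual, s2, qual))
            truth_rows.append(
                (
                    rid,
                    comp,
                    start,
                    ins,
                    "-" if flip else "+",
                    (start + ins - rl) % L if circular[comp] else start + ins - rl,
                    contaminated,
                )
            )
            idx += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "compartment", "frag_start", "insert", "mate1_strand", "mate2_start", "adaptor"],
    )
    return pairs, truth


def plant_mutations(
    seq: str,
    n_snps: int,
    n_indels: int,
    seed: int = 0,
    max_indel: int = 5,
    min_spacing: int = 150,
) -> tuple[str, pd.DataFrame]:
    """Plant well-spaced SNPs and short indels; returns (mutant, truth ledger).

    Events are placed at least ``min_spacing`` apart (and away from the ends)
    so each one is recoverable as a distinct variant.  The ledger gives the
    reference coordinate, type and both alleles of every planted event.
    """
    rng = np.random.default_rng(seed)
    n_events = n_snps + n_indels
    margin = min_spacing
    usable = len(seq) - 2 * margin
    if usable < n_events * min_spacing:
        raise SimParameterError("sequence too short for the requested events at this spacing")
    # one position per evenly sized bin, keeping spacing deterministic
    bin_w = usable // n_events
    positions = sorted(
        margin + i * bin_w + int(rng.integers(0, max(1, bin_w - min_spacing)))
        for i in range(n_events)
    )
    kinds = ["SNP"] * n_snps + ["indel"] * n_indels
    rng.shuffle(kinds)
    out = []
    ledger = []
    prev = 0
    offset_rows = []
    for pos, kind in zip(positions, kinds):
        out.append(seq[prev:pos])
        if kind == "SNP":
            ref = seq[pos]
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            out.append(alt)
            ledger.append((pos, "SNP", ref, alt))
            prev = pos + 1
        else:
            size = int(rng.integers(1, max_indel + 1))
            if rng.integers(0, 2):  # deletion from the reference
                ledger.append((pos, "indel", seq[pos : pos + size], ""))
                prev = pos + size
            else:  # insertion into the query
                ins = random_sequence(size, rng)
                out.append(ins)
                ledger.append((pos, "indel", "", ins))
                prev = pos
    out.append(seq[prev:])
    mutant = "".join(out)
    df = pd.DataFrame(ledger, columns=["ref_pos", "type", "ref_allele", "alt_allele"])
    return mutant, df


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
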