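"""End-to-end two-step assembly: plastid first, then mitochondrion.

Step A isolates and assembles the deep plastid stratum: QC-cleaned reads are
assembled with a high kmer-frequency threshold (everything below the plastid
depth stratum drops out of the graph), the resulting scaffolds are placed on
the reference plastid genome, joined into an N-gapped draft, and the gaps are
closed iteratively from the reads.

Step B removes every pair with at least one end mapping exactly to the
finished plastid, assembles the remainder at the standard thresholds, places
the scaffolds on the reference mitochondrial genome, and closes gaps with the
strict anchored iteration — using the full clean-read pool for fill material,
since the plastid-homologous tract's own reads were removed with the plastid
pairs and are recoverable only by exact anchoring to the mitochondrial draft.

The run report records the per-stage counts a user needs to summarise a run:
reads kept by QC, scaffolds total/aligned, gaps total/filled, final lengths
and unique-region depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import assembler, draftbuild, exactmap, gapclose, readqc, simgen
from .assembler import AssemblyParams
from .gapclose import GapCloseParams


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one TSA run needs; YAML-serialisable."""

    reads_r1: str | None = None
    reads_r2: str | None = None
    plastid_ref: str | None = None
    mito_ref: str | None = None
    outdir: str | None = None
    adaptor: str | None = None
    step1: AssemblyParams = field(default_factory=lambda: AssemblyParams(min_kmer_freq=150, min_edge_cov=150))
    step2: AssemblyParams = field(default_factory=AssemblyParams)
    gapclose: GapCloseParams = field(default_factory=GapCloseParams)
    min_scaffold_coverage: float = 0.5
    anchor_k: int = 31
    seed_k: int = 31
    shared_min_run: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (("step1", AssemblyParams), ("step2", AssemblyParams), ("gapclose", GapCloseParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class TsaResult:
    plastid: str
    mito: str
    report: dict[str, Any]


def _assemble_step(pairs, params: AssemblyParams, stage: str) -> assembler.ContigSet:
    if not pairs:
        raise PipelineError("assemble", f"{stage}: empty read set")
    contigs = assembler.assemble_contigs(pairs, params)
    if not len(contigs):
        raise PipelineError("assemble", f"{stage}: no contigs survive the thresholds")
    return contigs


def _place_and_draft(
    contigs: assembler.ContigSet,
    reference: str,
    cfg: PipelineConfig,
    stage: str,
) -> tuple[draftbuild.DraftGenome, int, int]:
    unique_pos = draftbuild.unique_kmer_positions(reference, cfg.anchor_k)
    scaffolds = {f"scaffold_{i}": c.sequence for i, c in enumerate(contigs)}
    circular_ids = {f"scaffold_{i}" for i, c in enumerate(contigs) if c.circular}
    alignments = []
    for sid, seq in scaffolds.items():
        a = draftbuild.align_scaffold(
            seq,
            reference,
            anchor_k=cfg.anchor_k,
            min_coverage=cfg.min_scaffold_coverage,
            circular=True,
            scaffold_id=sid,
            unique_pos=unique_pos,
        )
        if a is not None:
            a.circular_scaffold = sid in circular_ids
            alignments.append(a)
    if not alignments:
        raise PipelineError("draft", f"{stage}: no scaffold aligned to the reference")
    draft = draftbuild.build_draft(
        alignments, scaffolds, reference, circular=True
    )
    return draft, len(scaffolds), len(alignments)


def run_tsa(
    pairs: list[readqc.ReadPair] | None = None,
    plastid_ref: str | None = None,
    mito_ref: str | None = None,
    config: PipelineConfig | None = None,
) -> TsaResult:
    """Run the full two-step pipeline; inputs in memory or via ``config`` paths.

    Deterministic for a fixed config and read set.  Returns the two finished
    genomes and a per-stage run report.  Stage errors raise
    :class:`PipelineError` naming the stage.
    """
    cfg = config or PipelineConfig()
    if pairs is None:
        if not (cfg.reads_r1 and cfg.reads_r2):
            raise PipelineError("input", "no reads given (in memory or via config paths)")
        pairs = list(readqc.read_fastq_pairs(cfg.reads_r1, cfg.reads_r2))
    if plastid_ref is None:
        if not cfg.plastid_ref:
            raise PipelineError("input", "no plastid reference")
        plastid_ref = _read_single_fasta(cfg.plastid_ref)
    if mito_ref is None:
        if not cfg.mito_ref:
            raise PipelineError("input", "no mitochondrial reference")
        mito_ref = _read_single_fasta(cfg.mito_ref)

    report: dict[str, Any] = {"config": cfg.to_dict(), "input_pairs": len(pairs)}

    clean, discards = readqc.qc_filter_pairs(pairs, adaptor=cfg.adaptor)
    report["qc"] = {"kept": len(clean), "discarded": dict(discards)}
    read_len = len(clean[0].seq1) if clean else 100

    # --- step A: plastid ---
    contigs1 = _assemble_step(clean, cfg.step1, "plastid")
    draft_pt, n_scaf1, n_aln1 = _place_and_draft(contigs1, plastid_ref, cfg, "plastid")
    gaps_before_pt = len(draft_pt.gaps())
    final_pt, reports_pt = gapclose.close_gaps_iterative(draft_pt, clean, cfg.gapclose)
    plastid_seq = final_pt.sequence
    report["plastid"] = {
        "scaffolds_total": n_scaf1,
        "scaffolds_aligned": n_aln1,
        "gaps_total": gaps_before_pt,
        "gaps_filled": gaps_before_pt - len(final_pt.gaps()),
        "residual_gaps": [(g.start, g.end) for g in final_pt.gaps()],
        "length": len(plastid_seq),
        "iterations": [
            {"iteration": r.iteration, "pairs_mapped": r.pairs_mapped, "bases_extended": r.bases_extended}
            for r in reports_pt
        ],
    }
    if final_pt.gaps():
        plastid_clean = plastid_seq  # residual Ns retained for finishing
    else:
        plastid_clean = plastid_seq

    # --- step B: mitochondrion ---
    pt_index = exactmap.build_index(
        {"plastid": plastid_clean}, seed_k=cfg.seed_k,
        circular={"plastid"} if final_pt.circular else set(), wrap=read_len - 1,
    )
    removed, survivors = exactmap.partition_pairs(clean, pt_index, max_mismatch=0)
    report["plastid_read_removal"] = {
        "pairs_removed": len(removed),
        "pairs_kept": len(survivors),
        "kept_fraction": round(len(survivors) / len(clean), 4),
    }
    contigs2 = _assemble_step(survivors, cfg.step2, "mitochondrial")
    draft_mt, n_scaf2, n_aln2 = _place_and_draft(contigs2, mito_ref, cfg, "mitochondrial")
    gaps_before_mt = len(draft_mt.gaps())
    # fill material must come from the full clean pool: the homologous tract's
    # reads were removed with the plastid pairs
    final_mt, reports_mt = gapclose.close_gaps_iterative(draft_mt, clean, cfg.gapclose)
    mito_seq = final_mt.sequence
    report["mitochondrial"] = {
        "scaffolds_total": n_scaf2,
        "scaffolds_aligned": n_aln2,
        "gaps_total": gaps_before_mt,
        "gaps_filled": gaps_before_mt - len(final_mt.gaps()),
        "residual_gaps": [(g.start, g.end) for g in final_mt.gaps()],
        "length": len(mito_seq),
        "iterations": [
            {"iteration": r.iteration, "pairs_mapped": r.pairs_mapped, "bases_extended": r.bases_extended}
            for r in reports_mt
        ],
    }

    # --- depth statistics on unique regions ---
    try:
        report["depth"] = _depth_section(clean, plastid_clean, mito_seq, cfg, read_len)
    except Exception as e:  # depth reporting must not void the assemblies
        report["depth"] = {"error": str(e)}

    # conservation: step-B input = QC output - removed plastid pairs
    report["conservation"] = {
        "qc_kept": len(clean),
        "removed_plus_survivors": len(removed) + len(survivors),
    }

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        simgen.write_fasta({"plastid": plastid_clean}, out / "plastid.fasta")
        simgen.write_fasta({"mitochondrial": mito_seq}, out / "mitochondrial.fasta")
        with open(out / "report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
    return TsaResult(plastid_clean, mito_seq, report)


def _depth_section(clean, plastid_seq, mito_seq, cfg, read_len) -> dict[str, Any]:
    mask_pt, mask_mt = exactmap.shared_region_mask(plastid_seq, mito_seq, cfg.shared_min_run)
    regions = [
        exactmap.Region("plastid_unique", "plastid", exactmap.unique_regions(len(plastid_seq), mask_pt)),
        exactmap.Region("mito_unique", "mito", exactmap.unique_regions(len(mito_seq), mask_mt)),
    ]
    index = exactmap.build_index(
        {"plastid": plastid_seq, "mito": mito_seq},
        seed_k=cfg.seed_k,
        circular={"plastid", "mito"},
        wrap=read_len - 1,
    )
    placements = []
    for p in clean:
        placements.extend(exactmap.map_read(p.seq1, index, 0, read_id=p.id, mate=1))
        placements.extend(exactmap.map_read(p.seq2, index, 0, read_id=p.id, mate=2))
    rep = exactmap.depth_stats(placements, regions, read_len)
    return {
        r.name: {"length": r.region_length, "mapped_reads": r.mapped_reads, "depth": r.depth}
        for r in rep.rows
    }


def _read_single_fasta(path: str | Path) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PipelineError("input", f"no sequences in {path}")
    return str(records[0].seq).upper()
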