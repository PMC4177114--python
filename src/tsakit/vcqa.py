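"""Vector-control quantitative analysis (VCQA) of DNA-sample purity.

A single control vector carries one marker amplicon per genome compartment
(plastid *rpoB*, mitochondrial *ccmB*, nuclear *beta-actin*).  qPCR on the
vector (control) and on the DNA sample gives, per gene, an efficiency-corrected
relative quantity

    Q = (1 + E) ** (CT_control - CT_sample)

where E is the amplification efficiency (E = 1 means perfect doubling).
Ratios of organelle to nuclear relative quantities are the copy folds
ptDNA/ncDNA and mtDNA/ncDNA: the number of organelle genome copies per nuclear
genome copy, which equals the expected organelle sequencing depth when the
nuclear genome is covered one layer.  That identity turns the qPCR result into
a dataset-size calculator for organelle de novo assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

Role = Literal["plastid", "mitochondrial", "nuclear"]

_ROLES = ("plastid", "mitochondrial", "nuclear")


class InvalidMeasurementError(ValueError):
    """Raised for a qPCR measurement violating its invariants."""


def _round_half_away(x: float, digits: int) -> float:
    """Round half away from zero (the convention of printed qPCR tables)."""
    q = Decimal(1).scaleb(-digits) if digits > 0 else Decimal(1)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class QpcrMeasurement:
    """One gene's amplification efficiency and paired CT values.

    ct_control is the cycle threshold on the control vector, ct_sample on the
    DNA sample.  efficiency is E in (0, 1.5], the per-cycle gain.
    """

    gene_id: str
    role: Role
    efficiency: float
    ct_control: float
    ct_sample: float

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise InvalidMeasurementError(f"unknown role {self.role!r}")
        if not (0 < self.efficiency <= 1.5):
            raise InvalidMeasurementError(
                f"{self.gene_id}: efficiency {self.efficiency} outside (0, 1.5]"
            )
        if self.ct_control <= 0 or self.ct_sample <= 0:
            raise InvalidMeasurementError(f"{self.gene_id}: CT values must be positive")

    @property
    def delta_ct(self) -> float:
        """CT(control) - CT(sample)."""
        return self.ct_control - self.ct_sample


@dataclass
class PurityReport:
    """Relative quantities plus the two organelle/nuclear copy folds."""

    rel_quantity: dict[str, float]
    copy_fold_pt: int | None
    copy_fold_mt: int | None
    required_bases_pt: float | None = None
    required_bases_mt: float | None = None
    nuclear_genome_size: float | None = None
    target_depth: float | None = None
    sufficient: bool | None = None

    def to_tsv(self) -> str:
        lines = ["gene\trelative_quantity"]
        lines += [f"{g}\t{q}" for g, q in self.rel_quantity.items()]
        if self.copy_fold_mt is not None:
            lines.append(f"copy_fold_mt\t{self.copy_fold_mt}")
        if self.copy_fold_pt is not None:
            lines.append(f"copy_fold_pt\t{self.copy_fold_pt}")
        if self.required_bases_mt is not None:
            lines.append(f"required_bases_mt\t{self.required_bases_mt:.4g}")
        if self.required_bases_pt is not None:
            lines.append(f"required_bases_pt\t{self.required_bases_pt:.4g}")
        if self.sufficient is not None:
            lines.append(f"dataset_sufficient\t{self.sufficient}")
        return "\n".join(lines) + "\n"


def relative_quantity(m: QpcrMeasurement, round_digits: int = 4, *, exact: bool = False) -> float:
    """Efficiency-corrected relative quantity (1+E)**(CT_control - CT_sample).

    Rounded half-away-from-zero to ``round_digits`` decimals (4 matches the
    printing convention of qPCR tables) unless ``exact`` is set.
    """
    if m.efficiency <= 0:
        raise InvalidMeasurementError(f"{m.gene_id}: non-positive efficiency")
    q = (1.0 + m.efficiency) ** m.delta_ct
    return q if exact else _round_half_away(q, round_digits)


def copy_fold(
    organelle: QpcrMeasurement, nuclear: QpcrMeasurement, *, exact: bool = False
) -> int | float:
    """Organelle/nuclear copy fold from two qPCR measurements.

    The ratio is taken over 4-decimal-rounded relative quantities and rounded
    half-away-from-zero to an integer, the convention under which the printed
    table values are recovered.  ``exact=True`` returns the un-rounded ratio of
    un-rounded quantities, for scientific use.
    """
    if nuclear.role != "nuclear":
        raise InvalidMeasurementError("denominator measurement must have role 'nuclear'")
    if organelle.role == "nuclear":
        raise InvalidMeasurementError("numerator measurement must be an organelle gene")
    if exact:
        return relative_quantity(organelle, exact=True) / relative_quantity(nuclear, exact=True)
    qn = relative_quantity(nuclear, 4)
    if qn == 0:
        raise ZeroDivisionError("nuclear relative quantity rounds to zero")
    ratio = relative_quantity(organelle, 4) / qn
    return int(math.floor(ratio + 0.5))  # half away from zero; ratio is positive


def required_bases(nuclear_genome_size: float, fold: float, target_depth: float) -> float:
    """Dataset size (bases) at which the organelle reaches ``target_depth`` layers.

    With an organelle present at ``fold`` copies per nuclear copy, a dataset of
    G*D/fold bases covers the nuclear genome D/fold layers and the organelle D
    layers.
    """
    if nuclear_genome_size <= 0 or fold <= 0 or target_depth <= 0:
        raise ValueError("all arguments must be positive")
    return nuclear_genome_size * target_depth / fold


def read_qpcr_csv(path: str | Path) -> list[QpcrMeasurement]:
    """Read a qPCR table: header ``gene,role,efficiency,ct_control,ct_sample``."""
    df = pd.read_csv(path)
    expected = ["gene", "role", "efficiency", "ct_control", "ct_sample"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR CSV missing columns: {missing}")
    return [
        QpcrMeasurement(
            gene_id=str(r.gene),
            role=str(r.role),
            efficiency=float(r.efficiency),
            ct_control=float(r.ct_control),
            ct_sample=float(r.ct_sample),
        )
        for r in df.itertuples()
    ]


def purity_report(
    measurements: Iterable[QpcrMeasurement],
    nuclear_genome_size: float | None = None,
    target_depth: float = 50.0,
    dataset_bases: float | None = None,
) -> PurityReport:
    """Assemble the copy-fold report (and dataset sufficiency, if sizes given).

    Expects exactly one nuclear measurement; plastid/mitochondrial ones are
    optional.  ``dataset_bases`` (e.g. a planned 1.2e9) is compared against the
    per-organelle required sizes at ``target_depth`` layers.
    """
    ms = list(measurements)
    nuc = [m for m in ms if m.role == "nuclear"]
    if len(nuc) != 1:
        raise InvalidMeasurementError("expected exactly one nuclear measurement")
    nuclear = nuc[0]
    rel = {m.gene_id: relative_quantity(m) for m in ms}
    folds: dict[str, int] = {}
    for role in ("plastid", "mitochondrial"):
        cand = [m for m in ms if m.role == role]
        if cand:
            folds[role] = copy_fold(cand[0], nuclear)
    rep = PurityReport(
        rel_quantity=rel,
        copy_fold_pt=folds.get("plastid"),
        copy_fold_mt=folds.get("mitochondrial"),
        nuclear_genome_size=nuclear_genome_size,
        target_depth=target_depth,
    )
    if nuclear_genome_size is not None:
        if rep.copy_fold_pt:
            rep.required_bases_pt = required_bases(nuclear_genome_size, rep.copy_fold_pt, target_depth)
        if rep.copy_fold_mt:
            rep.required_bases_mt = required_bases(nuclear_genome_size, rep.copy_fold_mt, target_depth)
        if dataset_bases is not None:
            needs = [b for b in (rep.required_bases_pt, rep.required_bases_mt) if b is not None]
            rep.sufficient = bool(needs) and dataset_bases >= max(needs)
    return rep
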