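"""Family-based genotype QC: call-rate trimming and heterozygote-undercall
correction.

GBS genotypes of low-coverage offspring suffer allele dropout: a true
heterozygote is read as one of its homozygotes.  Because the parents were
sequenced at roughly ten times the offspring coverage, an offspring genotype
that cannot be formed from one allele of each parent is most likely such an
undercall.  The correction rule applied here: at each locus, offspring calls
that are Mendelian-implausible given the two parents are counted; if the
implausible fraction is below a threshold (default 10%) those calls are set
to missing and the locus is kept, otherwise the locus is discarded.
A call-rate filter (default: genotyped in >= 90% of individuals) runs first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

from .io_formats import MISSING, FamilyDataset, Genotype, LocusRecord


class Plausibility(Enum):
    PLAUSIBLE = "plausible"
    IMPLAUSIBLE = "implausible"
    UNKNOWN = "unknown"  # missing offspring call, or a missing parent


@dataclass
class QCConfig:
    """Thresholds for the two QC rules.

    max_implausible_frac: loci with an implausible-call fraction at or above
        this are discarded; strictly below, the implausible cells are set to
        missing (the keep side of the boundary is strict-less).
    min_call_rate: minimum non-missing fraction for a locus to survive
        call-rate trimming.
    call_rate_includes_parents: whether the call-rate denominator counts the
        two parents as well as the offspring.
    """

    max_implausible_frac: float = 0.10
    min_call_rate: float = 0.90
    call_rate_includes_parents: bool = True

    def __post_init__(self) -> None:
        for name in ("max_implausible_frac", "min_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class LocusQC:
    locus_id: str
    n_offspring_called: int
    n_implausible: int
    action: str  # kept | corrected | discarded_implausible | discarded_call_rate
    unassessable: bool = False  # a parent genotype was missing
    corrected_cells: list = field(default_factory=list)  # individual ids


@dataclass
class QCReport:
    records: list = field(default_factory=list)  # list[LocusQC]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": r.locus_id,
                "n_offspring_called": r.n_offspring_called,
                "n_implausible": r.n_implausible,
                "action": r.action,
                "unassessable": r.unassessable,
                "corrected_cells": ",".join(r.corrected_cells),
            }
            for r in self.records
        )

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def count(self, action: str) -> int:
        return sum(1 for r in self.records if r.action == action)


def mendel_check(locus: LocusRecord, mother_gt: Genotype, father_gt: Genotype,
                 offspring_indices: list) -> list:
    """Flag each offspring call as plausible, implausible, or unknown.

    A genotype is plausible iff it can be formed by taking one allele from
    each parent.  Missing offspring calls — and every call when either
    parent is missing — are UNKNOWN.
    """
    if mother_gt is None or father_gt is None:
        return [Plausibility.UNKNOWN] * len(offspring_indices)
    flags = []
    for idx in offspring_indices:
        gt = locus.genotypes[idx]
        if gt is None:
            flags.append(Plausibility.UNKNOWN)
            continue
        a, b = gt
        ok = (a in mother_gt and b in father_gt) or (b in mother_gt and a in father_gt)
        flags.append(Plausibility.PLAUSIBLE if ok else Plausibility.IMPLAUSIBLE)
    return flags


def undercall_correct(dataset: FamilyDataset, config: Optional[QCConfig] = None
                      ) -> tuple:
    """Apply the implausible-genotype correction locus by locus.

    Per locus, with both parents called, let f = implausible / called
    offspring.  f < max_implausible_frac: implausible cells are set to
    missing and the locus is kept (action ``corrected``, or ``kept`` if
    nothing was implausible).  f >= max_implausible_frac: the locus is
    discarded.  Loci with a missing parent pass through unmodified, flagged
    unassessable.
    """
    config = config or QCConfig()
    mi, fi = dataset.mother_index, dataset.father_index
    off = dataset.offspring_indices
    kept_loci, records = [], []
    for locus in dataset.loci:
        mother_gt, father_gt = locus.genotypes[mi], locus.genotypes[fi]
        if mother_gt is None or father_gt is None:
            kept_loci.append(locus)
            records.append(LocusQC(locus.locus_id, 0, 0, "kept", unassessable=True))
            continue
        flags = mendel_check(locus, mother_gt, father_gt, off)
        n_called = sum(1 for f in flags if f is not Plausibility.UNKNOWN)
        n_implausible = sum(1 for f in flags if f is Plausibility.IMPLAUSIBLE)
        frac = n_implausible / n_called if n_called else 0.0
        if n_called and frac >= config.max_implausible_frac:
            records.append(
                LocusQC(locus.locus_id, n_called, n_implausible, "discarded_implausible")
            )
            continue
        if n_implausible:
            new_gts = list(locus.genotypes)
            cells = []
            for idx, flag in zip(off, flags):
                if flag is Plausibility.IMPLAUSIBLE:
                    new_gts[idx] = MISSING
                    cells.append(dataset.individuals[idx].id)
            kept_loci.append(LocusRecord(locus.locus_id, locus.alleles, new_gts))
            records.append(
                LocusQC(locus.locus_id, n_called, n_implausible, "corrected",
                        corrected_cells=cells)
            )
        else:
            kept_loci.append(locus)
            records.append(LocusQC(locus.locus_id, n_called, 0, "kept"))
    return dataset.with_loci(kept_loci), QCReport(records)


def call_rate_filter(dataset: FamilyDataset, config: Optional[QCConfig] = None
                     ) -> tuple:
    """Keep loci genotyped in at least ``min_call_rate`` of individuals.

    The denominator is all individuals (parents included) by default, or
    offspring only when ``call_rate_includes_parents`` is False.  Locus
    order is preserved.
    """
    config = config or QCConfig()
    if config.call_rate_includes_parents:
        indices = list(range(len(dataset.individuals)))
    else:
        indices = dataset.offspring_indices
    denom = len(indices)
    kept_loci, records = [], []
    for locus in dataset.loci:
        n_called = sum(1 for i in indices if locus.genotypes[i] is not None)
        if denom == 0 or n_called / denom >= config.min_call_rate:
            kept_loci.append(locus)
            records.append(LocusQC(locus.locus_id, n_called, 0, "kept"))
        else:
            records.append(LocusQC(locus.locus_id, n_called, 0, "discarded_call_rate"))
    return dataset.with_loci(kept_loci), QCReport(records)


def run_qc(dataset: FamilyDataset, config: Optional[QCConfig] = None) -> tuple:
    """Call-rate trimming followed by undercall correction (pipeline order)."""
    config = config or QCConfig()
    trimmed, rate_report = call_rate_filter(dataset, config)
    corrected, correction_report = undercall_correct(trimmed, config)
    merged = QCReport(
        [r for r in rate_report.records if r.action == "discarded_call_rate"]
        + correction_report.records
    )
    return corrected, merged
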