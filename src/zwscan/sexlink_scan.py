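"""Scan for completely sex-biased loci and classify heterogamety.

A locus is completely sex-biased when, among offspring with non-missing
calls, every individual of one sex is heterozygous and every individual of
the other sex is homozygous.  The parents then disambiguate the chromosome:

* mother heterozygous, father homozygous, daughters heterozygous -> the SNP
  rides the maternal W (``W_pattern``: ZZ/ZW system, variant on W);
* mother heterozygous, father homozygous, sons heterozygous -> a variant on
  one maternal Z not carried by either paternal Z (``Z_pattern``);
* the paternal mirrors give ``Y_pattern`` (sons heterozygous) and
  ``X_pattern`` (daughters heterozygous) under XX/XY.

Calls that violate Mendelian consistency (e.g. both parents heterozygous,
or offspring genotypes not derivable from the parents) are reported as
``inconsistent`` rather than silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .io_formats import FamilyDataset, Genotype, genotype

W_PATTERN = "W_pattern"
Z_PATTERN = "Z_pattern"
X_PATTERN = "X_pattern"
Y_PATTERN = "Y_pattern"
INCONSISTENT = "inconsistent"
UNASSESSABLE = "UNASSESSABLE"


@dataclass
class ScanConfig:
    """min_informative_per_sex bounds chance hits: a locus is only a
    candidate when at least this many offspring of each sex carry calls.
    With require_all_offspring, any missing offspring call disqualifies the
    locus (the strict reading of "completely")."""

    min_informative_per_sex: int = 5
    require_all_offspring: bool = False

    def __post_init__(self) -> None:
        if self.min_informative_per_sex < 1:
            raise ValueError("min_informative_per_sex must be >= 1")


@dataclass
class SexBiasCandidate:
    locus_id: str
    heterozygous_sex: str  # F | M
    het_daughters: int
    hom_daughters: int
    het_sons: int
    hom_sons: int
    missing_f: int
    missing_m: int
    locus_index: int


@dataclass
class SexLinkageCall:
    locus_id: str
    heterozygous_sex: str
    pattern: str  # W_pattern | Z_pattern | X_pattern | Y_pattern | inconsistent | UNASSESSABLE
    mother_gt: Genotype
    father_gt: Genotype
    het_daughters: int = 0
    hom_daughters: int = 0
    het_sons: int = 0
    hom_sons: int = 0
    missing_f: int = 0
    missing_m: int = 0


@dataclass
class ScanResult:
    candidates: list  # list[SexBiasCandidate]
    n_loci_scanned: int = 0
    n_skipped_low_information: int = 0


def _is_het(gt: tuple) -> bool:
    return gt[0] != gt[1]


def scan_sex_biased(dataset: FamilyDataset, config: Optional[ScanConfig] = None
                    ) -> ScanResult:
    """Return loci where zygosity separates the sexes perfectly.

    Offspring of unknown sex are excluded.  Loci with fewer informative
    offspring than ``min_informative_per_sex`` in either sex are skipped and
    counted, not raised.
    """
    config = config or ScanConfig()
    f_idx = dataset.offspring_indices_by_sex("F")
    m_idx = dataset.offspring_indices_by_sex("M")
    candidates = []
    n_skipped = 0
    for locus_index, locus in enumerate(dataset.loci):
        gts = locus.genotypes
        f_called = [gts[i] for i in f_idx if gts[i] is not None]
        m_called = [gts[i] for i in m_idx if gts[i] is not None]
        missing_f = len(f_idx) - len(f_called)
        missing_m = len(m_idx) - len(m_called)
        if config.require_all_offspring and (missing_f or missing_m):
            continue
        if (len(f_called) < config.min_informative_per_sex
                or len(m_called) < config.min_informative_per_sex):
            n_skipped += 1
            continue
        het_f = sum(1 for g in f_called if _is_het(g))
        het_m = sum(1 for g in m_called if _is_het(g))
        if het_f == len(f_called) and het_m == 0:
            het_sex = "F"
        elif het_m == len(m_called) and het_f == 0:
            het_sex = "M"
        else:
            continue
        candidates.append(
            SexBiasCandidate(
                locus_id=locus.locus_id,
                heterozygous_sex=het_sex,
                het_daughters=het_f,
                hom_daughters=len(f_called) - het_f,
                het_sons=het_m,
                hom_sons=len(m_called) - het_m,
                missing_f=missing_f,
                missing_m=missing_m,
                locus_index=locus_index,
            )
        )
    return ScanResult(candidates, len(dataset.loci), n_skipped)


def classify_heterogamety(dataset: FamilyDataset, candidate: SexBiasCandidate
                          ) -> SexLinkageCall:
    """Assign a W/Z/X/Y inheritance pattern to a sex-biased candidate.

    Requires exactly one heterozygous parent; the heterozygous parent and
    the heterozygous offspring sex jointly determine the pattern.  The call
    is demoted to ``inconsistent`` when the offspring genotypes cannot be
    formed from the parents, or when the homozygous sex does not carry the
    expected non-sex-linked combination.  A missing parent genotype yields
    ``UNASSESSABLE``.
    """
    locus = dataset.loci[candidate.locus_index]
    mother_gt = locus.genotypes[dataset.mother_index]
    father_gt = locus.genotypes[dataset.father_index]
    counts = dict(
        het_daughters=candidate.het_daughters,
        hom_daughters=candidate.hom_daughters,
        het_sons=candidate.het_sons,
        hom_sons=candidate.hom_sons,
        missing_f=candidate.missing_f,
        missing_m=candidate.missing_m,
    )

    def call(pattern: str) -> SexLinkageCall:
        return SexLinkageCall(
            locus_id=candidate.locus_id,
            heterozygous_sex=candidate.heterozygous_sex,
            pattern=pattern,
            mother_gt=mother_gt,
            father_gt=father_gt,
            **counts,
        )

    if mother_gt is None or father_gt is None:
        return call(UNASSESSABLE)
    mother_het, father_het = _is_het(mother_gt), _is_het(father_gt)
    if mother_het == father_het:  # both het or both hom: underdetermined
        return call(INCONSISTENT)

    het_parent = mother_gt if mother_het else father_gt
    hom_parent = father_gt if mother_het else mother_gt
    c = hom_parent[0]
    # The homozygous offspring class must be c/c (c also present in the het
    # parent), and the heterozygous class must be c paired with the het
    # parent's other allele; anything else is a genotype-error artifact.
    if c not in het_parent:
        return call(INCONSISTENT)
    other = het_parent[0] if het_parent[1] == c else het_parent[1]
    expected_het = genotype(c, other)
    expected_hom = genotype(c, c)

    f_idx = dataset.offspring_indices_by_sex("F")
    m_idx = dataset.offspring_indices_by_sex("M")
    het_idx = f_idx if candidate.heterozygous_sex == "F" else m_idx
    hom_idx = m_idx if candidate.heterozygous_sex == "F" else f_idx
    gts = locus.genotypes
    for i in het_idx:
        if gts[i] is not None and gts[i] != expected_het:
            return call(INCONSISTENT)
    for i in hom_idx:
        if gts[i] is not None and gts[i] != expected_hom:
            return call(INCONSISTENT)

    if mother_het:
        return call(W_PATTERN if candidate.heterozygous_sex == "F" else Z_PATTERN)
    return call(Y_PATTERN if candidate.heterozygous_sex == "M" else X_PATTERN)


def scan_and_classify(dataset: FamilyDataset, config: Optional[ScanConfig] = None
                      ) -> list:
    """Convenience: scan then classify every candidate."""
    result = scan_sex_biased(dataset, config)
    return [classify_heterogamety(dataset, c) for c in result.candidates]


@dataclass
class SystemSummary:
    verdict: str  # ZZ/ZW | XX/XY | CONFLICTING | UNDETERMINED
    tallies: dict = field(default_factory=dict)

    def __str__(self) -> str:
        parts = ", ".join(f"{k}: {v}" for k, v in sorted(self.tallies.items()))
        return f"{self.verdict} ({parts})" if parts else self.verdict


def infer_system(calls: list) -> SystemSummary:
    """Tally pattern calls into a heterogamety verdict.

    ZZ/ZW when every informative call is a W or Z pattern, XX/XY when every
    one is X or Y, CONFLICTING when both groups occur, UNDETERMINED when no
    informative calls exist.
    """
    tallies = Counter(c.pattern for c in calls)
    zw = tallies[W_PATTERN] + tallies[Z_PATTERN]
    xy = tallies[X_PATTERN] + tallies[Y_PATTERN]
    if zw and not xy:
        verdict = "ZZ/ZW"
    elif xy and not zw:
        verdict = "XX/XY"
    elif zw and xy:
        verdict = "CONFLICTING"
    else:
        verdict = "UNDETERMINED"
    return SystemSummary(verdict, dict(tallies))
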