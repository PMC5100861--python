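"""Classify sex-linked tags by their reference-genome hit pattern and map
retained scaffolds onto chromosomes.

Short GBS tags queried against a related allotetraploid genome land in one
region (a clean ortholog), two regions (the two homeologs, matched with
similar strength), many regions (repetitive), or none (diverged).  Only the
first two cases are informative: a single-scaffold match is retained
directly, and for a two-scaffold match one scaffold is retained by a seeded
random draw.  Retained scaffolds are then assigned to chromosomes through a
whole-genome alignment segment table; a scaffold whose aligned segments sit
on two different chromosomes is reported as a split alignment.
"""

from __future__ import annotations

import random
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Optional

ONE_REGION = "one_region"
TWO_REGIONS = "two_regions"
MULTIPLE_REGIONS = "multiple_regions"
NO_REGION = "no_region"

SPLIT = "split"
UNPLACED = "unplaced"


@dataclass(frozen=True)
class TagHit:
    query: str
    subject: str
    pident: float
    length: int
    mismatches: int
    gapopens: int
    qstart: int  # 1-based inclusive, standard tabular hit convention
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


@dataclass
class TagHitTable:
    by_query: "OrderedDict[str, list]" = field(default_factory=OrderedDict)

    @classmethod
    def from_hits(cls, hits: list) -> "TagHitTable":
        table = cls()
        for hit in hits:
            if hit.evalue < 0:
                raise ValueError(f"negative e-value for query {hit.query}")
            table.by_query.setdefault(hit.query, []).append(hit)
        return table

    @property
    def queries(self) -> list:
        return list(self.by_query)


@dataclass
class TagScenario:
    query: str
    scenario: str  # one_region | two_regions | multiple_regions | no_region
    scaffolds_below_threshold: list
    retained_scaffold: Optional[str] = None


def classify_tag_hits(table: TagHitTable, evalue_threshold: float = 1e-5,
                      seed: int = 0) -> list:
    """Bucket each tag by its count of distinct scaffolds hit below threshold.

    The e-value comparison is strict (< threshold).  Multiple HSPs on one
    scaffold count as one region.  Two-region tags retain one scaffold by a
    seeded random choice; multi-region and no-region tags are discarded
    (retained_scaffold None).
    """
    rng = random.Random(seed)
    results = []
    for query, hits in table.by_query.items():
        scaffolds = sorted({h.subject for h in hits if h.evalue < evalue_threshold})
        if len(scaffolds) == 0:
            results.append(TagScenario(query, NO_REGION, scaffolds))
        elif len(scaffolds) == 1:
            results.append(TagScenario(query, ONE_REGION, scaffolds, scaffolds[0]))
        elif len(scaffolds) == 2:
            results.append(
                TagScenario(query, TWO_REGIONS, scaffolds, rng.choice(scaffolds))
            )
        else:
            results.append(TagScenario(query, MULTIPLE_REGIONS, scaffolds))
    return results


@dataclass(frozen=True)
class ChromSegment:
    scaffold: str
    chromosome: str
    start: int  # half-open on the scaffold
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ScaffoldChromMap:
    segments: list

    def __post_init__(self) -> None:
        self.by_scaffold: dict = {}
        for seg in self.segments:
            if seg.start >= seg.end:
                raise ValueError(f"degenerate segment {seg}")
            self.by_scaffold.setdefault(seg.scaffold, []).append(seg)


@dataclass
class ChromAssignment:
    scaffold: str
    placement: str  # a chromosome name | "split" | "unplaced"
    chromosomes: tuple = ()  # the pair for splits
    reason: Optional[str] = None


def assign_chromosome(scaffold: str, chrom_map: ScaffoldChromMap,
                      min_span: int = 1000) -> ChromAssignment:
    """Place a scaffold on a chromosome from its alignment segments.

    Chromosomes supported by >= min_span aligned bases count; exactly one
    such chromosome places the scaffold there, exactly two is a split
    alignment, and zero or three-plus leaves it unplaced with a reason.
    """
    segments = chrom_map.by_scaffold.get(scaffold, [])
    if not segments:
        return ChromAssignment(scaffold, UNPLACED, reason="not_in_map")
    spans = Counter()
    for seg in segments:
        spans[seg.chromosome] += seg.span
    supported = sorted(c for c, s in spans.items() if s >= min_span)
    if len(supported) == 1:
        return ChromAssignment(scaffold, supported[0])
    if len(supported) == 2:
        return ChromAssignment(scaffold, SPLIT, chromosomes=tuple(supported))
    if len(supported) == 0:
        return ChromAssignment(scaffold, UNPLACED, reason="below_min_span")
    return ChromAssignment(
        scaffold, UNPLACED, reason=f"{len(supported)}_chromosomes"
    )


@dataclass
class TagAssignment:
    query: str
    scenario: str
    retained_scaffold: Optional[str]
    placement: Optional[ChromAssignment]


def assign_tags(scenarios: list, chrom_map: ScaffoldChromMap,
                min_span: int = 1000) -> list:
    """Chromosome placement for every retained tag (discarded tags pass
    through with no placement)."""
    out = []
    for sc in scenarios:
        placement = None
        if sc.retained_scaffold is not None:
            placement = assign_chromosome(sc.retained_scaffold, chrom_map, min_span)
        out.append(TagAssignment(sc.query, sc.scenario, sc.retained_scaffold, placement))
    return out


def summarize_assignments(assignments: list) -> "OrderedDict[str, int]":
    """Per-chromosome tag tally (sorted), plus split/unplaced/discarded."""
    counts: Counter = Counter()
    n_split = n_unplaced = n_discarded = 0
    for a in assignments:
        if a.placement is None:
            n_discarded += 1
        elif a.placement.placement == SPLIT:
            n_split += 1
        elif a.placement.placement == UNPLACED:
            n_unplaced += 1
        else:
            counts[a.placement.placement] += 1
    tally: "OrderedDict[str, int]" = OrderedDict(sorted(counts.items()))
    if n_split:
        tally[SPLIT] = n_split
    if n_unplaced:
        tally[UNPLACED] = n_unplaced
    if n_discarded:
        tally["discarded"] = n_discarded
    return tally


def write_assignments_tsv(assignments: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("query\tscenario\tretained_scaffold\tplacement\tchromosomes\n")
        for a in assignments:
            place = a.placement.placement if a.placement else ""
            chroms = ",".join(a.placement.chromosomes) if a.placement else ""
            fh.write(
                f"{a.query}\t{a.scenario}\t{a.retained_scaffold or ''}\t"
                f"{place}\t{chroms}\n"
            )
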