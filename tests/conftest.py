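"""Shared builders for small hand-constructed families and datasets."""

import pytest

from zwscan import FamilyDataset, Individual, LocusRecord, genotype


def gt(token):
    """'A/T' -> canonical genotype tuple; './.' -> None."""
    if token in ("./.", None):
        return None
    a, b = token.split("/")
    return genotype(a, b)


def make_family(offspring_sexes, locus_rows, ids=None):
    """Build a FamilyDataset from genotype-token rows.

    offspring_sexes: string like "FFMM"; locus_rows: list of
    (locus_id, mother, father, [offspring tokens...]).
    """
    individuals = [Individual("mother", "mother", "F"),
                   Individual("father", "father", "M")]
    for i, sex in enumerate(offspring_sexes):
        individuals.append(Individual(f"o{i + 1:02d}", "offspring", sex))
    loci = []
    for locus_id, m, f, offspring in locus_rows:
        gts = [gt(m), gt(f)] + [gt(t) for t in offspring]
        alleles = frozenset(a for g in gts if g is not None for a in g)
        loci.append(LocusRecord(locus_id, alleles, gts))
    return FamilyDataset(individuals, loci)


@pytest.fixture
def trio_sexes():
    return "F" * 24 + "M" * 23
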