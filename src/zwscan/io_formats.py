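"""Readers and writers for the external formats the pipeline touches.

All downstream modules operate on the in-memory domain types defined here
(:class:`FamilyDataset`, :class:`LocusRecord`) and in their own modules
(gene families, hit tables).  Genotypes are unordered, unphased diploid
allele pairs: ``("A", "T")`` and ``("T", "A")`` are the same genotype and
are always stored in sorted order.  Half-calls (``./A``) are treated as
missing because the undercall-correction logic requires full diploid calls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import (
    AlignmentError,
    GenotypeParseError,
    HitTableParseError,
    PedigreeError,
    SampleMismatchError,
)

#: A diploid genotype: a sorted pair of allele symbols, or None for missing.
Genotype = Optional[tuple]

MISSING: Genotype = None

ROLES = ("mother", "father", "offspring")
SEXES = ("F", "M", "U")

# Genotype tuples are interned: a 100k-locus family holds ~5M cells but only
# a handful of distinct genotypes, so cells share tuple objects.
_GT_CACHE: dict = {}


def genotype(a: str, b: str) -> tuple:
    """Canonical (sorted, interned) unordered genotype for two allele symbols."""
    key = (a, b) if a <= b else (b, a)
    gt = _GT_CACHE.get(key)
    if gt is None:
        gt = _GT_CACHE[key] = key
    return gt


@dataclass(frozen=True)
class Individual:
    id: str
    role: str  # mother | father | offspring
    sex: str  # F | M | U


@dataclass
class LocusRecord:
    """One biallelic (or flagged multiallelic) tag SNP.

    ``genotypes`` is aligned with the parent dataset's individual order.
    """

    locus_id: str
    alleles: frozenset
    genotypes: list  # list[Genotype], one per individual

    @property
    def multiallelic(self) -> bool:
        return len(self.alleles) > 2

    def validate(self, n_individuals: int) -> None:
        if len(self.genotypes) != n_individuals:
            raise GenotypeParseError(
                f"locus {self.locus_id}: {len(self.genotypes)} genotypes for "
                f"{n_individuals} individuals"
            )
        for gt in self.genotypes:
            if gt is not None and not set(gt) <= self.alleles:
                raise GenotypeParseError(
                    f"locus {self.locus_id}: genotype {gt} uses alleles outside "
                    f"{sorted(self.alleles)}"
                )


@dataclass
class FamilyDataset:
    """Genotype matrix (loci x individuals) for a two-parent family cross."""

    individuals: list  # list[Individual]
    loci: list  # list[LocusRecord]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual ids: {dupes}")
        mothers = [i for i in self.individuals if i.role == "mother"]
        fathers = [i for i in self.individuals if i.role == "father"]
        if len(mothers) != 1 or len(fathers) != 1:
            raise PedigreeError(
                f"need exactly one mother and one father, got "
                f"{len(mothers)} mother(s) and {len(fathers)} father(s)"
            )
        for locus in self.loci:
            locus.validate(len(self.individuals))

    # -- indexing helpers -------------------------------------------------
    @property
    def mother_index(self) -> int:
        return next(i for i, x in enumerate(self.individuals) if x.role == "mother")

    @property
    def father_index(self) -> int:
        return next(i for i, x in enumerate(self.individuals) if x.role == "father")

    @property
    def offspring_indices(self) -> list:
        return [i for i, x in enumerate(self.individuals) if x.role == "offspring"]

    def offspring_indices_by_sex(self, sex: str) -> list:
        return [
            i
            for i, x in enumerate(self.individuals)
            if x.role == "offspring" and x.sex == sex
        ]

    def with_loci(self, loci: Iterable[LocusRecord]) -> "FamilyDataset":
        return FamilyDataset(individuals=self.individuals, loci=list(loci))


# ---------------------------------------------------------------------------
# Pedigree + genotype matrix loading
# ---------------------------------------------------------------------------


def load_pedigree(path: str) -> list:
    """Read a pedigree TSV with header columns id, role, sex."""
    individuals = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_id, i_role, i_sex = (header.index(c) for c in ("id", "role", "sex"))
        except ValueError as exc:
            raise PedigreeError(f"pedigree header must contain id/role/sex: {header}") from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ind = Individual(parts[i_id], parts[i_role], parts[i_sex])
            if ind.role not in ROLES:
                raise PedigreeError(f"line {lineno}: unknown role {ind.role!r}")
            if ind.sex not in SEXES:
                raise PedigreeError(f"line {lineno}: unknown sex {ind.sex!r}")
            individuals.append(ind)
    return individuals


def _parse_tsv_token(token: str, lineno: int, locus_id: str) -> Genotype:
    if token in ("./.", ".", "NA"):
        return MISSING
    parts = token.split("/")
    if len(parts) != 2 or not all(parts):
        raise GenotypeParseError(
            f"line {lineno} (locus {locus_id}): malformed genotype token {token!r}"
        )
    a, b = parts
    if a == "." or b == ".":  # half-call -> missing
        return MISSING
    return genotype(a, b)


def _load_genotype_tsv(path: str) -> tuple:
    """Return (sample_ids, loci) from the TSV dialect.

    Format: header row ``locus_id<TAB>id1<TAB>id2...``; one row per locus
    with ``A/T`` style tokens, ``./.`` for missing.
    """
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        n = len(sample_ids)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n + 1:
                raise GenotypeParseError(
                    f"line {lineno}: expected {n + 1} columns, got {len(parts)}"
                )
            locus_id = parts[0]
            gts = [_parse_tsv_token(t, lineno, locus_id) for t in parts[1:]]
            alleles = frozenset(a for gt in gts if gt is not None for a in gt)
            loci.append(LocusRecord(locus_id, alleles, gts))
    return sample_ids, loci


def _load_genotype_vcf(path: str) -> tuple:
    """Return (sample_ids, loci) from a VCF (GT field only; unphased)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    loci = []
    for variant in vcf:
        allele_strs = [variant.REF] + list(variant.ALT)
        locus_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        gts = []
        for g in variant.genotypes:
            a, b = g[0], g[1]
            if a < 0 or b < 0:  # missing or half-call
                gts.append(MISSING)
            else:
                gts.append(genotype(allele_strs[a], allele_strs[b]))
        alleles = frozenset(a for gt in gts if gt is not None for a in gt)
        loci.append(LocusRecord(locus_id, alleles, gts))
    return sample_ids, loci


def load_family_dataset(genotype_path: str, pedigree_path: str) -> FamilyDataset:
    """Load and validate a family genotype matrix plus its pedigree.

    The genotype file is a VCF (by ``.vcf``/``.vcf.gz`` extension) or the TSV
    dialect.  Individual order follows the pedigree file; genotype columns
    are reconciled by sample id.
    """
    individuals = load_pedigree(pedigree_path)
    if genotype_path.endswith((".vcf", ".vcf.gz")):
        sample_ids, loci = _load_genotype_vcf(genotype_path)
    else:
        sample_ids, loci = _load_genotype_tsv(genotype_path)

    ped_ids = [ind.id for ind in individuals]
    if set(sample_ids) != set(ped_ids):
        only_gt = sorted(set(sample_ids) - set(ped_ids))
        only_ped = sorted(set(ped_ids) - set(sample_ids))
        raise SampleMismatchError(
            f"sample ids differ between genotype file and pedigree "
            f"(only in genotypes: {only_gt}; only in pedigree: {only_ped})"
        )
    order = [sample_ids.index(i) for i in ped_ids]
    reordered = [
        LocusRecord(l.locus_id, l.alleles, [l.genotypes[j] for j in order])
        for l in loci
    ]
    return FamilyDataset(individuals=individuals, loci=reordered)


def write_family_dataset(dataset: FamilyDataset, genotype_path: str,
                         pedigree_path: Optional[str] = None) -> None:
    """Write the TSV dialect (and optionally the pedigree TSV)."""
    with open(genotype_path, "w") as fh:
        fh.write("locus_id\t" + "\t".join(i.id for i in dataset.individuals) + "\n")
        for locus in dataset.loci:
            tokens = [
                "./." if gt is None else f"{gt[0]}/{gt[1]}" for gt in locus.genotypes
            ]
            fh.write(locus.locus_id + "\t" + "\t".join(tokens) + "\n")
    if pedigree_path is not None:
        write_pedigree(dataset.individuals, pedigree_path)


def write_pedigree(individuals: Sequence[Individual], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\trole\tsex\n")
        for ind in individuals:
            fh.write(f"{ind.id}\t{ind.role}\t{ind.sex}\n")


def write_family_vcf(dataset: FamilyDataset, path: str) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields.

    Loci become unanchored records on a synthetic contig; allele order is
    alphabetical (REF = first allele).  Round-trips through
    :func:`load_family_dataset` up to allele-order relabeling.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=tags>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(i.id for i in dataset.individuals)
            + "\n"
        )
        for pos, locus in enumerate(dataset.loci, start=1):
            alleles = sorted(locus.alleles) or ["N"]
            ref, alts = alleles[0], alleles[1:]
            index = {a: i for i, a in enumerate(alleles)}
            cols = [
                "tags", str(pos), locus.locus_id, ref,
                ",".join(alts) if alts else ".", ".", ".", ".", "GT",
            ]
            for gt in locus.genotypes:
                cols.append("./." if gt is None else f"{index[gt[0]]}/{index[gt[1]]}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene families (FASTA alignment + optional Newick tree)
# ---------------------------------------------------------------------------


def parse_species(name: str, delimiter: str = "|") -> str:
    """Species label = sequence name up to the first delimiter (``xlae|c1``)."""
    if delimiter not in name:
        raise AlignmentError(
            f"sequence name {name!r} has no {delimiter!r} species delimiter"
        )
    species = name.split(delimiter, 1)[0]
    if not species:
        raise AlignmentError(f"empty species label in sequence name {name!r}")
    return species


def load_gene_family(alignment_path: str, tree_path: Optional[str] = None,
                     delimiter: str = "|"):
    """Load a species-tagged FASTA alignment, with an optional Newick tree."""
    from Bio import SeqIO

    from .homeolog_filter import GeneFamily

    names, seqs = [], []
    for rec in SeqIO.parse(alignment_path, "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not names:
        raise AlignmentError(f"{alignment_path}: no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(
            f"{alignment_path}: ragged alignment (row lengths {sorted(lengths)})"
        )
    species = {n: parse_species(n, delimiter) for n in names}

    tree = None
    if tree_path is not None:
        import dendropy

        tree = dendropy.Tree.get(path=tree_path, schema="newick")
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        if tips != set(names):
            raise AlignmentError(
                f"tree tips and alignment names differ "
                f"(only in tree: {sorted(tips - set(names))}; "
                f"only in alignment: {sorted(set(names) - tips)})"
            )
    family_id = os.path.splitext(os.path.basename(alignment_path))[0]
    return GeneFamily(
        family_id=family_id,
        names=names,
        sequences=dict(zip(names, seqs)),
        species=species,
        tree=tree,
    )


def write_gene_family(family, path: str) -> None:
    with open(path, "w") as fh:
        for name in family.names:
            fh.write(f">{name}\n{family.sequences[name]}\n")


# ---------------------------------------------------------------------------
# Tabular hit files and scaffold->chromosome maps
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def load_hit_table(path: str):
    """Read a 12-column tabular hit file (outfmt-6 style) into a TagHitTable.

    Coordinates are 1-based inclusive as in the standard tabular hit format.
    """
    from .tag_homology import TagHit, TagHitTable

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise HitTableParseError(
                    f"line {lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                hit = TagHit(
                    query=parts[0],
                    subject=parts[1],
                    pident=float(parts[2]),
                    length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gapopens=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except ValueError as exc:
                raise HitTableParseError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    return TagHitTable.from_hits(hits)


def load_scaffold_chrom_map(path: str):
    """Read the scaffold->chromosome mapping TSV.

    Columns: scaffold_id, chromosome, aln_start, aln_end (half-open on the
    scaffold; start < end required).
    """
    from .tag_homology import ChromSegment, ScaffoldChromMap

    segments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["scaffold_id", "chromosome"]:
            raise HitTableParseError(
                f"map header must start scaffold_id/chromosome: {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise HitTableParseError(
                    f"line {lineno}: expected 4 columns, got {len(parts)}"
                )
            start, end = int(parts[2]), int(parts[3])
            if start >= end:
                raise HitTableParseError(
                    f"line {lineno}: degenerate segment [{start}, {end})"
                )
            segments.append(ChromSegment(parts[0], parts[1], start, end))
    return ScaffoldChromMap(segments)
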