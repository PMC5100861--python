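# zwscan

Tools for discovering sex-linked markers in a single family cross, with the
genotype QC that makes such a scan trustworthy, and companion utilities for
comparative follow-up in allotetraploid frogs (subgenus *Xenopus*): gene-tree
based ortholog/homeolog disambiguation, tag-to-genome hit classification,
and small phylogenetic post-processing helpers.

## Who this is for

Researchers with reduced-representation (GBS/RAD) genotypes for a two-parent
family — mother, father, and sexed offspring — who want to know whether the
species has genetic sex determination, which sex is heterogametic (ZZ/ZW or
XX/XY), and which markers ride the sex chromosomes. The package also serves
groups working in allopolyploids who need to separate orthologous from
homeologous gene copies before any multi-species analysis.

## The method

**Genotype QC.** Offspring sequenced at low coverage suffer allele dropout:
a true heterozygote is read as a homozygote. With parents sequenced at ~10×
the offspring coverage, dropout shows up as Mendelian-implausible offspring
calls — e.g. parents A/T × A/A with an offspring called T/T. Per locus, with
*f* = (implausible calls) / (called offspring):

- *f* < 10% → implausible calls are set to missing, the locus is kept;
- *f* ≥ 10% → the locus is discarded.

A call-rate filter (genotyped in ≥ 90% of individuals) runs first.

**Sex-linkage scan.** A locus is *completely sex-biased* when every called
offspring of one sex is heterozygous and every called offspring of the other
sex is homozygous. The parents then identify the chromosome:

| mother | father | het offspring | pattern | system |
|--------|--------|---------------|---------|--------|
| het    | hom    | daughters     | W       | ZZ/ZW  |
| het    | hom    | sons          | Z       | ZZ/ZW  |
| hom    | het    | sons          | Y       | XX/XY  |
| hom    | het    | daughters     | X       | XX/XY  |

For an autosomal locus with one heterozygous parent and *n* called
offspring, complete sex bias arises by chance with probability 2·(1/2)ⁿ —
about 1.4 × 10⁻¹⁴ at *n* = 47 — so even one such locus is strong evidence.

**Ortholog/homeolog filter.** In an allotetraploid whose genome duplication
predates speciation, orthologs are more closely related than homeologs. A
gene family passes when its tree has an edge splitting the ingroup
sequences into two groups with (a) ≤ 1 sequence per species per group,
(b) ≥ 1 species present in both groups, and (c) ≥ 1 group of ≥ 3 sequences.
Alignment QC (ungapped length > 299 bp, ≥ 3 ingroup species, ≥ 1 duplicated
species) runs first; trees come from built-in neighbor-joining on
pairwise-deletion p-distances or are supplied; near-identical same-species
tips (splice variants, assembly duplicates) are pruned between up to three
build/assess rounds.

## Worked example

Simulate a ZW cross (24 daughters, 23 sons; 5,000 autosomal loci, 25
W-borne and 1 maternal-Z-borne variant; 2% allele dropout, 2% missingness),
run QC, and scan:

```sh
zwscan simulate-family --autosomal 5000 --sexlinked 25 --sexlinked-shared 1 \
    --system ZW --undercall 0.02 --missing 0.02 --seed 1 \
    -o fam.vcf --pedigree ped.tsv --truth truth.tsv
zwscan qc fam.vcf --pedigree ped.tsv -o qc.vcf --report qc_report.tsv
zwscan scan qc.vcf --pedigree ped.tsv -o calls.tsv --summary summary.txt
```

prints

```
wrote 5026 loci x 49 individuals
5026 loci in, 5004 kept
24 sex-biased loci; system: ZZ/ZW (W_pattern: 24)
```

and `calls.tsv` begins

```
locus_id   pattern    het_sex  mother_gt  father_gt  het_daughters  hom_daughters  het_sons  hom_sons  n_missing_F  n_missing_M
tag000493  W_pattern  F        C/T        T/T        24             0              0         22        0            1
tag000788  W_pattern  F        C/T        C/C        24             0              0         23        0            0
```

Reading: 24 of the 26 simulated sex-linked loci survive as completely
sex-biased W-pattern calls (mother heterozygous, father homozygous, all
daughters heterozygous, all sons homozygous), and the verdict is female
heterogamety (ZZ/ZW). Two loci are lost because an undercall to the
*Mendelian-plausible* homozygote is undetectable and breaks the
"completely heterozygous" requirement — with error-free genotypes the scan
recovers all 26 exactly (see below). The QC step dropped 22 of 5,026 loci.

The other stages work the same way from Python or the CLI:
`zwscan filter-homeologs`, `zwscan classify-tags`, `zwscan clock-bf`,
`zwscan rescale-trees`; see `zwscan --help`.

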